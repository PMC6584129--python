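"""Binding-site filtering, gene association, region classification, summaries."""

import math

import pytest

from lsr2tools.annotation import GeneModel
from lsr2tools.expression import DERecord, join_sites_expression
from lsr2tools.peaks import (
    BindingSite,
    annotate_sites,
    assign_site_to_genes,
    classify_region,
    filter_sites,
    read_site_table,
    site_gc,
    summarize_by_region,
)
from lsr2tools.sequence import NucSequence


class TestFilterSites:
    def test_strict_boundary(self):
        sites = [BindingSite(1, 10, 0.005), BindingSite(1, 10, 0.01), BindingSite(1, 10, 0.5)]
        kept = filter_sites(sites)
        assert kept == [sites[0]]  # q = 0.01 excluded by the strict <

    def test_matches_brute_force_filter(self, rng):
        sites = [BindingSite(1, 10, float(q)) for q in rng.uniform(0, 0.03, 200)]
        assert filter_sites(sites) == [s for s in sites if s.q_value < 0.01]


class TestGeneAssociation:
    def test_site_inside_gene_body(self):
        gene = GeneModel("g1", 1000, 2000, "+")
        assert assign_site_to_genes(BindingSite(1200, 1300, 0), [gene]) == [
            ("g1", "overlaps_cds")
        ]

    def test_site_far_from_gene(self):
        gene = GeneModel("g1", 1000, 2000, "+")
        assert assign_site_to_genes(BindingSite(5000, 5100, 0), [gene], 300) == []

    def test_divergent_promoter_hits_both_genes(self):
        # <-- left gene | intergenic | right gene -->
        left = GeneModel("gL", 500, 1000, "-")
        right = GeneModel("gR", 1400, 2000, "+")
        hits = assign_site_to_genes(BindingSite(1150, 1250, 0), [left, right], 300)
        assert set(hits) == {("gL", "upstream"), ("gR", "upstream")}

    def test_upstream_is_strand_aware(self):
        plus = GeneModel("gP", 1000, 2000, "+")
        minus = GeneModel("gM", 1000, 2000, "-")
        downstream_of_plus = BindingSite(2050, 2100, 0)
        assert assign_site_to_genes(downstream_of_plus, [plus], 300) == []
        assert assign_site_to_genes(downstream_of_plus, [minus], 300) == [("gM", "upstream")]

    def test_both_relations_reported(self):
        gene = GeneModel("g1", 1000, 2000, "+")
        hits = assign_site_to_genes(BindingSite(900, 1100, 0), [gene], 300)
        assert set(hits) == {("g1", "overlaps_cds"), ("g1", "upstream")}

    def test_mirror_symmetry_with_strand_flip(self, rng):
        """Associations are invariant under coordinate mirroring + strand flip."""
        L = 10_000
        genes = [GeneModel("g1", 2000, 2600, "+"), GeneModel("g2", 5000, 5400, "-")]
        mirrored = [
            GeneModel(g.locus_id, L + 1 - g.end, L + 1 - g.start, "+" if g.strand == "-" else "-")
            for g in genes
        ]
        for _ in range(50):
            start = int(rng.integers(1, L - 200))
            site = BindingSite(start, start + 199, 0)
            m_site = BindingSite(L + 1 - site.end, L + 1 - site.start, 0)
            direct = sorted(assign_site_to_genes(site, genes, 300))
            mirror = sorted(assign_site_to_genes(m_site, mirrored, 300))
            assert direct == mirror


class TestRegions:
    def test_midpoint_labels_match_brute_force(self, rng, small_regions):
        for _ in range(100):
            start = int(rng.integers(1, 9800))
            site = BindingSite(start, start + int(rng.integers(1, 200)), 0)
            label = classify_region(site, small_regions)
            mid = site.midpoint
            expected = next(
                name
                for name, (lo, hi) in [
                    ("left_arm", small_regions.left_arm),
                    ("core", small_regions.core),
                    ("right_arm", small_regions.right_arm),
                ]
                if lo <= mid <= hi
            )
            assert label == expected

    def test_midpoint_outside_chromosome_errors(self, small_regions):
        with pytest.raises(ValueError):
            classify_region(BindingSite(10_500, 10_600, 0), small_regions)


class TestSiteGC:
    def test_gc_only_region(self):
        chrom = NucSequence("c", "A" * 50 + "G" * 50)
        assert site_gc(BindingSite(51, 100, 0), chrom) == 1.0

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            site_gc(BindingSite(90, 120, 0), NucSequence("c", "A" * 100))


class TestSummaries:
    def _annotated(self, small_genes, small_regions, sites, changed):
        anns = annotate_sites(sites, small_genes, regions=small_regions)
        de = [
            DERecord(locus, 10.0, 0.001)
            for a, flag in zip(anns, changed)
            if flag
            for locus, _ in a.associated_genes
        ]
        return join_sites_expression(anns, de)

    def test_counts_sum_and_fractions(self, small_genes, small_regions):
        sites = [
            BindingSite(600, 700, 0.001),      # left arm
            BindingSite(4000, 4100, 0.001),    # core
            BindingSite(8200, 8300, 0.001),    # right arm
            BindingSite(8600, 8700, 0.001),    # right arm
        ]
        anns = self._annotated(small_genes, small_regions, sites, [True, False, True, True])
        summary = summarize_by_region(anns)
        assert summary["n_sites"].sum() == len(sites)
        assert (summary["fraction_with_change"] <= 1).all()

    def test_all_changed_gives_fraction_one(self, small_genes, small_regions):
        sites = [BindingSite(600, 700, 0.001), BindingSite(4000, 4100, 0.001)]
        anns = self._annotated(small_genes, small_regions, sites, [True, True])
        summary = summarize_by_region(anns)
        assert (summary["fraction_with_change"] == 1.0).all()

    def test_width_mean_and_empty_group_absent(self, small_genes, small_regions):
        sites = [BindingSite(600, 699, 0.001), BindingSite(701, 1000, 0.001)]  # widths 100, 300
        anns = self._annotated(small_genes, small_regions, sites, [True, True])
        summary = summarize_by_region(anns)
        assert summary.loc["left_arm", "mean_width_change"] == pytest.approx(200)
        assert math.isnan(summary.loc["left_arm", "mean_width_no_change"])

    def test_unjoined_sites_rejected(self, small_genes, small_regions):
        anns = annotate_sites([BindingSite(600, 700, 0.001)], small_genes, regions=small_regions)
        with pytest.raises(ValueError, match="transcription_change"):
            summarize_by_region(anns)


def test_read_site_table_tsv_and_bed(tmp_path):
    tsv = tmp_path / "sites.tsv"
    tsv.write_text("chrom\tstart\tend\tq_value\nc\t100\t200\t0.001\n")
    (s,) = read_site_table(tsv)
    assert (s.start, s.end, s.q_value) == (100, 200, 0.001)
    bed = tmp_path / "sites.bed"
    bed.write_text("c\t99\t200\tsite1\t0.001\n")
    (sb,) = read_site_table(bed, dialect="bed")
    assert (sb.start, sb.end, sb.q_value) == (100, 200, 0.001)
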