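"""Binding-site annotation: gene association, region classification, summaries.

ChIP-derived binding intervals are filtered at q < 0.01, associated with
genes they overlap or sit immediately upstream of (strand-aware, default
300-nt promoter window; a site between divergent genes can associate with
both), assigned to the left-arm/core/right-arm chromosome region containing
their midpoint, tagged with any specialized metabolic clusters they fall
in, and summarized per region by count, fraction associated with a
transcriptional change, and mean width by change status.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .annotation import ChromosomeRegions, ClusterDef, GeneModel
from .sequence import NucSequence, gc_content

__all__ = [
    "BindingSite",
    "SiteAnnotation",
    "filter_sites",
    "read_site_table",
    "assign_site_to_genes",
    "classify_region",
    "assign_clusters",
    "annotate_sites",
    "summarize_by_region",
    "site_gc",
]

DEFAULT_Q_MAX = 0.01
DEFAULT_UPSTREAM_WINDOW = 300


@dataclass(frozen=True)
class BindingSite:
    """A binding interval in 1-based inclusive coordinates with a q-value."""

    start: int
    end: int
    q_value: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"site ({self.start}, {self.end}): start > end")
        if not (0 <= self.q_value <= 1):
            raise ValueError("q_value must lie in [0, 1]")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class SiteAnnotation:
    site: BindingSite
    associated_genes: tuple = ()  # of (locus_id, relation) with relation in {overlaps_cds, upstream}
    region: str | None = None
    clusters: tuple = ()
    transcription_change: bool | None = None
    gc_fraction: float | None = None

    def with_transcription_change(self, changed: bool) -> "SiteAnnotation":
        return replace(self, transcription_change=changed)


def filter_sites(sites: Iterable[BindingSite], q_max: float = DEFAULT_Q_MAX) -> list[BindingSite]:
    """Sites with q strictly below ``q_max``, order preserved."""
    return [s for s in sites if s.q_value < q_max]


def read_site_table(path, dialect: str = "tsv") -> list[BindingSite]:
    """Read sites from a TSV (chrom,start,end,q; 1-based inclusive) or a
    BED-like file (0-based half-open, score column holds q)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower().strip(): c for c in df.columns}
    if dialect == "tsv":
        needed = ["start", "end", "q_value" if "q_value" in cols else "q"]
        if not all(c in cols for c in needed):
            raise ValueError(f"{path}: need start/end/q columns; found {list(df.columns)}")
        qcol = cols["q_value"] if "q_value" in cols else cols["q"]
        return [
            BindingSite(int(r[cols["start"]]), int(r[cols["end"]]), float(r[qcol]))
            for _, r in df.iterrows()
        ]
    if dialect == "bed":
        arr = pd.read_csv(path, sep="\t", header=None, comment="#")
        return [
            BindingSite(int(r[1]) + 1, int(r[2]), float(r[4] if len(r) > 4 else r[3]))
            for _, r in arr.iterrows()
        ]
    raise ValueError(f"unknown site-table dialect {dialect!r}")


def _upstream_interval(gene: GeneModel, window: int) -> tuple[int, int] | None:
    """Strand-aware promoter interval of ``window`` nt ending at the 5' end."""
    if window <= 0:
        return None
    if gene.strand == "+":
        lo, hi = gene.start - window, gene.start - 1
    else:
        lo, hi = gene.end + 1, gene.end + window
    if hi < 1:
        return None
    return max(lo, 1), hi


def assign_site_to_genes(
    site: BindingSite,
    genes: Sequence[GeneModel],
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
) -> list[tuple[str, str]]:
    """Genes a site overlaps or sits immediately upstream of.

    A gene is associated when the site intersects its body
    (``overlaps_cds``) and/or its strand-aware upstream window
    (``upstream``); both relations are reported when both hold, and a site
    centred between two divergently transcribed genes can associate with
    both. Requires ``upstream_window >= 0``.
    """
    if upstream_window < 0:
        raise ValueError("upstream_window must be >= 0")
    out: list[tuple[str, str]] = []
    for gene in genes:
        if site.start <= gene.end and site.end >= gene.start:
            out.append((gene.locus_id, "overlaps_cds"))
        ival = _upstream_interval(gene, upstream_window)
        if ival is not None and site.start <= ival[1] and site.end >= ival[0]:
            out.append((gene.locus_id, "upstream"))
    return out


def classify_region(site: BindingSite, regions: ChromosomeRegions) -> str:
    """Region label of the interval containing the site midpoint.

    A midpoint on a boundary belongs to the leftward interval (the
    partition is built from inclusive intervals, so no coordinate is
    ambiguous).
    """
    return regions.label_of(site.midpoint)


def assign_clusters(
    site: BindingSite,
    clusters: Sequence[ClusterDef],
    genes: Sequence[GeneModel],
) -> list[str]:
    """Names of clusters whose genomic span intersects the site."""
    names = []
    for cl in clusters:
        try:
            lo, hi = cl.genomic_span(genes)
        except ValueError:
            continue
        if site.start <= hi and site.end >= lo:
            names.append(cl.name)
    return names


def site_gc(site: BindingSite, chrom: NucSequence) -> float:
    """GC fraction of the chromosome subsequence spanned by the site."""
    if not (1 <= site.start and site.end <= len(chrom)):
        raise ValueError(
            f"site [{site.start}, {site.end}] outside chromosome of length {len(chrom)}"
        )
    return gc_content(chrom.subsequence(site.start, site.end))


def annotate_sites(
    sites: Iterable[BindingSite],
    genes: Sequence[GeneModel],
    regions: ChromosomeRegions | None = None,
    clusters: Sequence[ClusterDef] = (),
    chrom: NucSequence | None = None,
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
) -> list[SiteAnnotation]:
    """Full per-site annotation (gene associations, region, clusters, GC)."""
    out = []
    for site in sites:
        out.append(
            SiteAnnotation(
                site=site,
                associated_genes=tuple(assign_site_to_genes(site, genes, upstream_window)),
                region=classify_region(site, regions) if regions is not None else None,
                clusters=tuple(assign_clusters(site, clusters, genes)) if clusters else (),
                gc_fraction=site_gc(site, chrom) if chrom is not None else None,
            )
        )
    return out


def summarize_by_region(annotated_sites: Sequence[SiteAnnotation]) -> pd.DataFrame:
    """Per-region site counts, change fractions, and width means.

    Returns one row per region with columns ``n_sites``, ``n_with_change``,
    ``fraction_with_change``, ``mean_width_change``, ``mean_width_no_change``.
    Means over empty groups are reported as NaN (absent), never zero.
    Requires ``transcription_change`` to have been joined on every site.
    """
    rows = []
    for ann in annotated_sites:
        if ann.transcription_change is None:
            raise ValueError("transcription_change not joined; run join_sites_expression first")
        rows.append(
            {
                "region": ann.region,
                "width": ann.site.width,
                "change": bool(ann.transcription_change),
            }
        )
    df = pd.DataFrame(rows)
    out = []
    for region, grp in df.groupby("region", sort=True):
        changed = grp[grp["change"]]
        unchanged = grp[~grp["change"]]
        out.append(
            {
                "region": region,
                "n_sites": len(grp),
                "n_with_change": len(changed),
                "fraction_with_change": len(changed) / len(grp),
                "mean_width_change": changed["width"].mean() if len(changed) else float("nan"),
                "mean_width_no_change": unchanged["width"].mean() if len(unchanged) else float("nan"),
            }
        )
    return pd.DataFrame(out).set_index("region")
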