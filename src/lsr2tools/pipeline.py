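"""End-to-end run configuration and combined reporting.

``run_pipeline`` ties the stages together over one set of inputs: load the
chromosome, genes, clusters, sites and DE table; filter sites and DE
records at the reference thresholds; annotate sites (gene association,
region, clusters, GC); join transcriptional changes; summarize per region
and per cluster; run the binomial cluster-enrichment test; optionally run
the volatile pipeline. All outputs are TSVs under one directory plus a
JSON manifest of every parameter, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation, expression, peaks, sequence, volatiles

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str
    fasta: str | None = None
    genes: str | None = None
    clusters: str | None = None
    sites: str | None = None
    de_table: str | None = None
    volatile_matrix: str | None = None
    volatile_groups: str | None = None
    region_boundaries: dict | None = None
    total_loci: int | None = None
    fc_threshold: float = expression.DEFAULT_FC_THRESHOLD
    q_threshold: float = expression.DEFAULT_Q_THRESHOLD
    site_q_max: float = peaks.DEFAULT_Q_MAX
    alpha: float = 0.05
    upstream_window: int = peaks.DEFAULT_UPSTREAM_WINDOW
    scan: sequence.ScanConfig = field(default_factory=sequence.ScanConfig)
    seed: int = 0

    def validate(self) -> None:
        for attr in ("fc_threshold", "q_threshold", "site_q_max", "alpha"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        for attr in ("fasta", "genes", "clusters", "sites", "de_table",
                     "volatile_matrix", "volatile_groups"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{attr}: no such file {path}")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage the config provides inputs for; return the bundle.

    The returned dict maps section name to DataFrame (also written as
    ``<out_dir>/<section>.tsv``); a ``manifest.json`` records parameters.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, pd.DataFrame] = {}

    chrom = None
    if config.fasta:
        records = sequence.read_fasta(config.fasta)
        chrom = records[0]
        profiles = [sequence.at_profile(r, config.scan) for r in records]
        bundle["sequence_profiles"] = pd.DataFrame([dataclasses.asdict(p) for p in profiles])

    genes = annotation.read_annotation(config.genes) if config.genes else []
    clusters = annotation.read_cluster_table(config.clusters) if config.clusters else []
    regions = (
        annotation.partition_regions(config.region_boundaries)
        if config.region_boundaries
        else None
    )

    de_records = []
    if config.de_table:
        de_records = expression.read_de_table(config.de_table)
        significant = expression.filter_de(de_records, config.fc_threshold, config.q_threshold)
        bundle["de_significant"] = pd.DataFrame(
            [
                {"locus": r.locus_id, "fold_change": r.fold_change,
                 "q_value": r.q_value, "direction": r.direction}
                for r in significant
            ]
        )
        if clusters:
            summaries = [
                expression.cluster_de_summary(c, significant) for c in clusters
            ]
            bundle["cluster_summaries"] = pd.DataFrame(
                [
                    {"cluster": s.cluster, "n_members": s.n_members, "n_up": s.n_up,
                     "n_down": s.n_down, "pct_up": s.pct_up}
                    for s in summaries
                ]
            )
            if config.total_loci:
                k = sum(
                    1 for r in significant
                    if any(c.contains_locus(r.locus_id) for c in clusters)
                )
                res = expression.enrichment_binomial(
                    k, len(significant),
                    expression.null_cluster_proportion(clusters, config.total_loci),
                )
                bundle["enrichment"] = pd.DataFrame([dataclasses.asdict(res)])

    if config.sites and genes:
        sites = peaks.filter_sites(peaks.read_site_table(config.sites), config.site_q_max)
        annotated = peaks.annotate_sites(
            sites, genes, regions=regions, clusters=clusters, chrom=chrom,
            upstream_window=config.upstream_window,
        )
        annotated = expression.join_sites_expression(annotated, de_records)
        bundle["annotated_sites"] = pd.DataFrame(
            [
                {
                    "start": a.site.start, "end": a.site.end, "width": a.site.width,
                    "q_value": a.site.q_value,
                    "genes": ";".join(f"{l}:{rel}" for l, rel in a.associated_genes),
                    "region": a.region, "clusters": ";".join(a.clusters),
                    "transcription_change": a.transcription_change,
                    "gc_fraction": a.gc_fraction,
                }
                for a in annotated
            ]
        )
        if regions is not None:
            bundle["region_summary"] = peaks.summarize_by_region(annotated).reset_index()

    if config.volatile_matrix and config.volatile_groups:
        matrix = volatiles.AbundanceMatrix.from_tsv(
            config.volatile_matrix, config.volatile_groups
        )
        bundle["volatile_results"] = volatiles.significant_compounds(
            matrix, alpha=config.alpha
        ).reset_index()

    for name, df in bundle.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    manifest = {
        k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
        for k, v in dataclasses.asdict(config).items()
    }
    manifest["sections"] = sorted(bundle)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return bundle
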