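"""Differential-expression filtering and cluster-enrichment statistics.

The reference analysis compares wild-type and silencer-mutant RNA-seq
expression (RPKM), keeps genes with a fold change strictly greater than 4
and an adjusted significance (q) strictly below 0.01, summarizes hits per
specialized metabolic cluster, and asks — with a one-sided binomial test —
whether differentially expressed genes are over-represented inside cluster
locus spans relative to the genome-wide fraction of cluster loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .annotation import ClusterDef, parse_locus_index, read_cluster_table

__all__ = [
    "DERecord",
    "ClusterSummary",
    "EnrichmentResult",
    "rpkm",
    "filter_de",
    "read_de_table",
    "cluster_de_summary",
    "cluster_locus_union",
    "null_cluster_proportion",
    "enrichment_binomial",
    "join_sites_expression",
    "load_reference_cluster_table",
]

logger = logging.getLogger(__name__)

DEFAULT_FC_THRESHOLD = 4.0
DEFAULT_Q_THRESHOLD = 0.01
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class DERecord:
    """Per-gene differential-expression summary.

    ``fold_change`` is mutant/wild-type (pseudocounted when derived from
    expression means), so repression shows as fold_change < 1; the filter
    is symmetric via max(fc, 1/fc).
    """

    locus_id: str
    fold_change: float
    q_value: float
    wt_expr: float | None = None
    mut_expr: float | None = None

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError(f"{self.locus_id}: fold change must be positive")
        if not (0 <= self.q_value <= 1):
            raise ValueError(f"{self.locus_id}: q-value must lie in [0, 1]")

    @property
    def direction(self) -> str:
        return "up" if self.fold_change >= 1 else "down"

    def is_significant(
        self,
        fc_threshold: float = DEFAULT_FC_THRESHOLD,
        q_threshold: float = DEFAULT_Q_THRESHOLD,
    ) -> bool:
        magnitude = max(self.fold_change, 1.0 / self.fold_change)
        return magnitude > fc_threshold and self.q_value < q_threshold


@dataclass(frozen=True)
class ClusterSummary:
    cluster: str
    n_members: int
    n_up: int
    n_down: int

    @property
    def pct_up(self) -> float:
        return round(100.0 * self.n_up / self.n_members, 2)


@dataclass(frozen=True)
class EnrichmentResult:
    k: int
    n: int
    p0: float
    p_value: float


def rpkm(read_count: float, gene_len_nt: float, library_size: float) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_len_nt <= 0 or library_size <= 0:
        raise ValueError("gene length and library size must be positive")
    if read_count < 0:
        raise ValueError("read count must be non-negative")
    return read_count / ((gene_len_nt / 1000.0) * (library_size / 1e6))


def _fold_change(wt: float, mut: float, pseudocount: float) -> float:
    return (mut + pseudocount) / (wt + pseudocount)


def read_de_table(path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[DERecord]:
    """Read a DE table TSV.

    Requires ``locus`` and ``q_value`` columns plus either a ``fold_change``
    column or both ``wt_rpkm`` and ``mut_rpkm`` (fold change then computed
    as (mut+pc)/(wt+pc)). Records lacking both are skipped with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower().strip(): c for c in df.columns}
    if "locus" not in cols or "q_value" not in cols:
        raise ValueError(f"{path}: need 'locus' and 'q_value' columns; found {list(df.columns)}")
    records: list[DERecord] = []
    for _, row in df.iterrows():
        locus = str(row[cols["locus"]])
        q = float(row[cols["q_value"]])
        fc = None
        wt = mut = None
        if "fold_change" in cols and pd.notna(row[cols["fold_change"]]):
            fc = float(row[cols["fold_change"]])
        elif (
            "wt_rpkm" in cols
            and "mut_rpkm" in cols
            and pd.notna(row[cols["wt_rpkm"]])
            and pd.notna(row[cols["mut_rpkm"]])
        ):
            wt = float(row[cols["wt_rpkm"]])
            mut = float(row[cols["mut_rpkm"]])
            fc = _fold_change(wt, mut, pseudocount)
        if fc is None:
            logger.warning("%s: no expression or fold change for %s; record skipped", path, locus)
            continue
        records.append(DERecord(locus_id=locus, fold_change=fc, q_value=q, wt_expr=wt, mut_expr=mut))
    return records


def filter_de(
    records: Iterable[DERecord],
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> list[DERecord]:
    """Significant subset: |fold change| strictly > threshold in either
    direction AND q strictly below threshold. Order preserved; idempotent."""
    return [r for r in records if r.is_significant(fc_threshold, q_threshold)]


def cluster_de_summary(
    cluster: ClusterDef,
    significant: Sequence[DERecord],
    member_mode: str = "span",
    explicit_members: Sequence[str] | None = None,
) -> ClusterSummary:
    """Count significant up/down genes inside one cluster.

    ``member_mode='span'`` counts members as the inclusive locus-index span
    (the cluster table's first-gene-through-last-gene convention);
    ``'explicit'`` uses a caller-supplied membership list, for clusters
    whose published member count differs from the span.
    """
    if member_mode == "span":
        n_members = cluster.n_span_loci
        in_cluster = [r for r in significant if cluster.contains_locus(r.locus_id)]
    elif member_mode == "explicit":
        if not explicit_members:
            raise ValueError("explicit member_mode requires explicit_members")
        member_set = set(explicit_members)
        n_members = len(member_set)
        in_cluster = [r for r in significant if r.locus_id in member_set]
    else:
        raise ValueError(f"unknown member_mode {member_mode!r}")
    if n_members == 0:
        raise ValueError(f"{cluster.name}: empty cluster")
    n_up = sum(1 for r in in_cluster if r.direction == "up")
    n_down = len(in_cluster) - n_up
    return ClusterSummary(cluster=cluster.name, n_members=n_members, n_up=n_up, n_down=n_down)


def cluster_locus_union(clusters: Iterable[ClusterDef]) -> int:
    """Number of distinct locus indices covered by the clusters' spans.

    Overlapping spans (clusters sharing loci) are merged so shared loci
    count once.
    """
    ranges = sorted(c.index_range for c in clusters)
    total = 0
    cur_lo = cur_hi = None
    for lo, hi in ranges:
        if cur_hi is None or lo > cur_hi + 1:
            if cur_hi is not None:
                total += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        total += cur_hi - cur_lo + 1
    return total


def null_cluster_proportion(clusters: Iterable[ClusterDef], total_loci: int) -> float:
    """Genome-wide fraction of loci inside cluster spans (the binomial null)."""
    if total_loci <= 0:
        raise ValueError("total_loci must be positive")
    union = cluster_locus_union(clusters)
    if union > total_loci:
        raise ValueError("cluster span union exceeds the stated locus total")
    return union / total_loci


def enrichment_binomial(k: int, n: int, p0: float) -> EnrichmentResult:
    """Upper-tail binomial probability P(X >= k), X ~ Binomial(n, p0).

    Asks whether k differentially expressed genes landing in cluster spans
    is more than expected if each of the n DE genes independently fell in a
    cluster with probability p0. Evaluated via the regularized incomplete
    beta function (scipy's binomial survival function), which is stable for
    extreme tails.
    """
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0 < p0 < 1):
        raise ValueError("require 0 < p0 < 1")
    p_value = float(stats.binom.sf(k - 1, n, p0))
    return EnrichmentResult(k=k, n=n, p0=p0, p_value=p_value)


def join_sites_expression(annotated_sites, de_records: Iterable[DERecord]):
    """Set ``transcription_change`` on each annotated site.

    A site is associated with a transcriptional change iff any of its
    associated genes is in the significant DE set. Returns new annotation
    objects (input is not mutated).
    """
    significant_loci = {r.locus_id for r in de_records if r.is_significant()}
    out = []
    for ann in annotated_sites:
        changed = any(locus in significant_loci for locus, _ in ann.associated_genes)
        out.append(ann.with_transcription_change(changed))
    return out


def load_reference_cluster_table() -> list[ClusterDef]:
    """The packaged *S. venezuelae* specialized-metabolic-cluster table."""
    with resources.as_file(
        resources.files("lsr2tools.data").joinpath("sven_cluster_table.tsv")
    ) as p:
        return read_cluster_table(p)


def load_reference_cluster_frame() -> pd.DataFrame:
    """The packaged cluster table as a DataFrame (all columns)."""
    with resources.as_file(
        resources.files("lsr2tools.data").joinpath("sven_cluster_table.tsv")
    ) as p:
        return pd.read_csv(p, sep="\t", comment="#")
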