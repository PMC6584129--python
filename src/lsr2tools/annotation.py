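"""Gene models, specialized-metabolic-cluster definitions, and chromosome regions.

Coordinates are 1-based inclusive throughout (GFF convention); BED input is
converted at the boundary. Cluster membership follows the locus-index
convention of antiSMASH-style cluster tables: a cluster is the inclusive
range of locus numbers from its first to its last gene (e.g. SVEN_0223
through SVEN_0234 spans 12 loci), independent of genomic coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd

__all__ = [
    "GeneModel",
    "ClusterDef",
    "ChromosomeRegions",
    "parse_locus_index",
    "read_annotation",
    "write_gff3",
    "read_cluster_table",
    "partition_regions",
    "cluster_members",
]

_LOCUS_RE = re.compile(r"^(?P<prefix>.+?)_?(?P<digits>\d+)$")


def parse_locus_index(locus_id: str) -> tuple[str, int]:
    """Split a prefix_digits locus ID (``SVEN_0223`` -> ``('SVEN', 223)``)."""
    m = _LOCUS_RE.match(locus_id)
    if not m:
        raise ValueError(f"locus ID {locus_id!r} does not follow prefix_digits form")
    return m.group("prefix").rstrip("_"), int(m.group("digits"))


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene interval in 1-based inclusive coordinates."""

    locus_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.locus_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.locus_id}: strand must be + or -")

    @property
    def locus_index(self) -> int:
        return parse_locus_index(self.locus_id)[1]

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ClusterDef:
    """A specialized metabolic gene cluster as an inclusive locus-ID range."""

    name: str
    first_locus: str
    last_locus: str
    product_note: str = ""

    def __post_init__(self) -> None:
        p1, i1 = parse_locus_index(self.first_locus)
        p2, i2 = parse_locus_index(self.last_locus)
        if p1 != p2:
            raise ValueError(f"{self.name}: locus prefixes differ ({p1!r} vs {p2!r})")
        if i1 > i2:
            raise ValueError(f"{self.name}: first locus index exceeds last")

    @property
    def index_range(self) -> tuple[int, int]:
        return (parse_locus_index(self.first_locus)[1], parse_locus_index(self.last_locus)[1])

    @property
    def n_span_loci(self) -> int:
        """Member count as the inclusive locus-index span."""
        lo, hi = self.index_range
        return hi - lo + 1

    def contains_locus(self, locus_id: str) -> bool:
        try:
            prefix, idx = parse_locus_index(locus_id)
        except ValueError:
            return False
        if prefix != parse_locus_index(self.first_locus)[0]:
            return False
        lo, hi = self.index_range
        return lo <= idx <= hi

    def genomic_span(self, genes: Sequence[GeneModel]) -> tuple[int, int]:
        """Hull of member genes' coordinates; requires at least one member."""
        members = [g for g in genes if self.contains_locus(g.locus_id)]
        if not members:
            raise ValueError(f"{self.name}: no member genes found in annotation")
        return min(g.start for g in members), max(g.end for g in members)


@dataclass(frozen=True)
class ChromosomeRegions:
    """Left arm / core / right arm partition of a linear chromosome.

    The three intervals must be contiguous, ordered, non-overlapping, and
    jointly cover [1, chromosome_length].
    """

    left_arm: tuple[int, int]
    core: tuple[int, int]
    right_arm: tuple[int, int]

    def __post_init__(self) -> None:
        ivals = [self.left_arm, self.core, self.right_arm]
        for lo, hi in ivals:
            if lo > hi:
                raise ValueError(f"region interval ({lo}, {hi}) has start > end")
        if ivals[0][0] != 1:
            raise ValueError("left arm must start at coordinate 1")
        for (_, hi), (lo2, _) in zip(ivals, ivals[1:]):
            if lo2 != hi + 1:
                raise ValueError("regions must be contiguous and ordered with no gap or overlap")

    @property
    def chromosome_length(self) -> int:
        return self.right_arm[1]

    def label_of(self, position: int) -> str:
        """Region containing ``position``; boundaries belong to the leftward interval."""
        if not (1 <= position <= self.chromosome_length):
            raise ValueError(f"position {position} outside chromosome [1, {self.chromosome_length}]")
        for label, (lo, hi) in zip(
            ("left_arm", "core", "right_arm"), (self.left_arm, self.core, self.right_arm)
        ):
            if lo <= position <= hi:
                return label
        raise AssertionError("unreachable: partition covers the chromosome")


def read_annotation(path, format: str | None = None) -> list[GeneModel]:
    """Load gene models from GFF3 or BED, sorted by start coordinate.

    ``format`` is inferred from the suffix when omitted. BED intervals
    (0-based half-open) are converted to 1-based inclusive. Duplicate locus
    IDs are rejected.
    """
    path = Path(path)
    fmt = (format or ("BED" if path.suffix.lower() == ".bed" else "GFF3")).upper()
    if fmt == "GFF3":
        genes = _read_gff3(path)
    elif fmt == "BED":
        genes = _read_bed(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    seen: set[str] = set()
    for g in genes:
        if g.locus_id in seen:
            raise ValueError(f"duplicate locus ID {g.locus_id!r} in {path}")
        seen.add(g.locus_id)
    return sorted(genes, key=lambda g: (g.start, g.end))


def _read_gff3(path: Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    genes = []
    for feat in db.features_of_type(("gene", "CDS")):
        locus = (
            feat.attributes.get("locus_tag", [None])[0]
            or feat.attributes.get("ID", [None])[0]
            or feat.attributes.get("Name", [None])[0]
        )
        if locus is None:
            raise ValueError(f"{path}: feature at {feat.start}-{feat.end} lacks an ID/locus_tag")
        genes.append(GeneModel(locus_id=locus, start=feat.start, end=feat.end, strand=feat.strand))
    return genes


def _read_bed(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED line needs >=6 fields for stranded genes")
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end0 <= start0:
                raise ValueError(f"{path}:{lineno}: end <= start")
            genes.append(
                GeneModel(locus_id=fields[3], start=start0 + 1, end=end0, strand=fields[5])
            )
    return genes


def write_gff3(genes: Iterable[GeneModel], path, seqid: str = "chromosome") -> None:
    """Write gene models as GFF3 ``gene`` features (exact round-trip of coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{seqid}\tlsr2tools\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.locus_id};locus_tag={g.locus_id}\n"
            )


def read_cluster_table(path) -> list[ClusterDef]:
    """Read a cluster table TSV with columns ``name``, ``first_locus``, ``last_locus``.

    A ``product`` column, when present, populates ``product_note``. Extra
    columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = {c.lower().strip(): c for c in df.columns}
    required = ["name", "first_locus", "last_locus"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    clusters = []
    for _, row in df.iterrows():
        clusters.append(
            ClusterDef(
                name=str(row[cols["name"]]),
                first_locus=str(row[cols["first_locus"]]).strip(),
                last_locus=str(row[cols["last_locus"]]).strip(),
                product_note=str(row[cols["product"]]) if "product" in cols else "",
            )
        )
    return clusters


def cluster_members(
    cluster: ClusterDef,
    de_loci: Iterable[str],
) -> list[str]:
    """Subset of ``de_loci`` falling in the cluster's locus-index range."""
    return [locus for locus in de_loci if cluster.contains_locus(locus)]


def partition_regions(
    boundaries: dict | Sequence[tuple[int, int]],
) -> ChromosomeRegions:
    """Build a validated left-arm/core/right-arm partition.

    ``boundaries`` is either a mapping with keys ``left_arm``, ``core``,
    ``right_arm`` (each a (start, end) pair) or a sequence of the three
    pairs in left-to-right order. Boundaries are user-supplied: arm/core
    limits are a published chromosome-biology annotation, not derivable
    from sequence alone.
    """
    if isinstance(boundaries, dict):
        try:
            ivals = [tuple(boundaries[k]) for k in ("left_arm", "core", "right_arm")]
        except KeyError as exc:
            raise ValueError(f"missing region key: {exc}") from exc
    else:
        ivals = [tuple(b) for b in boundaries]
        if len(ivals) != 3:
            raise ValueError("need exactly three region intervals")
    return ChromosomeRegions(left_arm=ivals[0], core=ivals[1], right_arm=ivals[2])
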