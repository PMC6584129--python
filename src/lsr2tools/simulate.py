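"""Synthetic genomes, annotations, binding sites, DE tables, and volatile matrices.

Every pipeline stage is testable without downloads against data whose
ground truth is planted and recorded. The generators emulate the
statistical structure of a high-GC *Streptomyces* chromosome under
xenogeneic silencing:

* background composition ~72.4% GC with embedded AT-rich islands (the
  compositional signature of silencer binding sites);
* non-overlapping genes with consecutive locus numbering, specialized
  metabolic clusters as consecutive locus blocks, and a left-arm/core/
  right-arm chromosome partition;
* differential expression planted per-gene Bernoulli at ~15% inside
  clusters vs ~4% outside, with planted genes given fold change > 4 and
  q < 0.01 and all others sub-threshold, so the planted set is exactly
  what the DE filter recovers;
* one binding site per island (jittered bounds, q below threshold) plus
  uniform noise sites;
* log-normal volatile intensities with a subset of compounds shifted by a
  chosen number of standard deviations in one group.

Composition is i.i.d. within background and islands — real genomes are
more heterogeneous, which is why genome-baseline window counts are
property-level rather than value-level reproductions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import ChromosomeRegions, ClusterDef, GeneModel
from .peaks import BindingSite
from .sequence import NucSequence
from .volatiles import AbundanceMatrix

__all__ = [
    "IslandSpec",
    "SyntheticTruth",
    "simulate_chromosome",
    "simulate_annotation",
    "simulate_de",
    "simulate_sites",
    "simulate_volatiles",
    "default_scene",
]

BACKGROUND_GC = 0.724
P_DE_CLUSTER = 0.15
P_DE_BACKGROUND = 0.04
# Stamped into each guaranteed-core island: 6 nt, all A/T.
_CORE_STAMP = "AATATT"


@dataclass(frozen=True)
class IslandSpec:
    """A planted AT-rich island: (1-based start, length, AT fraction)."""

    start: int
    length: int
    at_fraction: float
    guaranteed_core: bool = True

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class SyntheticTruth:
    """Planted ground truth, filled in by whichever generators ran."""

    islands: list[IslandSpec] = field(default_factory=list)
    cluster_members: dict[str, list[str]] = field(default_factory=dict)
    de_genes: dict[str, str] = field(default_factory=dict)  # locus -> 'up'|'down'
    shifted_compounds: dict[str, str] = field(default_factory=dict)  # compound -> group
    site_island_index: list[int | None] = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        d["islands"] = [asdict(i) for i in self.islands]
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["islands"] = [IslandSpec(**i) for i in d["islands"]]
        return cls(**d)


def _draw_bases(rng: np.random.Generator, n: int, p_gc: float) -> np.ndarray:
    """i.i.d. bases with P(G or C) = p_gc, G/C and A/T equiprobable within pair."""
    probs = [p_gc / 2, p_gc / 2, (1 - p_gc) / 2, (1 - p_gc) / 2]
    return rng.choice(np.frombuffer(b"GCAT", dtype="S1"), size=n, p=probs)


def simulate_chromosome(
    length: int,
    background_gc: float = BACKGROUND_GC,
    islands: Sequence[tuple[int, int, float]] | Sequence[IslandSpec] = (),
    seed: int = 0,
    guaranteed_core: bool = True,
) -> tuple[NucSequence, SyntheticTruth]:
    """A chromosome of i.i.d. background composition with planted AT islands.

    ``islands`` are (start, length, at_fraction) triples in 1-based
    coordinates (or IslandSpec objects); they must fit inside the
    chromosome and not overlap. When ``guaranteed_core`` is set, a 6-nt
    all-A/T stamp is written at each island's centre so every island is
    certain to carry an AT-rich core.
    """
    specs = [
        i if isinstance(i, IslandSpec) else IslandSpec(i[0], i[1], i[2], guaranteed_core)
        for i in islands
    ]
    for spec in specs:
        if not (1 <= spec.start and spec.end <= length):
            raise ValueError(f"island {spec} does not fit in chromosome of length {length}")
    for a, b in zip(sorted(specs, key=lambda s: s.start), sorted(specs, key=lambda s: s.start)[1:]):
        if b.start <= a.end:
            raise ValueError(f"islands overlap: {a} and {b}")

    rng = np.random.default_rng(seed)
    bases = _draw_bases(rng, length, background_gc)
    for spec in specs:
        bases[spec.start - 1 : spec.end] = _draw_bases(rng, spec.length, 1 - spec.at_fraction)
        if spec.guaranteed_core and spec.length >= len(_CORE_STAMP):
            mid = spec.start - 1 + (spec.length - len(_CORE_STAMP)) // 2
            bases[mid : mid + len(_CORE_STAMP)] = np.frombuffer(
                _CORE_STAMP.encode(), dtype="S1"
            )
    seq = NucSequence("synthetic_chromosome", bases.tobytes().decode())
    return seq, SyntheticTruth(islands=specs)


def simulate_annotation(
    chrom_length: int,
    n_genes: int,
    mean_gene_len: int = 850,
    n_clusters: int = 25,
    genes_per_cluster: int = 40,
    seed: int = 0,
    locus_prefix: str = "SYN",
) -> tuple[list[GeneModel], list[ClusterDef], ChromosomeRegions, SyntheticTruth]:
    """Non-overlapping genes with consecutive locus numbering plus clusters.

    Gene lengths are drawn around ``mean_gene_len`` and genes are packed
    left to right with small random intergenic gaps, so locus numbering is
    strictly increasing with coordinate. Clusters are ``n_clusters``
    disjoint blocks of ``genes_per_cluster`` consecutive loci at random
    offsets. The chromosome is partitioned into left arm (first quarter),
    core (middle half) and right arm (last quarter).
    """
    if n_clusters * genes_per_cluster > n_genes:
        raise ValueError("more cluster genes requested than genes")
    rng = np.random.default_rng(seed)
    lengths = np.maximum(90, rng.normal(mean_gene_len, mean_gene_len / 4, n_genes).astype(int))
    gaps = rng.integers(20, 200, n_genes)
    footprint = int(lengths.sum() + gaps.sum())
    if footprint > chrom_length:
        raise ValueError(
            f"cannot pack {n_genes} genes (footprint {footprint}) into {chrom_length} nt"
        )
    # Stretch gaps uniformly to spread genes over the whole chromosome.
    slack = chrom_length - footprint
    extra = rng.multinomial(slack, np.ones(n_genes) / n_genes)
    width = len(str(n_genes))
    genes: list[GeneModel] = []
    pos = 1
    for i in range(n_genes):
        pos += int(gaps[i] + extra[i])
        start = pos
        end = start + int(lengths[i]) - 1
        genes.append(
            GeneModel(
                locus_id=f"{locus_prefix}_{i + 1:0{max(width, 4)}d}",
                start=start,
                end=end,
                strand="+" if rng.integers(2) else "-",
            )
        )
        pos = end + 1

    # Clusters: disjoint blocks of consecutive locus indices.
    block = genes_per_cluster
    n_slots = n_genes // block
    if n_clusters > n_slots:
        raise ValueError("cannot place that many disjoint clusters")
    slots = rng.choice(n_slots, size=n_clusters, replace=False)
    clusters, members = [], {}
    for j, slot in enumerate(sorted(slots)):
        first = int(slot) * block
        name = f"cluster_{j + 1:02d}"
        clusters.append(
            ClusterDef(
                name=name,
                first_locus=genes[first].locus_id,
                last_locus=genes[first + block - 1].locus_id,
            )
        )
        members[name] = [g.locus_id for g in genes[first : first + block]]

    q1, q3 = chrom_length // 4, 3 * chrom_length // 4
    regions = ChromosomeRegions(
        left_arm=(1, q1), core=(q1 + 1, q3), right_arm=(q3 + 1, chrom_length)
    )
    return genes, clusters, regions, SyntheticTruth(cluster_members=members)


def simulate_de(
    genes: Sequence[GeneModel],
    clusters: Sequence[ClusterDef],
    p_cluster: float = P_DE_CLUSTER,
    p_background: float = P_DE_BACKGROUND,
    p_up: float = 0.9,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """A DE table with cluster-enriched planted significance.

    Each gene is independently planted significant with probability
    ``p_cluster`` if any cluster's locus range contains it, else
    ``p_background``. Planted genes get fold change drawn log-uniform in
    (4.5, 900) (inverted for the 'down' fraction) and q log-uniform in
    (1e-6, 0.01); all others get sub-threshold fold changes and/or large
    q-values, so the DE filter returns exactly the planted set.
    """
    rng = np.random.default_rng(seed)
    from .annotation import parse_locus_index

    ranges = [c.index_range for c in clusters]
    prefixes = {parse_locus_index(c.first_locus)[0] for c in clusters}
    rows, truth = [], SyntheticTruth()
    for g in genes:
        prefix, idx = parse_locus_index(g.locus_id)
        hit = prefix in prefixes and any(lo <= idx <= hi for lo, hi in ranges)
        p = p_cluster if hit else p_background
        planted = rng.random() < p
        if planted:
            fc = 10 ** rng.uniform(np.log10(4.5), np.log10(900))
            direction = "up" if rng.random() < p_up else "down"
            if direction == "down":
                fc = 1.0 / fc
            q = 10 ** rng.uniform(-6, np.log10(0.01)) * 0.999
            truth.de_genes[g.locus_id] = direction
        else:
            fc = 10 ** rng.uniform(np.log10(0.3), np.log10(3.3))
            q = rng.uniform(0.02, 1.0)
        wt = 10 ** rng.uniform(0, 2)
        rows.append(
            {
                "locus": g.locus_id,
                "wt_rpkm": round(wt, 3),
                "mut_rpkm": round(wt * fc, 3),
                "fold_change": fc,
                "q_value": q,
            }
        )
    return pd.DataFrame(rows), truth


def simulate_sites(
    islands: Sequence[IslandSpec],
    chrom_length: int,
    n_noise_sites: int = 0,
    seed: int = 0,
    q_max: float = 0.01,
) -> tuple[list[BindingSite], SyntheticTruth]:
    """One significant binding site per island plus uniform noise sites.

    Island sites have bounds jittered by up to 10% of the island length
    (always still overlapping the island) and q below ``q_max``; noise
    sites are uniform random intervals with q uniform in [0, 1). The truth
    records each site's source island index (None for noise).
    """
    rng = np.random.default_rng(seed)
    sites: list[BindingSite] = []
    origin: list[int | None] = []
    for idx, isl in enumerate(islands):
        jitter = max(1, isl.length // 10)
        start = max(1, isl.start + int(rng.integers(-jitter, jitter + 1)))
        end = min(chrom_length, isl.end + int(rng.integers(-jitter, jitter + 1)))
        end = max(end, start + 1)
        sites.append(BindingSite(start=start, end=end, q_value=float(rng.uniform(0, q_max * 0.9))))
        origin.append(idx)
    for _ in range(n_noise_sites):
        width = int(rng.integers(100, 1000))
        start = int(rng.integers(1, max(2, chrom_length - width)))
        sites.append(
            BindingSite(start=start, end=start + width - 1, q_value=float(rng.uniform(0, 1)))
        )
        origin.append(None)
    return sites, SyntheticTruth(islands=list(islands), site_island_index=origin)


def simulate_volatiles(
    n_compounds: int = 200,
    n_per_group: int = 6,
    n_shifted: int = 10,
    shift_sd: float = 3.0,
    seed: int = 0,
    groups: tuple[str, str, str] = ("WT", "mutant", "medium"),
) -> tuple[AbundanceMatrix, SyntheticTruth]:
    """Log-normal volatile intensity matrix with planted group shifts.

    Per compound, log10 intensity is Normal(mu, sigma) with mu ~ U(4, 7)
    and sigma = 0.25 in every group. The first ``n_shifted`` compounds (in
    a seeded random order) are displaced by ``shift_sd``·sigma in one of
    the two tested groups (alternating, emulating compounds higher in
    either strain). A sterile-medium group is included at a lower
    baseline for display, as in the reference heatmap.
    """
    rng = np.random.default_rng(seed)
    g_a, g_b, g_medium = groups
    sigma = 0.25
    compounds = [f"compound_{i + 1:04d}" for i in range(n_compounds)]
    shifted_idx = rng.choice(n_compounds, size=n_shifted, replace=False)
    truth = SyntheticTruth()
    samples = (
        [f"{g_a}_{j + 1}" for j in range(n_per_group)]
        + [f"{g_b}_{j + 1}" for j in range(n_per_group)]
        + [f"{g_medium}_{j + 1}" for j in range(n_per_group)]
    )
    data = np.empty((n_compounds, len(samples)))
    for i in range(n_compounds):
        mu = rng.uniform(4, 7)
        mu_a = mu_b = mu
        if i in shifted_idx:
            target = g_a if (i % 2 == 0) else g_b
            if target == g_a:
                mu_a = mu + shift_sd * sigma
            else:
                mu_b = mu + shift_sd * sigma
            truth.shifted_compounds[compounds[i]] = target
        row = np.concatenate(
            [
                rng.normal(mu_a, sigma, n_per_group),
                rng.normal(mu_b, sigma, n_per_group),
                rng.normal(mu - 1.5, sigma, n_per_group),
            ]
        )
        data[i] = 10**row
    matrix = AbundanceMatrix(
        data=pd.DataFrame(data, index=compounds, columns=samples),
        groups={s: s.rsplit("_", 1)[0] for s in samples},
    )
    return matrix, truth


def default_scene(seed: int = 0, scale: float = 1.0) -> dict:
    """The default synthetic study scene, sized to the reference magnitudes.

    At ``scale=1``: an 8 Mb chromosome carrying 8 000 loci of which ~1 000
    sit in 25 specialized clusters of 40 genes, ~220 AT-rich islands each
    carrying a binding site, plus noise sites, a DE table with 15%/4%
    planted rates, and a 200-compound volatile matrix. ``scale`` shrinks
    the genome-sized components proportionally for quick runs.
    """
    rng = np.random.default_rng(seed)
    n_genes = max(200, int(8000 * scale))
    # floors keep small-scale scenes packable
    chrom_length = max(int(8_000_000 * scale), n_genes * 1300)
    n_clusters = max(2, int(25 * scale))
    n_islands = max(10, int(220 * scale))

    # Non-overlapping islands on a coarse grid, then jittered.
    grid = np.sort(rng.choice(chrom_length // 2000 - 1, size=n_islands, replace=False))
    islands = [
        IslandSpec(start=int(g) * 2000 + 1, length=int(rng.integers(200, 800)), at_fraction=0.55)
        for g in grid
    ]
    chrom, chrom_truth = simulate_chromosome(
        chrom_length, islands=islands, seed=int(rng.integers(2**31))
    )
    genes, clusters, regions, ann_truth = simulate_annotation(
        chrom_length, n_genes, n_clusters=n_clusters, seed=int(rng.integers(2**31))
    )
    de_table, de_truth = simulate_de(genes, clusters, seed=int(rng.integers(2**31)))
    sites, site_truth = simulate_sites(
        islands, chrom_length, n_noise_sites=max(5, n_islands // 10), seed=int(rng.integers(2**31))
    )
    volatiles, vol_truth = simulate_volatiles(seed=int(rng.integers(2**31)))
    truth = SyntheticTruth(
        islands=chrom_truth.islands,
        cluster_members=ann_truth.cluster_members,
        de_genes=de_truth.de_genes,
        shifted_compounds=vol_truth.shifted_compounds,
        site_island_index=site_truth.site_island_index,
    )
    return {
        "chromosome": chrom,
        "genes": genes,
        "clusters": clusters,
        "regions": regions,
        "de_table": de_table,
        "sites": sites,
        "volatiles": volatiles,
        "truth": truth,
    }
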