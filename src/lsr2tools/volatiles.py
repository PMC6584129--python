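"""Volatile-metabolome differential statistics.

Relative compound abundances (total-ion-chromatogram intensities from
headspace GC×GC-TOFMS) are log10-transformed, mean-centered and unit-scaled
per compound; each compound is then compared between two sample groups
(wild type vs silencer mutant) with a two-sided Mann–Whitney U-test, p-values
are Benjamini–Hochberg adjusted, and compounds with adjusted p below alpha
are reported with the direction of their median shift. Sterile-medium
samples are carried along for display but excluded from testing.

The Mann–Whitney test is rank-based, so the per-compound monotone transform
does not change its p-values; testing is performed on the raw intensities
and the transformed matrix is what a heatmap of the results would show.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AbundanceMatrix",
    "preprocess",
    "mwu_test",
    "bh_adjust",
    "significant_compounds",
]

EXACT_MAX_COMBINED_N = 12


@dataclass(frozen=True)
class AbundanceMatrix:
    """Compounds × samples intensity matrix with per-sample group labels.

    ``data`` has compounds as the index and sample IDs as columns;
    ``groups`` maps each sample ID to a label such as ``WT``, ``mutant`` or
    ``medium``. Intensities must be non-negative.
    """

    data: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        missing = [c for c in self.data.columns if c not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        if (self.data.values < 0).any():
            raise ValueError("intensities must be non-negative")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.data.columns if self.groups[s] == group]

    @classmethod
    def from_tsv(cls, matrix_path, groups_path) -> "AbundanceMatrix":
        """Load from a matrix TSV (first column = compound id) and a
        two-column sample→group map TSV."""
        data = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
        gmap = pd.read_csv(groups_path, sep="\t", comment="#")
        groups = dict(zip(gmap.iloc[:, 0].astype(str), gmap.iloc[:, 1].astype(str)))
        return cls(data=data, groups=groups)


def _impute_zeros(row: np.ndarray) -> np.ndarray:
    """Replace zeros with half the smallest positive value of the compound."""
    positive = row[row > 0]
    if positive.size == 0:
        return row
    return np.where(row == 0, positive.min() / 2.0, row)


def preprocess(matrix: AbundanceMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Per-compound log10 / mean-center / unit-scale.

    Returns the transformed matrix (rows have mean 0 and population sd 1)
    and the list
    of compounds excluded because they have zero variance or fewer than two
    finite values after transformation. Zero intensities are imputed as
    half the compound's smallest positive value before the log.
    """
    transformed = {}
    excluded: list[str] = []
    for compound, row in matrix.data.iterrows():
        vals = _impute_zeros(row.to_numpy(dtype=float))
        with np.errstate(divide="ignore"):
            logs = np.log10(vals)
        finite = np.isfinite(logs)
        if finite.sum() < 2:
            excluded.append(compound)
            continue
        sd = np.nanstd(logs[finite], ddof=0)
        if sd == 0:
            excluded.append(compound)
            continue
        transformed[compound] = (logs - np.nanmean(logs[finite])) / sd
    out = pd.DataFrame.from_dict(transformed, orient="index", columns=matrix.data.columns)
    return out, excluded


def mwu_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U-test: returns (U of group_a, p).

    Uses the exact null distribution when the combined sample size is at
    most 12 and there are no ties; otherwise the normal approximation with
    continuity and tie corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= EXACT_MAX_COMBINED_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_compounds(
    matrix: AbundanceMatrix,
    group_a: str = "WT",
    group_b: str = "mutant",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full differential pipeline between two sample groups.

    Returns a DataFrame indexed by compound with columns ``U``, ``p_raw``,
    ``p_adj``, ``significant`` and ``direction`` (``higher_in_<group>`` by
    comparing group medians of the raw intensities). Other groups (e.g.
    sterile medium) are ignored by the test. Zero-variance compounds are
    excluded before testing.
    """
    samples_a = matrix.samples_in(group_a)
    samples_b = matrix.samples_in(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need at least two samples per tested group")
    _, excluded = preprocess(matrix)
    testable = [c for c in matrix.data.index if c not in set(excluded)]
    rows = []
    for compound in testable:
        a = matrix.data.loc[compound, samples_a].to_numpy(dtype=float)
        b = matrix.data.loc[compound, samples_b].to_numpy(dtype=float)
        u, p = mwu_test(a, b)
        med_a, med_b = np.median(a), np.median(b)
        if med_a > med_b:
            direction = f"higher_in_{group_a}"
        elif med_b > med_a:
            direction = f"higher_in_{group_b}"
        else:
            direction = "none"
        rows.append({"compound": compound, "U": u, "p_raw": p, "direction": direction})
    res = pd.DataFrame(rows).set_index("compound")
    res["p_adj"] = bh_adjust(res["p_raw"].to_numpy()) if len(res) else []
    res["significant"] = res["p_adj"] < alpha
    return res
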