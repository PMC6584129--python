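"""Volatile-metabolome pipeline: transform, rank test, BH correction, selection."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from lsr2tools.simulate import simulate_volatiles
from lsr2tools.volatiles import (
    AbundanceMatrix,
    bh_adjust,
    mwu_test,
    preprocess,
    significant_compounds,
)


def exact_mwu_two_sided(a, b):
    """Enumeration oracle: two-sided p over all rank assignments (no ties)."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    na = len(a)
    n_total = na * len(b)

    def u_of(idx_a):
        set_a = set(idx_a)
        u = 0
        for i in set_a:
            u += sum(1 for j in range(len(pooled)) if j not in set_a and pooled[i] > pooled[j])
        return u

    observed = sum(1 for x in a for y in b if x > y)
    lo, hi = min(observed, n_total - observed), max(observed, n_total - observed)
    count = 0
    for idx_a in combinations(range(len(pooled)), na):
        u = u_of(idx_a)
        if u <= lo or u >= hi:
            count += 1
    return count / comb(len(pooled), na)


class TestMWU:
    def test_identical_groups_give_p_near_one(self):
        _, p = mwu_test([1, 2, 3], [1, 2, 3])
        assert p > 0.9

    def test_fully_separated_exact_p(self):
        u, p = mwu_test([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(2 / comb(6, 3))  # 0.1

    def test_u_identity(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=7)
        ua, _ = mwu_test(a, b)
        ub, _ = mwu_test(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_exact_branch_matches_enumeration(self, rng):
        for na, nb in [(2, 3), (3, 3), (4, 4), (3, 6), (5, 5)]:
            vals = rng.permutation(np.arange(1.0, na + nb + 1))
            a, b = vals[:na], vals[na:] + 0.5 * rng.random(nb)
            a, b = list(a), list(b)
            if len(set(a + b)) < na + nb:
                continue
            _, p = mwu_test(a, b)
            assert p == pytest.approx(exact_mwu_two_sided(a, b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mwu_test([], [1.0])


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(0, 1, 50)
        assert (bh_adjust(p) >= p).all()

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(0, 1, 40)
        perm = rng.permutation(40)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))

    def test_selection_idempotent(self, rng):
        p = rng.uniform(0, 0.2, 30)
        adj = bh_adjust(p)
        selected = adj < 0.05
        re_adj = bh_adjust(adj)
        assert ((re_adj < 0.05) == selected).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestPreprocess:
    def _matrix(self, rows, groups=None):
        df = pd.DataFrame(rows).T
        df.columns = [f"s{i}" for i in range(df.shape[1])]
        return AbundanceMatrix(df, groups or {c: "WT" for c in df.columns})

    def test_closed_form_example(self):
        m = self._matrix({"c1": [10.0, 100.0, 1000.0]})
        out, excluded = preprocess(m)
        assert excluded == []
        assert out.loc["c1"].to_numpy() == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    def test_constant_compound_excluded(self):
        m = self._matrix({"c1": [5.0, 5.0, 5.0], "c2": [1.0, 2.0, 4.0]})
        out, excluded = preprocess(m)
        assert excluded == ["c1"] and list(out.index) == ["c2"]

    def test_rows_standardized(self, rng):
        m = self._matrix({f"c{i}": 10 ** rng.uniform(2, 6, 8) for i in range(5)})
        out, _ = preprocess(m)
        assert out.mean(axis=1).to_numpy() == pytest.approx(np.zeros(5), abs=1e-12)
        assert out.std(axis=1, ddof=0).to_numpy() == pytest.approx(np.ones(5))

    def test_zeros_imputed_as_half_minimum(self):
        m = self._matrix({"c1": [0.0, 10.0, 1000.0]})
        out, excluded = preprocess(m)
        assert excluded == []  # zero replaced by 5.0 before the log

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError):
            self._matrix({"c1": [-1.0, 2.0, 3.0]})


class TestSignificantCompounds:
    def test_planted_shift_recovery(self):
        matrix, truth = simulate_volatiles(
            n_compounds=200, n_per_group=6, n_shifted=10, shift_sd=3, seed=0
        )
        res = significant_compounds(matrix)
        hits = set(res.index[res["significant"]])
        planted = set(truth.shifted_compounds)
        assert len(hits & planted) >= 8
        assert len(hits - planted) <= 10  # false positives stay modest

    def test_direction_matches_planted_group(self):
        matrix, truth = simulate_volatiles(n_shifted=10, shift_sd=3, seed=0)
        res = significant_compounds(matrix)
        for compound in set(res.index[res["significant"]]) & set(truth.shifted_compounds):
            assert res.loc[compound, "direction"] == f"higher_in_{truth.shifted_compounds[compound]}"

    def test_null_yields_few_selections(self):
        matrix, _ = simulate_volatiles(n_compounds=150, n_shifted=0, seed=3)
        res = significant_compounds(matrix)
        assert res["significant"].sum() <= 0.05 * 150

    def test_alpha_zero_selects_nothing(self):
        matrix, _ = simulate_volatiles(n_compounds=50, n_shifted=5, seed=1)
        res = significant_compounds(matrix, alpha=0.0)
        assert res["significant"].sum() == 0

    def test_invariant_to_per_compound_scaling(self):
        matrix, _ = simulate_volatiles(n_compounds=40, n_shifted=4, seed=5)
        scaled = AbundanceMatrix(
            matrix.data.mul(
                pd.Series(np.linspace(0.1, 50, 40), index=matrix.data.index), axis=0
            ),
            matrix.groups,
        )
        a = significant_compounds(matrix)
        b = significant_compounds(scaled)
        assert a["p_raw"].to_numpy() == pytest.approx(b["p_raw"].to_numpy())
        assert (a["significant"] == b["significant"]).all()

    def test_medium_group_not_tested(self):
        matrix, _ = simulate_volatiles(n_compounds=20, n_shifted=0, seed=2)
        res = significant_compounds(matrix)
        # only WT and mutant samples feed the U statistic: U <= 6*6
        assert (res["U"] <= 36).all()
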