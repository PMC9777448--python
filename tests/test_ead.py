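"""EAD reference regression, residuals and group/intervention comparisons."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from epiclock.ead import (
    compare_groups,
    compute_ead,
    fit_ead_reference,
    intervention_delta,
)


def enumerated_ranksum_p(a, b):
    """Independent oracle: two-sided rank-sum p by counting pairwise wins over
    every assignment of the pooled values to a group of size len(a)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    na, n = a.size, a.size + b.size

    def u_stat(group_idx):
        ga = pooled[list(group_idx)]
        gb = pooled[[i for i in range(n) if i not in set(group_idx)]]
        wins = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in ga for y in gb)
        return wins

    center = na * (n - na) / 2.0
    dev_obs = abs(u_stat(range(na)) - center)
    hits, total = 0, 0
    for idx in combinations(range(n), na):
        if abs(u_stat(idx) - center) >= dev_obs - 1e-9:
            hits += 1
        total += 1
    return hits / total


class TestReference:
    def test_identity_line(self):
        ref = fit_ead_reference([20, 40, 60, 80], [20, 40, 60, 80])
        assert ref.slope_ == pytest.approx(1.0)
        assert ref.intercept_ == pytest.approx(0.0, abs=1e-12)

    def test_known_line(self):
        chrono = np.array([20.0, 40, 60, 80])
        ref = fit_ead_reference(0.8 * chrono + 10, chrono)
        assert ref.slope_ == pytest.approx(0.8)
        assert ref.intercept_ == pytest.approx(10.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        chrono = rng.uniform(20, 80, 100)
        pred = 0.9 * chrono + 5 + rng.normal(0, 4, 100)
        ref = fit_ead_reference(pred, chrono)
        X = np.column_stack([np.ones(100), chrono])
        beta = np.linalg.solve(X.T @ X, X.T @ pred)
        assert ref.intercept_ == pytest.approx(beta[0], abs=1e-10)
        assert ref.slope_ == pytest.approx(beta[1], abs=1e-10)

    def test_degenerate_chrono(self):
        with pytest.raises(ValueError):
            fit_ead_reference([30, 40, 50], [60, 60, 60])


class TestComputeEAD:
    def test_on_line_and_offset(self):
        ref = fit_ead_reference([20.0, 40, 60, 80], [20.0, 40, 60, 80])
        tab = compute_ead(
            ref,
            pd.Series([50.0, 55.0], index=["a", "b"]),
            pd.Series([50.0, 50.0], index=["a", "b"]),
        )
        assert tab.loc["a", "ead"] == pytest.approx(0.0, abs=1e-12)
        assert tab.loc["b", "ead"] == pytest.approx(5.0)

    def test_mean_over_reference_samples_is_zero(self):
        rng = np.random.default_rng(3)
        chrono = rng.uniform(20, 80, 200)
        pred = chrono + rng.normal(0, 6, 200)
        ref = fit_ead_reference(pred, chrono)
        ead = ref.residuals(chrono, pred)
        assert abs(ead.mean()) < 1e-9

    def test_equivariance_under_constant_shift(self):
        rng = np.random.default_rng(4)
        chrono = rng.uniform(20, 80, 50)
        pred = chrono + rng.normal(0, 5, 50)
        base = fit_ead_reference(pred, chrono).residuals(chrono, pred)
        # shifting epigenetic ages before fitting leaves residuals unchanged
        shifted = fit_ead_reference(pred + 7, chrono).residuals(chrono, pred + 7)
        np.testing.assert_allclose(shifted, base, atol=1e-9)
        # shifting after fitting moves every residual by the shift
        after = fit_ead_reference(pred, chrono).residuals(chrono, pred + 7)
        np.testing.assert_allclose(after, base + 7, atol=1e-9)


class TestCompareGroups:
    def test_exact_separated_groups(self):
        res = compare_groups([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        res = compare_groups([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)
        assert res.statistic == pytest.approx(4.5)  # U at its null center

    @pytest.mark.parametrize("na,nb", [(2, 2), (2, 5), (3, 3), (4, 4), (3, 7), (5, 5)])
    def test_exact_matches_enumeration(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        # integer values force ties, exercising the midrank path
        a = rng.integers(0, 6, size=na).astype(float)
        b = rng.integers(0, 6, size=nb).astype(float)
        res = compare_groups(a, b)
        assert res.p_value == pytest.approx(enumerated_ranksum_p(a, b), abs=1e-12)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 40)
        b = rng.normal(1, 1, 40)
        res = compare_groups(a, b)
        assert 0 < res.p_value < 0.01

    def test_welch(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 30)
        b = rng.normal(2, 3, 25)
        res = compare_groups(a, b, test="welch_t")
        assert res.p_value < 0.01
        assert res.statistic < 0

    def test_paired_direction(self):
        a = np.full(10, -0.5)
        a[0] = -0.4
        b = np.zeros(10)
        res = compare_groups(a, b, test="paired_t")
        assert res.statistic < 0
        assert res.mean_a - res.mean_b < 0

    def test_paired_zero_variance_degenerate(self):
        res = compare_groups([1.0, 2.0, 3.0], [0.0, 1.0, 2.0], test="paired_t")
        assert res.degenerate
        assert np.isnan(res.p_value)

    def test_paired_length_mismatch(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3], [1, 2], test="paired_t")


class TestInterventionDelta:
    def test_no_change(self):
        e = pd.Series([1.0, -2.0, 0.5], index=["a", "b", "c"])
        res = intervention_delta(e, e.copy())
        assert res["mean_delta"] == 0.0

    def test_constant_shift_recovered(self):
        e0 = pd.Series([1.0, -2.0, 0.5, 3.0], index=list("abcd"))
        res = intervention_delta(e0, e0 - 0.58)
        assert res["mean_delta"] == pytest.approx(-0.58)

    def test_exactly_constant_differences_are_degenerate(self):
        # -0.5 is exactly representable, so every difference is identical
        e0 = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        res = intervention_delta(e0, e0 - 0.5)
        assert res["mean_delta"] == -0.5
        assert res["paired_t"].degenerate

    def test_symmetric_deltas(self):
        e0 = pd.Series([0.0, 0.0, 0.0], index=list("abc"))
        e1 = pd.Series([-1.0, 0.0, 1.0], index=list("abc"))
        res = intervention_delta(e0, e1)
        assert res["mean_delta"] == pytest.approx(0.0)
        assert res["paired_t"].statistic == pytest.approx(0.0, abs=1e-12)

    def test_incomplete_subjects_dropped(self):
        e0 = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        e1 = pd.Series([1.5, 2.5, 9.0], index=["a", "b", "d"])
        res = intervention_delta(e0, e1)
        assert res["n_pairs"] == 2
        assert res["dropped"] == ["c", "d"]

    def test_no_pairs_raises(self):
        with pytest.raises(ValueError):
            intervention_delta(
                pd.Series([1.0], index=["a"]), pd.Series([2.0], index=["b"])
            )
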