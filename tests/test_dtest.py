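"""Max-type statistics, Gumbel calibration, and competing tests."""

import math

import numpy as np
import pytest

from mecaf import dtest, simulate
from mecaf.dtest import (
    DegenerateVarianceError,
    gumbel_quantile,
    mec_statistic,
    mec_test,
    mec_variant_test,
    mecaf_statistic,
    mecaf_test,
    null_calibration,
)

TOY_X1 = np.array([[1.0, -1.0], [-1.0, 1.0]])
TOY_X2 = np.array([[2.0, -2.0], [0.0, 0.0]])


class TestMecafStatistic:
    def test_zero_for_identical_groups(self, rng):
        X = rng.standard_normal((5, 6))
        X -= X.mean(axis=1, keepdims=True)
        stat, comps = mecaf_statistic(X, X.copy())
        assert stat == 0.0
        np.testing.assert_array_equal(comps, 0.0)

    def test_hand_computed_toy(self):
        # group means 0 vs 1, per-group 1/n variances both 1, sigma_jj = 4
        stat, comps = mecaf_statistic(TOY_X1, TOY_X2)
        assert stat == pytest.approx(1.0, abs=1e-14)
        np.testing.assert_allclose(comps, [1.0])

    def test_max_over_all_diagnostic(self):
        stat, comps = mecaf_statistic(TOY_X1, TOY_X2, max_over_all=True)
        assert comps.shape == (2,)
        assert stat == pytest.approx(1.0)

    def test_compositional_invariance(self, rng):
        """Per-sample depth rescaling before the CLR pipeline cannot move T."""
        from mecaf.compositions import AbundanceTable, clr_pipeline

        raw1 = rng.gamma(2.0, 1.0, size=(8, 6)) + 0.05
        raw2 = rng.gamma(2.0, 1.0, size=(9, 6)) + 0.05
        d1 = rng.uniform(0.5, 20.0, size=8)[:, None]
        d2 = rng.uniform(0.5, 20.0, size=9)[:, None]
        base = mecaf_statistic(
            clr_pipeline(AbundanceTable(raw1)), clr_pipeline(AbundanceTable(raw2))
        )
        scaled = mecaf_statistic(
            clr_pipeline(AbundanceTable(raw1 * d1)), clr_pipeline(AbundanceTable(raw2 * d2))
        )
        assert base[0] == pytest.approx(scaled[0], rel=1e-10)

    def test_label_symmetry(self, rng):
        X1 = rng.standard_normal((7, 5))
        X2 = rng.standard_normal((11, 5))
        assert mecaf_statistic(X1, X2)[0] == pytest.approx(
            mecaf_statistic(X2, X1)[0], rel=1e-12
        )

    def test_degenerate_variance(self):
        X1 = np.array([[1.0, -1.0], [1.0, -1.0]])  # zero variance, column 0
        X2 = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(DegenerateVarianceError):
            mecaf_statistic(X1, X2)
        # zero variance with zero difference contributes 0
        stat, comps = mecaf_statistic(X1, X1.copy(), max_over_all=True)
        assert stat == 0.0

    def test_taxon_order_mismatch(self):
        from mecaf.compositions import CLRMatrix

        a = CLRMatrix(np.zeros((3, 3)), taxon_ids=["x", "y", "z"])
        b = CLRMatrix(np.zeros((3, 3)), taxon_ids=["y", "x", "z"])
        with pytest.raises(ValueError, match="taxon order"):
            mecaf_statistic(a, b)


class TestNullCalibration:
    def test_printed_formula_at_p3(self):
        with pytest.warns(UserWarning, match="poor approximation"):
            cal = null_calibration(3)
        lp = math.log(2)
        bracket = math.log(lp) + math.log(4 * math.pi)
        h3 = 2 * lp - bracket + bracket / (2 * lp)
        assert cal.h_p == pytest.approx(h3, abs=1e-14)
        assert cal.scale == pytest.approx(2 - 1 / lp, abs=1e-14)
        assert cal.shift == pytest.approx(h3 + math.log(4) - math.log(4) / (2 * lp), abs=1e-14)

    def test_scale_increases_to_two(self):
        scales = [null_calibration(p).scale for p in (10, 50, 200, 2000, 200000)]
        assert all(b > a for a, b in zip(scales, scales[1:]))
        assert scales[-1] < 2.0
        assert scales[-1] == pytest.approx(2.0, abs=0.1)

    def test_shift_increasing_in_p(self):
        shifts = [null_calibration(p).shift for p in range(10, 500, 7)]
        assert all(b > a for a, b in zip(shifts, shifts[1:]))

    def test_small_p_rejected(self):
        with pytest.raises(ValueError):
            null_calibration(2)


class TestGumbelQuantile:
    def test_unit_log_alpha_gives_zero(self):
        assert gumbel_quantile(1 - math.exp(-1)) == pytest.approx(0.0, abs=1e-12)

    def test_reference_value(self):
        assert gumbel_quantile(0.05) == pytest.approx(2.9702, abs=1e-4)

    @pytest.mark.parametrize("alpha", [0.01, 0.05, 0.1])
    def test_round_trip(self, alpha):
        q = gumbel_quantile(alpha)
        assert math.exp(-math.exp(-q)) == pytest.approx(1 - alpha, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 1.5])
    def test_domain(self, alpha):
        with pytest.raises(ValueError):
            gumbel_quantile(alpha)


class TestMecafTest:
    def test_standardized_zero_gives_gumbel_cdf_at_zero(self, rng):
        cal = null_calibration(40)
        # build data whose statistic lands exactly at the shift
        res = _result_with_statistic(rng, p=40, target=cal.shift)
        assert res.p_value == pytest.approx(1 - math.exp(-1), abs=1e-9)

    def test_boundary_statistic_rejects_with_pvalue_alpha(self, rng):
        cal = null_calibration(40)
        crit = cal.critical_value(0.05)
        # p-value at the critical value is exactly alpha (round trip)
        assert cal.pvalue(crit) == pytest.approx(0.05, abs=1e-12)
        res = _result_with_statistic(rng, p=40, target=crit + 1e-9, alpha=0.05)
        assert res.p_value == pytest.approx(0.05, abs=1e-8)
        assert res.reject  # >= convention at the boundary

    def test_pvalue_critical_value_agreement(self, rng):
        """p < alpha iff the statistic clears the critical value, off ties."""
        for _ in range(200):
            p = int(rng.integers(10, 60))
            n1, n2 = int(rng.integers(5, 20)), int(rng.integers(5, 20))
            X1 = rng.standard_normal((n1, p))
            X2 = rng.standard_normal((n2, p)) + rng.normal(0, 0.3)
            alpha = float(rng.uniform(0.005, 0.3))
            res = mecaf_test(X1, X2, alpha=alpha)
            assert (res.p_value < alpha) == res.reject
            assert res.statistic == pytest.approx(np.max(res.per_component))

    def test_survival_pvalue_not_underflowing(self, rng):
        res = _result_with_statistic(rng, p=40, target=2000.0)
        assert 0.0 < res.p_value < 1e-200


def _result_with_statistic(rng, p, target, alpha=0.05):
    """Null-ish data rescaled so one component hits an exact statistic value."""
    n1 = n2 = 30
    X1 = rng.standard_normal((n1, p))
    X2 = rng.standard_normal((n2, p))
    X1[:, 0] = rng.standard_normal(n1)
    # shift component 0 to achieve exactly T = target (solve for the mean gap)
    d = X1[:, 0].mean() - X2[:, 0].mean()
    v = (n1 + n2) / n1 * X1[:, 0].var() + (n1 + n2) / n2 * X2[:, 0].var()
    want = math.sqrt(target * v / (n1 + n2))
    X2[:, 0] += d - want
    # damp other components so component 0 is the max
    X1[:, 1:] *= 1e-3
    X2[:, 1:] *= 1e-3
    res = mecaf_test(X1, X2, alpha=alpha)
    assert res.statistic == pytest.approx(target, rel=1e-9)
    return res


class TestMec:
    def test_zero_for_identical_groups(self, rng):
        X = rng.standard_normal((6, 5))
        assert mec_statistic(X, X.copy())[0] == 0.0

    def test_hand_computed_toy(self):
        # pooled variance 1 in both columns, n1 n2 / n = 1, diff^2 = 1
        stat, comps = mec_statistic(TOY_X1, TOY_X2)
        assert stat == pytest.approx(1.0, abs=1e-14)
        np.testing.assert_allclose(comps, [1.0, 1.0])

    def test_matches_mecaf_components_under_equal_covariance(self):
        """With equal covariances and large equal n the two per-component
        vectors are nearly proportional (correlation > 0.99)."""
        config = simulate.SimulationConfig(
            p=100, n1=500, n2=500, scenario="equal_banded", seed=3, n_reps=1
        )
        d = simulate.draw_dataset(config, 0)
        _, a = mecaf_statistic(d.X1, d.X2)
        _, b = mec_statistic(d.X1, d.X2)
        assert np.corrcoef(a, b[:-1])[0, 1] > 0.99

    def test_permutation_calibration_reasonable(self, rng):
        X1 = rng.standard_normal((15, 12))
        X2 = rng.standard_normal((15, 12))
        res = mec_test(X1, X2, calibration="permutation", n_perm=199, seed=0)
        assert 0.0 < res.p_value <= 1.0
        res2 = mec_test(X1, X2, calibration="permutation", n_perm=199, seed=0)
        assert res.p_value == res2.p_value  # seeded reproducibility


class TestMecVariants:
    def test_clr_variant_is_plain_mec(self, rng):
        X1 = rng.standard_normal((8, 6))
        X2 = rng.standard_normal((9, 6))
        a = mec_variant_test(X1, X2, "clr")
        b = mec_test(X1, X2)
        assert a.statistic == b.statistic
        assert a.p_value == b.p_value
        assert a.method == "MEC"

    def test_log_variant_equals_mec_on_logged_compositions(self, rng):
        R1 = rng.dirichlet(np.ones(6), size=8)
        R2 = rng.dirichlet(np.ones(6), size=9)
        a = mec_variant_test(R1, R2, "log")
        b = mec_test(np.log(R1), np.log(R2), method_label="MEC-Log")
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
        assert a.method == "MEC-Log"

    def test_oracle_outside_simulation_errors(self, rng):
        A = rng.gamma(2, 1, size=(6, 5)) + 0.1
        with pytest.raises(ValueError, match="unobservable"):
            mec_variant_test(A, A, "oracle", simulation=False)

    def test_unknown_variant(self, rng):
        with pytest.raises(ValueError, match="unknown variant"):
            mec_variant_test(np.ones((3, 3)), np.ones((3, 3)), "bogus")


class TestPermutationOracle:
    def test_asymptotic_pvalue_tracks_permutation_pvalue(self):
        """On equal-covariance null data the closed-form p-value tracks a
        label-permutation p-value of the same statistic: closely where
        decisions are made (p <= 0.3), loosely across the whole range."""
        config = simulate.SimulationConfig(
            p=100, n1=200, n2=200, scenario="equal_banded", seed=7, n_reps=1
        )
        chols = simulate._cholesky_pair(config)
        diffs, tail_diffs = [], []
        for rep in range(12):
            d = simulate.draw_dataset(config, rep, _chols=chols)
            res = mecaf_test(d.X1, d.X2)
            pooled = np.vstack([d.X1, d.X2])
            rng = np.random.default_rng(rep)
            count = 0
            n_perm = 499
            for _ in range(n_perm):
                idx = rng.permutation(pooled.shape[0])
                s, _ = mecaf_statistic(pooled[idx[:200]], pooled[idx[200:]])
                count += s >= res.statistic
            perm_p = (1 + count) / (1 + n_perm)
            diffs.append(abs(perm_p - res.p_value))
            if min(perm_p, res.p_value) <= 0.3:
                tail_diffs.append(abs(perm_p - res.p_value))
        assert np.mean(diffs) < 0.05
        assert tail_diffs and np.mean(tail_diffs) < 0.03
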