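"""Bilinear OLS machinery against closed-form and brute-force oracles."""

import numpy as np
import pytest

from strucdiv import (
    adequacy,
    adjusted_r2,
    contributions,
    fit_bilinear,
    fit_linear,
    partial_correlations,
    vif,
)
from strucdiv.errors import DegenerateDataError


def normal_equations(x1, x2, y):
    """Independent brute-force oracle: solve (X'X) b = X'y directly."""
    X = np.column_stack([np.ones_like(x1), x1, x2])
    b = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ b
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return b, 1.0 - ss_res / ss_tot


class TestFitBilinear:
    def test_noiseless_exact(self, rng):
        x1 = rng.normal(size=10)
        x2 = rng.normal(size=10)
        y = 1 + 2 * x1 + 3 * x2
        f = fit_bilinear(x1, x2, y)
        assert f.b0 == pytest.approx(1, abs=1e-10)
        assert f.b1 == pytest.approx(2, abs=1e-10)
        assert f.b2 == pytest.approx(3, abs=1e-10)
        assert f.r == pytest.approx(1, abs=1e-10)
        assert f.r2 == pytest.approx(1, abs=1e-10)
        assert (f.sss, f.sids) == (abs(f.b1), abs(f.b2))

    def test_orthogonal_irrelevant_predictor(self):
        # x2 orthogonal (in sample) to both y and x1
        x1 = np.array([-3.0, -1.0, 1.0, 3.0] * 4)
        x2 = np.array([1.0, -1.0, -1.0, 1.0] * 4)
        y = 2.0 * x1
        x2 = x2 - x2.mean()
        assert abs(np.corrcoef(x1, x2)[0, 1]) < 1e-12
        f = fit_bilinear(x1, x2, y + np.array([0.01, -0.01] * 8))
        assert f.b2 == pytest.approx(0, abs=1e-10)
        assert f.c_indel == pytest.approx(0, abs=1e-10)
        assert f.r == pytest.approx(abs(np.corrcoef(x1, y + np.array([0.01, -0.01] * 8))[0, 1]))

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            x1 = rng.normal(size=n)
            x2 = 0.5 * x1 + rng.normal(size=n)
            y = 1 + 0.5 * x1 - 1.5 * x2 + rng.normal(size=n)
            f = fit_bilinear(x1, x2, y)
            (b0, b1, b2), r2 = normal_equations(x1, x2, y)
            assert f.b0 == pytest.approx(b0, abs=1e-8)
            assert f.b1 == pytest.approx(b1, abs=1e-8)
            assert f.b2 == pytest.approx(b2, abs=1e-8)
            assert f.r2 == pytest.approx(r2, abs=1e-8)

    def test_zero_variance_named(self):
        x = np.arange(10.0)
        with pytest.raises(DegenerateDataError, match="x2"):
            fit_bilinear(x, np.ones(10), x)

    def test_perfect_collinearity_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(DegenerateDataError, match="collinear"):
            fit_bilinear(x, 2 * x + 1, x**2)

    def test_scale_invariance(self, rng):
        x1 = rng.normal(size=60)
        x2 = rng.normal(size=60)
        y = 1 + x1 + 2 * x2 + rng.normal(size=60)
        f = fit_bilinear(x1, x2, y)
        g = fit_bilinear(10 * x1, x2, y)
        assert g.b1 == pytest.approx(f.b1 / 10)
        for attr in ("r", "r2", "adj_r2", "p_value", "beta1", "beta2",
                     "c_sub", "c_indel", "partial1", "partial2", "vif"):
            assert getattr(g, attr) == pytest.approx(getattr(f, attr), abs=1e-10)


class TestFitLinear:
    def test_exact_slope(self):
        x = np.arange(1.0, 8.0)
        f = fit_linear(x, 2 * x)
        assert f.b1 == pytest.approx(2, abs=1e-12)
        assert f.r2 == pytest.approx(1, abs=1e-12)

    def test_null_case_r2_near_zero(self, rng):
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        assert fit_linear(x, y).r2 < 0.01

    def test_closed_form_slope(self, rng):
        x = rng.normal(size=80)
        y = 3 - 0.7 * x + rng.normal(size=80)
        f = fit_linear(x, y)
        assert f.b1 == pytest.approx(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))
        assert f.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)


class TestAdjustedR2:
    def test_perfect_fit_stays_one(self):
        assert adjusted_r2(1.0, 10, 2) == pytest.approx(1.0, abs=1e-15)

    def test_spot_value(self):
        assert adjusted_r2(0.64, 100, 2) == pytest.approx(1 - 0.36 * 99 / 97, abs=1e-12)
        assert adjusted_r2(0.64, 100, 2) == pytest.approx(0.6325773195876289, abs=1e-12)

    def test_k_zero_identity(self):
        assert adjusted_r2(0.5, 30, 0) == pytest.approx(0.5, abs=1e-15)

    def test_dof_error(self):
        with pytest.raises(DegenerateDataError):
            adjusted_r2(0.5, 3, 2)


class TestAdequacy:
    def test_equal_adjusted_r2_is_one(self, rng):
        x1 = rng.normal(size=40)
        x2 = rng.normal(size=40)
        y = x1 + x2 + rng.normal(size=40)
        f = fit_bilinear(x1, x2, y)
        lin = fit_linear(x1, y)
        lin.adj_r2 = f.adj_r2
        assert adequacy(f, lin) == pytest.approx(1.0, abs=1e-12)

    def test_ten_percent_improvement(self, rng):
        x1 = rng.normal(size=40)
        x2 = rng.normal(size=40)
        f = fit_bilinear(x1, x2, x1 + x2 + rng.normal(size=40))
        lin = fit_linear(x1, np.arange(40.0) + rng.normal(size=40))
        f.adj_r2, lin.adj_r2 = 0.66, 0.60
        assert adequacy(f, lin) == pytest.approx(1.1)

    def test_nested_model_improvement_when_x2_matters(self):
        wins = 0
        n_rep = 100
        for r in range(n_rep):
            rng = np.random.default_rng(r)
            x1 = rng.normal(size=200)
            x2 = rng.normal(size=200)
            y = x1 + 0.8 * x2 + rng.normal(size=200)
            f = fit_bilinear(x1, x2, y)
            if adequacy(f, fit_linear(x1, y)) > 1:
                wins += 1
        assert wins >= 0.95 * n_rep

    def test_nonpositive_denominator_rejected(self, rng):
        x1 = rng.normal(size=40)
        x2 = rng.normal(size=40)
        f = fit_bilinear(x1, x2, x1 + x2)
        lin = fit_linear(x1, rng.normal(size=40))
        lin.adj_r2 = -0.01
        with pytest.raises(DegenerateDataError):
            adequacy(f, lin)


class TestPartialCorrelations:
    def test_zero_collinearity_reduction(self):
        x1 = np.array([-3.0, -1.0, 1.0, 3.0] * 5)
        x2 = np.array([1.0, -1.0, -1.0, 1.0] * 5)
        y = x1 + 0.3 * np.array([1.0, 1.0, -1.0, -1.0] * 5)
        p1, _, _, _ = partial_correlations(x1, x2, y)
        ry1 = np.corrcoef(y, x1)[0, 1]
        ry2 = np.corrcoef(y, x2)[0, 1]
        assert p1 == pytest.approx(ry1 / np.sqrt(1 - ry2**2), abs=1e-12)

    def test_pure_signal_vs_pure_noise(self, rng):
        x1 = rng.normal(size=500)
        x2 = rng.normal(size=500)
        y = x1 + 0.01 * rng.normal(size=500)
        p1, pv1, p2, pv2 = partial_correlations(x1, x2, y)
        assert p1 > 0.999
        assert abs(p2) < 0.15
        assert pv1 < 1e-10

    def test_residual_regression_oracle(self, rng):
        """partial r(y, x1 | x2) equals the correlation of the residuals of
        y-on-x2 and x1-on-x2 regressions."""
        x1 = rng.normal(size=120)
        x2 = 0.6 * x1 + rng.normal(size=120)
        y = x1 - x2 + rng.normal(size=120)
        p1, _, p2, _ = partial_correlations(x1, x2, y)

        def residuals(v, w):
            slope = np.cov(v, w, ddof=1)[0, 1] / np.var(w, ddof=1)
            return v - v.mean() - slope * (w - w.mean())

        oracle1 = np.corrcoef(residuals(y, x2), residuals(x1, x2))[0, 1]
        oracle2 = np.corrcoef(residuals(y, x1), residuals(x2, x1))[0, 1]
        assert p1 == pytest.approx(oracle1, abs=1e-10)
        assert p2 == pytest.approx(oracle2, abs=1e-10)

    def test_degenerate_correlation_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(DegenerateDataError):
            partial_correlations(x, np.sin(x), x)


class TestVif:
    def test_uncorrelated_is_one(self):
        x1 = np.array([-1.0, 1.0, -1.0, 1.0])
        x2 = np.array([1.0, 1.0, -1.0, -1.0])
        assert vif(x1, x2) == pytest.approx(1.0, abs=1e-12)

    def test_spot_value(self, rng):
        # construct predictors with exact sample correlation 0.6
        x1 = rng.normal(size=5000)
        z = rng.normal(size=5000)
        x1 = (x1 - x1.mean()) / x1.std()
        z = z - z.mean()
        z = z - (z @ x1) / (x1 @ x1) * x1
        z /= z.std()
        x2 = 0.6 * x1 + np.sqrt(1 - 0.36) * z
        assert vif(x1, x2) == pytest.approx(1 / (1 - 0.36), abs=1e-9)

    def test_independent_large_sample_near_one(self, rng):
        assert vif(rng.normal(size=5000), rng.normal(size=5000)) == pytest.approx(
            1.0, abs=0.01
        )


class TestContributions:
    def test_orthogonal_predictors_split_into_squared_correlations(self):
        x1 = np.array([-3.0, -1.0, 1.0, 3.0] * 10)
        x2 = np.array([1.0, -1.0, -1.0, 1.0] * 10)
        rng = np.random.default_rng(5)
        y = x1 + 2 * x2 + rng.normal(size=40)
        f = fit_bilinear(x1, x2, y)
        c1, c2 = contributions(f)
        assert c1 == pytest.approx(f.ry1**2, abs=1e-10)
        assert c2 == pytest.approx(f.ry2**2, abs=1e-10)

    def test_single_driver(self, rng):
        x1 = rng.normal(size=30)
        x2 = rng.normal(size=30)
        f = fit_bilinear(x1, x2, 5 * x1)
        assert f.c_sub == pytest.approx(1, abs=1e-10)
        assert f.c_indel == pytest.approx(0, abs=1e-10)

    def test_sum_equals_r2_for_correlated_predictors(self, rng):
        for _ in range(10):
            n = int(rng.integers(20, 150))
            x1 = rng.normal(size=n)
            x2 = 0.7 * x1 + rng.normal(size=n)
            y = x1 - 2 * x2 + rng.normal(size=n)
            f = fit_bilinear(x1, x2, y)
            assert f.c_sub + f.c_indel == pytest.approx(f.r2, abs=1e-10)


class TestPValueMonotonicity:
    def test_p_decreases_with_n(self):
        """For fixed population signal, the overall-F p-value shrinks as n grows."""
        pvals = []
        for n in (20, 80, 320):
            rng = np.random.default_rng(99)
            x1 = rng.normal(size=n)
            x2 = rng.normal(size=n)
            y = 0.3 * x1 + 0.3 * x2 + rng.normal(size=n)
            pvals.append(fit_bilinear(x1, x2, y).p_value)
        assert pvals[0] > pvals[1] > pvals[2]
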