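import math

import numpy as np
import pytest
from scipy.stats import gaussian_kde

from directqr import (
    BandwidthSpec,
    GridPolicy,
    RegressionSample,
    compute_local_quantiles,
    conditional_cdf,
    conditional_density,
    diagnose,
    direct_quantile_curve,
    direct_quantile_curves,
    local_quantile,
    nw_weights,
    true_conditional_quantile,
)
from directqr.errors import (
    ExtrapolationError,
    ExtrapolationWarning,
    GridCoverageError,
    InvalidInputError,
)
from directqr.gumbel_sim import GumbelParams

from conftest import make_gumbel_sample


class TestRegressionSample:
    def test_row_mismatch(self):
        with pytest.raises(InvalidInputError):
            RegressionSample(y=np.zeros(5), X=np.zeros((6, 1)))

    def test_too_few_rows(self):
        with pytest.raises(InvalidInputError):
            RegressionSample(y=np.zeros(4), X=np.zeros((4, 1)))

    def test_nonfinite_rejected(self):
        y = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        with pytest.raises(InvalidInputError):
            RegressionSample(y=y, X=np.zeros((5, 1)))

    def test_1d_covariates_promoted(self, rng):
        s = RegressionSample(y=rng.normal(size=10), X=rng.normal(size=10))
        assert s.X.shape == (10, 1) and s.d == 1 and s.n == 10


class TestConditionalDensity:
    def test_single_cluster_bump(self, rng):
        # all mass near one (y, x) point: conditional density at that x is a
        # bump centred near the common y value
        y = np.full(6, 2.0) + rng.normal(size=6) * 1e-3
        x = np.full(6, 1.0) + rng.normal(size=6) * 1e-3
        s = RegressionSample(y=y, X=x)
        grid = np.linspace(-2, 6, 801)
        bw = BandwidthSpec.fixed([1.0])
        dens = conditional_density(s, [1.0], grid, bw=bw)
        assert np.all(dens >= 0)
        assert abs(grid[np.argmax(dens)] - 2.0) < 0.05

    def test_independent_covariate_recovers_marginal(self):
        # y independent of x: f(y|x0) approaches the 1-d KDE of y alone
        rng = np.random.default_rng(5)
        n = 500
        y = rng.standard_normal(n)
        x = rng.standard_normal(n)
        s = RegressionSample(y=y, X=x)
        grid = np.linspace(-4, 4, 201)
        dens = conditional_density(s, [0.0], grid, estimator="product")
        oracle = gaussian_kde(y)(grid)  # independent 1-d KDE implementation
        assert np.max(np.abs(dens - oracle)) < 0.05

    def test_grid_integral_near_one(self, gumbel_sample):
        # shared fixed bandwidth makes the joint's marginal equal the ratio's
        # denominator, so the raw conditional mass integrates to 1
        bw = BandwidthSpec.fixed([0.5])
        grid = np.linspace(-6, 14, 2001)
        dens = conditional_density(gumbel_sample, [1.0], grid, bw=bw)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.01)

    def test_dimension_mismatch(self, gumbel_sample):
        with pytest.raises(InvalidInputError):
            conditional_density(gumbel_sample, [1.0, 2.0],
                                np.linspace(0, 5, 10))


class TestConditionalCdf:
    def test_normalization_contract(self, gumbel_sample):
        grid = np.linspace(-6, 16, 1501)
        cdf = conditional_cdf(gumbel_sample, [1.0], grid)
        assert cdf[-1] == pytest.approx(1.0)
        assert cdf[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(cdf) >= 0)
        assert np.all((cdf >= 0) & (cdf <= 1))

    def test_narrow_grid_rejected(self, gumbel_sample):
        grid = np.linspace(0.0, 0.5, 50)  # far narrower than the y spread
        with pytest.raises(GridCoverageError):
            conditional_cdf(gumbel_sample, [1.0], grid)

    def test_exponential_sample_sup_norm(self):
        # y ~ Exp(1) with an independent covariate: the conditional CDF should
        # track 1 - exp(-y)
        rng = np.random.default_rng(11)
        n = 200
        y = rng.exponential(size=n)
        x = rng.standard_normal(n)
        s = RegressionSample(y=y, X=x)
        grid = np.linspace(-3, 12, 1001)
        cdf = conditional_cdf(s, [0.0], grid, estimator="product")
        truth = np.where(grid >= 0, 1 - np.exp(-np.maximum(grid, 0)), 0.0)
        assert np.max(np.abs(cdf - truth)) < 0.1


class TestLocalQuantile:
    def test_monotone_in_tau(self, gumbel_sample):
        q1 = local_quantile(gumbel_sample, 3, 0.5)
        q2 = local_quantile(gumbel_sample, 3, 0.9)
        q3 = local_quantile(gumbel_sample, 3, 0.99)
        assert q1 <= q2 <= q3

    def test_invalid_tau(self, gumbel_sample):
        with pytest.raises(InvalidInputError):
            local_quantile(gumbel_sample, 0, 1.5)

    def test_invalid_row(self, gumbel_sample):
        with pytest.raises(InvalidInputError):
            local_quantile(gumbel_sample, 1000, 0.5)

    def test_node_exact_inversion(self):
        # a CDF hitting tau exactly at a grid node must return that node
        from directqr.direct_qr import _invert_cdf
        y_grid = np.array([0.0, 1.0, 2.0, 3.0])
        cdf = np.array([0.0, 0.25, 0.75, 1.0])
        assert _invert_cdf(y_grid, cdf, 0.25) == 1.0
        assert _invert_cdf(y_grid, cdf, 0.75) == 2.0
        assert _invert_cdf(y_grid, cdf, 0.5) == pytest.approx(1.5)

    def test_against_true_quantile_gumbel(self):
        # oracle: exact conditional quantile of the generating distribution
        params = GumbelParams(alpha=1.0)
        s = make_gumbel_sample(300, seed=21)
        lqs = compute_local_quantiles(s, [0.95])[0.95]
        truth = true_conditional_quantile(0.95, s.X[:, 0], params)
        mean_abs = float(np.mean(np.abs(lqs.xi - truth)))
        # tolerance calibrated once from independent replications at n=300
        assert mean_abs < 0.8

    def test_batch_matches_single(self, gumbel_sample):
        lqs = compute_local_quantiles(gumbel_sample, [0.9])[0.9]
        for i in (0, 17, 99):
            assert lqs.xi[i] == pytest.approx(
                local_quantile(gumbel_sample, i, 0.9), abs=1e-12)


class TestNWWeights:
    def test_single_point(self):
        w = nw_weights([0.0], np.array([[3.0]]), BandwidthSpec.fixed([1.0]))
        assert np.allclose(w, [1.0])

    def test_equidistant_symmetry(self):
        X = np.array([[-1.0], [1.0]])
        w = nw_weights([0.0], X, BandwidthSpec.fixed([0.7]))
        assert np.allclose(w, [0.5, 0.5])

    def test_three_point_hand_computation(self):
        X = np.array([[0.0], [1.0], [3.0]])
        x0, h = 0.5, 1.0
        raw = [math.exp(-0.5 * ((x0 - xi) / h) ** 2) for xi in (0.0, 1.0, 3.0)]
        expected = np.array(raw) / sum(raw)
        w = nw_weights([x0], X, BandwidthSpec.fixed([h]))
        assert np.allclose(w, expected, atol=1e-12)

    def test_sum_to_one(self, rng):
        X = rng.standard_normal((50, 2))
        bw = BandwidthSpec.per_dimension(X)
        for _ in range(20):
            w = nw_weights(rng.standard_normal(2), X, bw)
            assert np.all(w >= 0)
            assert abs(w.sum() - 1.0) < 1e-12

    def test_underflow_raises(self):
        X = np.zeros((5, 1))
        with pytest.raises(ExtrapolationError):
            nw_weights([1e6], X, BandwidthSpec.fixed([0.1]))


class TestDirectQuantileCurve:
    def test_constant_local_quantiles_give_constant_curve(self, monkeypatch):
        # all xi equal c -> curve identically c (weights sum to one)
        from directqr import direct_qr as module
        s = make_gumbel_sample(50, seed=3)

        def fake_lqs(sample, taus, **kwargs):
            from directqr.direct_qr import LocalQuantileSet
            return {float(t): LocalQuantileSet(
                tau=float(t), X=sample.X, xi=np.full(sample.n, 4.2),
                bandwidths=BandwidthSpec.fixed([1.0])) for t in taus}

        monkeypatch.setattr(module, "compute_local_quantiles", fake_lqs)
        curve = module.direct_quantile_curve(s, 0.9, np.linspace(0, 5, 30))
        assert np.allclose(curve.q_values, 4.2, atol=1e-12)

    def test_isolated_point_dominant_weight(self):
        # evaluating at a lone data point far from the rest returns its xi
        x = np.concatenate([np.linspace(0, 1, 20), [50.0]])
        rng = np.random.default_rng(8)
        y = np.concatenate([rng.normal(size=20), [9.0]])
        s = RegressionSample(y=y, X=x)
        bw = BandwidthSpec.fixed([1.0])
        lqs = compute_local_quantiles(
            s, [0.5], bw=BandwidthSpec.fixed([1.0]), estimator="product")[0.5]
        curve = direct_quantile_curve(
            s, 0.5, np.array([50.0]),
            bw_density=BandwidthSpec.fixed([1.0]),
            bw_smooth=bw, estimator="product")
        assert curve.q_values[0] == pytest.approx(lqs.xi[-1], abs=1e-6)

    def test_convex_combination_bound(self):
        for seed in range(3):
            s = make_gumbel_sample(80, seed=seed)
            lqs = compute_local_quantiles(s, [0.95])[0.95]
            curve = direct_quantile_curve(s, 0.95, np.linspace(0, 6, 61))
            assert np.all(curve.q_values >= lqs.xi.min() - 1e-9)
            assert np.all(curve.q_values <= lqs.xi.max() + 1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_non_crossing_ten_seeds(self, seed):
        s = make_gumbel_sample(60, seed=100 + seed)
        grid = np.linspace(0, 6, 41)
        curves = direct_quantile_curves(s, [0.9, 0.95, 0.99], grid)
        qs = {c.tau: c.q_values for c in curves}
        assert np.all(qs[0.9] <= qs[0.95] + 1e-9)
        assert np.all(qs[0.95] <= qs[0.99] + 1e-9)

    def test_extrapolation_warning_and_fallback(self):
        s = make_gumbel_sample(30, seed=2)
        far = np.array([1e4])
        with pytest.warns(ExtrapolationWarning):
            curve = direct_quantile_curve(s, 0.9, far)
        assert np.isfinite(curve.q_values[0])

    def test_degenerate_covariate_reduces_to_marginal_quantile(self, rng):
        # all x equal: the curve is flat at the smoothed marginal quantile of y
        y = rng.exponential(size=100)
        x = np.full(100, 2.0)
        s = RegressionSample(y=y, X=x)
        bw = BandwidthSpec.fixed([0.3, 1.0])
        lqs = compute_local_quantiles(s, [0.9], bw=BandwidthSpec.fixed([0.3, 1.0]),
                                      estimator="product")[0.9]
        assert np.ptp(lqs.xi) == pytest.approx(0.0, abs=1e-12)
        curve = direct_quantile_curve(
            s, 0.9, np.array([2.0, 2.5]),
            bw_density=BandwidthSpec.fixed([0.3, 1.0]),
            bw_smooth=BandwidthSpec.fixed([1.0]), estimator="product")
        assert np.allclose(curve.q_values, lqs.xi[0], atol=1e-9)
        # marginal check: the flat level matches the same-bandwidth 1-d
        # kernel CDF of y inverted at tau
        from directqr.direct_qr import _invert_cdf
        from scipy.stats import norm
        grid = np.linspace(y.min() - 3, y.max() + 6, 4001)
        kcdf = np.mean(norm.cdf((grid[:, None] - y[None, :]) / 0.3), axis=1)
        kcdf /= kcdf[-1]
        marginal_q = _invert_cdf(grid, kcdf, 0.9)
        assert curve.q_values[0] == pytest.approx(marginal_q, abs=0.02)

    def test_mise_decreases_with_n(self):
        # oracle consistency: error vs the exact conditional quantile shrinks
        params = GumbelParams(alpha=1.0)
        grid = np.linspace(0, 4, 81)
        truth = true_conditional_quantile(0.9, grid, params)

        def mise(n, reps=8):
            vals = []
            for r in range(reps):
                s = make_gumbel_sample(n, seed=3000 + r)
                c = direct_quantile_curve(s, 0.9, grid)
                vals.append(np.trapezoid((c.q_values - truth) ** 2, grid))
            return float(np.mean(vals))

        assert mise(400) < mise(100)


class TestDiagnose:
    def test_single_curve_no_crossing(self, gumbel_sample):
        curve = direct_quantile_curve(gumbel_sample, 0.9, np.linspace(0, 5, 21))
        report = diagnose([curve], gumbel_sample)
        assert report.crossings == ()
        assert report.ok

    def test_coverage_near_nominal(self):
        s = make_gumbel_sample(500, seed=9)
        curve = direct_quantile_curve(s, 0.95, np.linspace(0, 8, 200))
        report = diagnose([curve], s)
        cov = report.coverage[(0.95, "direct")]
        assert 0.90 <= cov <= 0.99

    def test_swapped_labels_flagged(self, gumbel_sample):
        grid = np.linspace(0, 5, 21)
        c1, c2 = direct_quantile_curves(gumbel_sample, [0.9, 0.99], grid)
        from directqr import QuantileCurve
        swapped = [
            QuantileCurve(tau=0.9, x_eval=grid, q_values=c2.q_values,
                          method="direct"),
            QuantileCurve(tau=0.99, x_eval=grid, q_values=c1.q_values,
                          method="direct"),
        ]
        report = diagnose(swapped, gumbel_sample)
        assert report.crossings

    def test_empty_curve_list_rejected(self, gumbel_sample):
        with pytest.raises(InvalidInputError):
            diagnose([], gumbel_sample)
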