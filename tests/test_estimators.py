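"""Estimator correctness: closed-form oracles, limiting cases, invariances."""

import numpy as np
import pytest
import statsmodels.api as sm

from mrpipe import (
    EstimationError, ci_bounds, ivw, mr_egger, mr_raps, to_effect_size,
    wald_ratio, weighted_median, weighted_mode,
)
from mrpipe.estimators import _weighted_median_core
from tests.conftest import make_h, sim_h


class TestWaldRatio:
    def test_exact_ratio(self):
        h = make_h([0.5], [-0.5], se_alpha=[0.1])
        assert wald_ratio(h).b == pytest.approx(-1.0)

    def test_identity_instrument(self):
        h = make_h([1.0], [0.3], se_alpha=[0.07])
        est = wald_ratio(h)
        assert est.b == pytest.approx(0.3)
        assert est.se == pytest.approx(0.07)

    def test_zero_gamma_rejected(self):
        with pytest.raises(EstimationError):
            wald_ratio(make_h([0.0], [0.1]))

    def test_multi_snp_rejected(self):
        with pytest.raises(EstimationError):
            wald_ratio(make_h([0.1, 0.2], [0.1, 0.2]))

    def test_delta_method_se_matches_monte_carlo(self, rng):
        # strong instrument: first-order propagation should hold to ~2%
        g, sg, a, sa = 0.2, 0.002, 0.05, 0.01
        draws = rng.normal(a, sa, 100_000) / rng.normal(g, sg, 100_000)
        h = make_h([g], [a], se_alpha=[sa], se_gamma=[sg])
        assert wald_ratio(h).se == pytest.approx(draws.std(), rel=0.02)


def wls_zero_intercept(gamma, alpha, se_alpha):
    """Independent oracle: zero-intercept WLS via statsmodels."""
    return sm.WLS(alpha, gamma[:, None], weights=1.0 / se_alpha**2).fit().params[0]


class TestIVW:
    def test_degenerate_heterogeneity_recovers_common_ratio(self):
        gamma = np.array([0.1, 0.2, 0.15])
        h = make_h(gamma, 0.3 * gamma, se_alpha=[0.01, 0.02, 0.015])
        fixed = ivw(h, "fixed")
        random = ivw(h, "multiplicative_random")
        assert fixed.b == pytest.approx(0.3)
        assert random.se == pytest.approx(fixed.se)  # Q=0 -> no inflation

    def test_single_snp_dispatch_error(self):
        with pytest.raises(EstimationError, match="wald_ratio"):
            ivw(make_h([0.1], [0.05]))

    def test_toy_snps_match_closed_form_oracle(self):
        h = make_h([0.10, 0.20, 0.15], [0.05, 0.12, 0.06],
                   se_alpha=[0.01, 0.02, 0.015])
        expect = wls_zero_intercept(h.gamma, h.alpha, h.se_alpha)
        assert ivw(h, "fixed").b == pytest.approx(expect, rel=1e-12)

    def test_random_inputs_match_wls_to_ten_digits(self, rng):
        for _ in range(20):
            j = rng.integers(5, 60)
            gamma = rng.normal(0, 0.1, j)
            alpha = rng.normal(0, 0.05, j)
            se_a = rng.uniform(0.005, 0.05, j)
            h = make_h(gamma, alpha, se_a)
            assert ivw(h, "fixed").b == pytest.approx(
                wls_zero_intercept(gamma, alpha, se_a), rel=1e-10)

    def test_random_effects_never_deflate(self, rng):
        for seed in range(5):
            h, _ = sim_h("null", seed=seed)
            assert ivw(h, "multiplicative_random").se >= ivw(h, "fixed").se


class TestEgger:
    def test_perfect_line_through_origin(self):
        gamma = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_h(gamma, 0.25 * gamma)
        slope, intercept = mr_egger(h)
        assert slope.b == pytest.approx(0.25)
        assert intercept.b == pytest.approx(0.0, abs=1e-12)

    def test_affine_recovery(self):
        gamma = np.array([0.1, 0.2, 0.3, 0.5])
        h = make_h(gamma, 0.02 + 0.4 * gamma)
        slope, intercept = mr_egger(h)
        assert slope.b == pytest.approx(0.4)
        assert intercept.b == pytest.approx(0.02)

    def test_matches_statsmodels_wls(self, random_h):
        flip = np.sign(random_h.gamma)
        x = random_h.gamma * flip
        y = random_h.alpha * flip
        X = sm.add_constant(x)
        fit = sm.WLS(y, X, weights=1.0 / random_h.se_alpha**2).fit()
        slope, intercept = mr_egger(random_h)
        assert slope.b == pytest.approx(fit.params[1], rel=1e-10)
        assert intercept.b == pytest.approx(fit.params[0], rel=1e-10)

    def test_too_few_snps(self):
        with pytest.raises(EstimationError):
            mr_egger(make_h([0.1, 0.2], [0.1, 0.2]))

    def test_directional_pleiotropy_intercept_recovery(self):
        # mean Egger intercept over replicates approaches mu_a = 0.02
        intercepts = []
        for seed in range(300):
            h, _ = sim_h("directional", seed=seed)
            intercepts.append(mr_egger(h)[1].b)
        mean = np.mean(intercepts)
        mc_se = np.std(intercepts, ddof=1) / np.sqrt(len(intercepts))
        assert abs(mean - 0.02) < 3 * mc_se + 1e-4


class TestWeightedMedian:
    def test_equal_ratios(self):
        gamma = np.array([0.1, 0.2, 0.3])
        h = make_h(gamma, 0.7 * gamma)
        assert weighted_median(h, n_boot=50).b == pytest.approx(0.7)

    def test_unweighted_median_of_three(self):
        h = make_h([1.0, 1.0, 1.0], [1.0, 2.0, 9.0], se_alpha=[0.1, 0.1, 0.1])
        assert weighted_median(h, n_boot=50).b == pytest.approx(2.0)

    def test_matches_cumulative_weight_scan_oracle(self, rng):
        for _ in range(50):
            j = int(rng.integers(5, 12))
            ratios = rng.normal(0, 1, j)
            w = rng.uniform(0.1, 2.0, j)
            # independent scan: walk sorted ratios until half the mass is passed
            order = np.argsort(ratios)
            r, wn = ratios[order], w[order] / w.sum()
            cum = np.cumsum(wn) - 0.5 * wn
            if 0.5 <= cum[0] or 0.5 >= cum[-1]:
                expected = r[0] if 0.5 <= cum[0] else r[-1]
            else:
                k = np.searchsorted(cum, 0.5)
                f = (0.5 - cum[k - 1]) / (cum[k] - cum[k - 1])
                expected = r[k - 1] + f * (r[k] - r[k - 1])
            assert _weighted_median_core(ratios, w) == pytest.approx(expected)

    def test_bootstrap_reproducible(self, random_h):
        a = weighted_median(random_h, n_boot=200, seed=42)
        b = weighted_median(random_h, n_boot=200, seed=42)
        assert a.se == b.se

    def test_zero_gamma_snp_excluded(self):
        h = make_h([0.0, 0.1, 0.2, 0.3], [0.0, 0.05, 0.1, 0.15])
        assert weighted_median(h, n_boot=20).n_snps == 3


class TestWeightedMode:
    def test_equal_ratios(self):
        gamma = np.array([0.1, 0.2, 0.3])
        h = make_h(gamma, 0.7 * gamma)
        assert weighted_mode(h, n_boot=20).b == pytest.approx(0.7)

    def test_majority_cluster_wins(self):
        gamma = np.ones(10)
        ratios = np.array([1.0, 1.02, 0.98, 1.01, 0.99, 1.03, 0.97, 5.0, 5.1, 4.9])
        h = make_h(gamma, ratios, se_alpha=np.full(10, 0.1))
        b = weighted_mode(h, n_boot=20).b
        assert 0.9 < b < 1.1

    def test_weight_scale_invariance(self):
        gamma = np.array([0.1, 0.2, 0.3, 0.4])
        alpha = np.array([0.03, 0.09, 0.1, 0.18])
        h1 = make_h(gamma, alpha, se_alpha=np.full(4, 0.01))
        h2 = make_h(gamma, alpha, se_alpha=np.full(4, 0.01) / np.sqrt(2))
        # halving all variances doubles every weight: mode unchanged
        assert weighted_mode(h1, n_boot=0).b == pytest.approx(
            weighted_mode(h2, n_boot=0).b, abs=1e-9)


class TestRAPS:
    def test_reduces_to_ivw_when_gamma_exact(self, rng):
        gamma = rng.normal(0, 0.1, 20)
        alpha = 0.2 * gamma + rng.normal(0, 0.01, 20)
        h = make_h(gamma, alpha, se_alpha=np.full(20, 0.01),
                   se_gamma=np.full(20, 1e-10))
        assert mr_raps(h).b == pytest.approx(ivw(h, "fixed").b, rel=1e-8)

    def test_perfect_line(self):
        gamma = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_h(gamma, 0.15 * gamma, se_gamma=np.full(4, 0.001))
        est = mr_raps(h, overdispersion=True)
        assert est.b == pytest.approx(0.15, abs=1e-6)

    def test_weak_instruments_less_biased_than_ivw(self):
        raps_err, ivw_err = [], []
        for seed in range(200):
            h, truth = sim_h("weak_instruments", seed=seed)
            raps_err.append(mr_raps(h).b - truth.true_beta)
            ivw_err.append(ivw(h).b - truth.true_beta)
        assert abs(np.mean(raps_err)) < abs(np.mean(ivw_err))

    def test_huber_loss_converges(self, random_h):
        est = mr_raps(random_h, loss="huber", overdispersion=True)
        assert np.isfinite(est.b) and est.se > 0


class TestReportingArithmetic:
    @pytest.mark.parametrize("b,se,lo,hi", [
        (-0.230, 0.028, -0.285, -0.175),
        (-0.998, 0.322, -1.629, None),  # upper bound not recoverable from
        (0.0, 1.0, -1.960, 1.960),      # the rounded (b, SE) pair
    ])
    def test_ci_bounds_reproduce_printed_intervals(self, b, se, lo, hi):
        low, high = ci_bounds(b, se)
        assert round(low, 3) == lo
        if hi is not None:
            assert round(high, 3) == hi

    @pytest.mark.parametrize("b,or_", [(0.0, 1.0), (-0.230, 0.795), (-0.341, 0.711)])
    def test_odds_ratio_conversion(self, b, or_):
        est = wald_ratio(make_h([1.0], [b], se_alpha=[0.1]))
        es = to_effect_size(est, "binary")
        assert round(es.value, 3) == or_

    def test_continuous_without_scale_flagged(self):
        est = wald_ratio(make_h([1.0], [0.5], se_alpha=[0.1]))
        assert to_effect_size(est, "continuous").kind == "unstandardised_beta"
        es = to_effect_size(est, "continuous", sd_scale=0.5)
        assert es.kind == "standardised_beta"
        assert es.value == pytest.approx(0.25)


class TestInvariances:
    @pytest.mark.parametrize("est_fn", [
        lambda h: ivw(h).b,
        lambda h: mr_egger(h)[0].b,
        lambda h: weighted_median(h, n_boot=0).b,
        lambda h: mr_raps(h).b,
    ], ids=["ivw", "egger", "median", "raps"])
    def test_negating_alpha_negates_estimate(self, random_h, est_fn):
        h_neg = make_h(random_h.gamma, -random_h.alpha, random_h.se_alpha,
                       random_h.se_gamma)
        assert est_fn(h_neg) == pytest.approx(-est_fn(random_h), rel=1e-9)

    @pytest.mark.parametrize("est_fn", [
        lambda h: ivw(h).b,
        lambda h: mr_egger(h)[0].b,
        lambda h: weighted_median(h, n_boot=0).b,
        lambda h: mr_raps(h).b,
    ], ids=["ivw", "egger", "median", "raps"])
    def test_instrument_orientation_invariance(self, random_h, est_fn, rng):
        flip = rng.choice([-1.0, 1.0], len(random_h))
        h_flip = make_h(random_h.gamma * flip, random_h.alpha * flip,
                        random_h.se_alpha, random_h.se_gamma)
        assert est_fn(h_flip) == pytest.approx(est_fn(random_h), rel=1e-9)
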