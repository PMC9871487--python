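"""Causal estimators: Wald ratio, IVW, Egger, weighted median, MLE, RAPS."""

import math

import numpy as np
import pytest

from mrkit.errors import (
    CollinearityError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from mrkit.estimators import (
    _profile_nll,
    ivw,
    max_likelihood,
    mr_egger,
    mr_raps,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)

from conftest import draw_harmonized, make_pairs


class TestWaldRatio:
    def test_direct_arithmetic(self):
        (pair,) = make_pairs([0.1], [0.02], [0.2], [0.05])
        est = wald_ratio(pair)
        assert est.beta == 2.0 and est.se == 0.5 and est.n_snps == 1

    def test_null_outcome(self):
        (pair,) = make_pairs([0.1], [0.02], [0.0], [0.05])
        est = wald_ratio(pair)
        assert est.beta == 0.0 and est.or_ == 1.0

    def test_second_order_se_matches_delta_method(self):
        (pair,) = make_pairs([0.1], [0.02], [0.2], [0.05])
        est = wald_ratio(pair, second_order_se=True)
        bx, by, sx, sy = 0.1, 0.2, 0.02, 0.05
        oracle = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
        assert math.isclose(est.se, oracle, rel_tol=1e-12)

    def test_zero_exposure_effect_rejected(self):
        (pair,) = make_pairs([0.0], [0.02], [0.2], [0.05])
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(pair)


class TestIVW:
    def test_single_pair_delegates_to_wald(self):
        pairs = make_pairs([0.1], [0.02], [0.2], [0.05])
        assert ivw(pairs) == wald_ratio(pairs[0])

    def test_equal_weight_average(self):
        # ratio estimates 1 and 3 with unit ratio SE: bx = 1, sy = 1
        pairs = make_pairs([1.0, 1.0], [0.1, 0.1], [1.0, 3.0], [1.0, 1.0])
        est = ivw(pairs, mode="fixed")
        assert math.isclose(est.beta, 2.0, rel_tol=1e-14)
        assert math.isclose(est.se, 1 / math.sqrt(2), rel_tol=1e-14)

    def test_mre_inflates_only_when_overdispersed(self, rng):
        pairs = draw_harmonized(rng, 30, true_beta=0.1)
        fixed = ivw(pairs, mode="fixed")
        mre = ivw(pairs, mode="mre")
        assert mre.beta == fixed.beta
        assert mre.se >= fixed.se
        q = mre.extra["Q"]
        expected = fixed.se * max(1.0, math.sqrt(q / 29))
        assert math.isclose(mre.se, expected, rel_tol=1e-12)


class TestEgger:
    def test_exact_interpolation(self):
        bx = np.array([1.0, 2.0, 3.0])
        by = 0.5 + 1.5 * bx
        pairs = make_pairs(bx, [0.1] * 3, by, [0.1] * 3)
        est = mr_egger(pairs)
        assert math.isclose(est.beta, 1.5, abs_tol=1e-12)
        assert math.isclose(est.extra["intercept"], 0.5, abs_tol=1e-12)

    def test_collinear_design_rejected(self):
        pairs = make_pairs([1.0, 1.0, 1.0], [0.1] * 3, [1.0, 2.0, 3.0], [0.1] * 3)
        with pytest.raises(CollinearityError):
            mr_egger(pairs)

    def test_too_few_snps(self):
        pairs = make_pairs([1.0, 2.0], [0.1] * 2, [1.0, 2.0], [0.1] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(pairs)

    def test_orientation_invariance(self, rng):
        """Flipping the reported effect allele of any SNP (negating both
        betas) must not change the Egger fit."""
        pairs = draw_harmonized(rng, 15, true_beta=0.2)
        est1 = mr_egger(pairs)
        import dataclasses

        flipped = [
            dataclasses.replace(p, beta_exp=-p.beta_exp, beta_out=-p.beta_out)
            if i % 2 == 0
            else p
            for i, p in enumerate(pairs)
        ]
        est2 = mr_egger(flipped)
        assert math.isclose(est1.beta, est2.beta, rel_tol=1e-12)
        assert math.isclose(est1.extra["intercept"], est2.extra["intercept"], rel_tol=1e-12)


class TestWeightedMedian:
    def test_symmetric_median(self):
        pairs = make_pairs([1.0] * 3, [0.1] * 3, [1.0, 2.0, 3.0], [1.0] * 3)
        est = weighted_median(pairs, n_boot=100, seed=0)
        assert math.isclose(est.beta, 2.0, rel_tol=1e-14)

    def test_deterministic_under_seed(self, rng):
        pairs = draw_harmonized(rng, 10, true_beta=0.1)
        a = weighted_median(pairs, n_boot=200, seed=42)
        b = weighted_median(pairs, n_boot=200, seed=42)
        assert a.beta == b.beta and a.se == b.se

    def test_minimum_bootstrap_size(self, rng):
        pairs = draw_harmonized(rng, 5, true_beta=0.1)
        with pytest.raises(ValueError):
            weighted_median(pairs, n_boot=50, seed=0)


class TestMaxLikelihood:
    def test_se_exp_zero_limit_equals_fixed_ivw(self, rng):
        pairs = draw_harmonized(rng, 20, true_beta=0.1)
        import dataclasses

        tiny = [dataclasses.replace(p, se_exp=1e-8) for p in pairs]
        mle = max_likelihood(tiny)
        fixed = ivw(tiny, mode="fixed")
        assert abs(mle.beta - fixed.beta) < 1e-4

    def test_two_consistent_pairs_recover_beta(self):
        beta = 0.7
        bx = np.array([0.1, 0.2])
        by = beta * bx + np.array([1e-5, -1e-5])
        pairs = make_pairs(bx, [0.01, 0.01], by, [0.01, 0.01])
        est = max_likelihood(pairs)
        assert abs(est.beta - beta) < 1e-3

    def test_matches_grid_search(self, rng):
        pairs = draw_harmonized(rng, 20, true_beta=0.3)
        est = max_likelihood(pairs)
        bx = np.array([p.beta_exp for p in pairs])
        sx = np.array([p.se_exp for p in pairs])
        by = np.array([p.beta_out for p in pairs])
        sy = np.array([p.se_out for p in pairs])
        grid = np.arange(-2.0, 2.0, 1e-4)
        nll = [_profile_nll(b, bx, sx, by, sy) for b in grid]
        assert abs(est.beta - grid[int(np.argmin(nll))]) <= 1e-4


class TestRaps:
    def test_l2_no_overdispersion_equals_mle(self, rng):
        pairs = draw_harmonized(rng, 20, true_beta=0.2)
        raps = mr_raps(pairs, loss="l2", overdispersion=False)
        mle = max_likelihood(pairs)
        assert abs(raps.beta - mle.beta) < 1e-4

    def test_huber_resists_planted_outlier(self, rng):
        import dataclasses

        truth = 2.0
        pairs = draw_harmonized(rng, 25, true_beta=truth, gamma_sd=0.1)
        # shift one SNP's outcome effect by 10 ratio units
        p0 = pairs[0]
        pairs[0] = dataclasses.replace(p0, beta_out=p0.beta_out + 10.0 * p0.beta_exp)
        huber = mr_raps(pairs, loss="huber", overdispersion=False)
        l2 = mr_raps(pairs, loss="l2", overdispersion=False)
        assert abs(huber.beta - truth) < abs(l2.beta - truth)

    def test_clean_data_recovery_within_three_se(self, rng):
        pairs = draw_harmonized(rng, 50, true_beta=0.1)
        est = mr_raps(pairs)
        assert abs(est.beta - 0.1) < 3 * est.se


class TestOddsRatioTransform:
    def test_null_effect_symmetric_ci(self):
        (pair,) = make_pairs([0.1], [0.02], [0.0], [0.05])
        est = to_odds_ratio(wald_ratio(pair))
        assert est.or_ == 1.0
        assert math.isclose(est.or_low * est.or_high, 1.0, rel_tol=1e-12)

    def test_negative_effect_values(self):
        import dataclasses

        (pair,) = make_pairs([1.0], [0.01], [-0.5], [0.1])
        est = to_odds_ratio(wald_ratio(pair))
        assert math.isclose(est.or_, math.exp(-0.5), rel_tol=1e-12)
        assert math.isclose(est.or_low, math.exp(-0.5 - 1.959963984540054 * 0.1), rel_tol=1e-12)
        assert math.isclose(est.or_high, math.exp(-0.5 + 1.959963984540054 * 0.1), rel_tol=1e-12)
        assert round(est.or_, 4) == 0.6065


class TestEquivariance:
    @pytest.mark.parametrize("method", ["ivw", "egger", "wm", "mle", "raps_l2", "raps_huber"])
    def test_sign_equivariance(self, rng, method):
        """Negating every outcome effect negates the causal estimate."""
        import dataclasses

        pairs = draw_harmonized(rng, 15, true_beta=0.2)
        mirrored = [dataclasses.replace(p, beta_out=-p.beta_out) for p in pairs]

        def fit(ps):
            if method == "ivw":
                return ivw(ps).beta
            if method == "egger":
                return mr_egger(ps).beta
            if method == "wm":
                return weighted_median(ps, n_boot=100, seed=7).beta
            if method == "mle":
                return max_likelihood(ps).beta
            if method == "raps_l2":
                return mr_raps(ps, loss="l2", overdispersion=False).beta
            return mr_raps(ps, loss="huber", overdispersion=False).beta

        assert abs(fit(pairs) + fit(mirrored)) < 1e-8

    @pytest.mark.parametrize("method", ["ivw", "wm"])
    def test_scale_equivariance(self, rng, method):
        """Multiplying all exposure effects by c divides ratio estimates by c."""
        import dataclasses

        c = 3.0
        pairs = draw_harmonized(rng, 15, true_beta=0.2)
        scaled = [
            dataclasses.replace(p, beta_exp=c * p.beta_exp, se_exp=c * p.se_exp)
            for p in pairs
        ]
        if method == "ivw":
            assert math.isclose(ivw(scaled).beta, ivw(pairs).beta / c, rel_tol=1e-12)
        else:
            a = weighted_median(scaled, n_boot=100, seed=3).beta
            b = weighted_median(pairs, n_boot=100, seed=3).beta
            assert math.isclose(a, b / c, rel_tol=1e-12)
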