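"""Logistic fitting, rate profiles and interaction-constant calibration."""

import numpy as np
import pytest

from clonedyn import (
    GrowthParams,
    InteractionParams,
    ModelParams,
    RateProfile,
    calibrate_interactions,
    calibrate_to_anchor_rates,
    correlation_product,
    fit_logistic,
    interpolated_rate_profile,
)
from clonedyn.rates import CalibrationError, FitError


def logistic(t, n, b, k):
    return n / (1.0 + b * np.exp(-k * t))


DAYS = np.arange(6.0)


class TestFitLogistic:
    def test_recovers_exact_parameters(self):
        y = logistic(DAYS, 6e5, 11.0, 1.0)  # y(0) = 50,000
        fit = fit_logistic(DAYS, y)
        assert fit.k == pytest.approx(1.0, rel=1e-3)
        assert fit.n_fit == pytest.approx(6e5, rel=1e-3)
        assert fit.b == pytest.approx(11.0, rel=1e-2)
        assert fit.rss < 1.0

    @pytest.mark.parametrize("lam", [0.1, 10.0, 1e3])
    def test_scale_equivariance(self, lam):
        """Scaling counts scales the fitted capacity and leaves k, b alone."""
        y = logistic(DAYS, 6e5, 11.0, 1.0)
        base = fit_logistic(DAYS, y)
        scaled = fit_logistic(DAYS, lam * y)
        assert scaled.k == pytest.approx(base.k, rel=1e-6)
        assert scaled.b == pytest.approx(base.b, rel=1e-5)
        assert scaled.n_fit == pytest.approx(lam * base.n_fit, rel=1e-6)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(DAYS, np.zeros_like(DAYS))

    def test_constant_series_is_unidentifiable(self):
        with pytest.raises(FitError):
            fit_logistic(DAYS, np.full_like(DAYS, 6e5))

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_logistic([0, 1, 2], [1.0, 2.0, 4.0])

    def test_mixed_mutualistic_rate_exceeds_pure_rate(self, base_growth):
        """In a mutualistic mixture the sensitive clone's fitted short-term
        rate beats its pure-culture value (the simulation is the oracle)."""
        params = ModelParams(
            base_growth, InteractionParams(1e-6, 1e-6, weighted=False)
        )
        profile = interpolated_rate_profile(params, fractions=(0.0, 0.5))
        assert profile.k_sensitive[1] > profile.k_sensitive[0]


class TestInterpolatedRateProfile:
    def test_pure_fractions_reduce_to_single_clone_rates(self, invitro_growth):
        profile = interpolated_rate_profile(
            ModelParams(invitro_growth), fractions=(0.0, 1.0)
        )
        assert profile.k_sensitive[0] == pytest.approx(1.069, rel=5e-3)
        assert np.isnan(profile.k_sensitive[1])
        assert np.isnan(profile.k_resistant[0])
        assert profile.k_resistant[1] == pytest.approx(0.4695, rel=5e-3)

    def test_noninteracting_sensitive_rate_declines_linearly(self, invitro_growth):
        fractions = np.linspace(0.0, 0.9, 10)
        profile = interpolated_rate_profile(
            ModelParams(invitro_growth), fractions=fractions
        )
        ks = profile.k_sensitive
        assert np.all(np.diff(ks) < 0.0)
        # near-linear: a straight line explains almost all variation
        resid = ks - np.polyval(np.polyfit(fractions, ks, 1), fractions)
        r2 = 1.0 - np.sum(resid**2) / np.sum((ks - ks.mean()) ** 2)
        assert r2 > 0.98

    def test_mutualistic_sensitive_rate_rises_then_falls(self, invitro_growth):
        c_gr, c_rg = calibrate_to_anchor_rates(2.0)
        params = ModelParams(
            invitro_growth, InteractionParams(c_gr, c_rg, m=2.0, weighted=True)
        )
        fractions = np.linspace(0.0, 0.9, 10)
        ks = interpolated_rate_profile(params, fractions=fractions).k_sensitive
        diffs = np.diff(ks)
        assert diffs[0] > 0.0 and diffs[-1] < 0.0
        switch = np.flatnonzero(np.diff(np.sign(diffs)))
        assert len(switch) == 1  # single rise-then-fall turning point


class TestCorrelationProduct:
    def profile(self, ks, kr):
        return RateProfile(np.linspace(0, 1, len(ks)), ks, kr)

    def test_identity_gives_unit_product(self):
        a = self.profile([1.0, 1.2, 1.1, np.nan], [np.nan, 0.5, 0.6, 0.47])
        assert correlation_product(a, a) == pytest.approx((1.0, 1.0, 1.0))

    def test_affine_invariance_and_symmetry(self):
        a = self.profile([1.0, 1.2, 1.1, 0.9], [0.4, 0.5, 0.6, 0.47])
        b = self.profile(
            2.0 * np.array([1.0, 1.2, 1.1, 0.9]) + 0.3,
            0.5 * np.array([0.4, 0.5, 0.6, 0.47]) + 1.0,
        )
        assert correlation_product(a, b) == pytest.approx((1.0, 1.0, 1.0))
        assert correlation_product(b, a) == pytest.approx(correlation_product(a, b))

    def test_reversed_vector_anticorrelates(self):
        # x + reversed(x) constant, so corr(x, reversed(x)) = -1 exactly
        ks = [1.0, 1.1, 1.3, 1.4]
        a = self.profile(ks, [0.4, 0.5, 0.6, 0.7])
        b = self.profile(ks[::-1], [0.4, 0.5, 0.6, 0.7])
        corr_g, corr_r, product = correlation_product(a, b)
        assert corr_g == pytest.approx(-1.0)
        assert product == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        a = self.profile([1.0, 1.2, np.nan, np.nan], [0.4, 0.5, 0.6, 0.7])
        with pytest.raises(ValueError):
            correlation_product(a, a)

    def test_zero_variance_rejected(self):
        a = self.profile([1.0, 1.0, 1.0, 1.0], [0.4, 0.5, 0.6, 0.7])
        with pytest.raises(ValueError):
            correlation_product(a, a)

    def test_mismatched_fraction_grids_rejected(self):
        a = self.profile([1.0, 1.2, 1.1, 0.9], [0.4, 0.5, 0.6, 0.47])
        b = RateProfile([0.0, 0.2, 0.4, 0.8], a.k_sensitive, a.k_resistant)
        with pytest.raises(ValueError):
            correlation_product(a, b)


class TestCalibration:
    GRID = np.round(np.linspace(0.0, 1.0, 6), 10)  # step 0.2, truth on grid

    def test_planted_constants_recovered_exactly(self, invitro_growth):
        truth = (0.4, 0.2)
        params = ModelParams(
            invitro_growth, InteractionParams(*truth, m=2.0, weighted=True)
        )
        obs = interpolated_rate_profile(params)
        res = calibrate_interactions(obs, 2.0, self.GRID, self.GRID, invitro_growth)
        assert (res.c_gr_hat, res.c_rg_hat) == truth
        assert res.corr_product == pytest.approx(1.0, abs=1e-12)

    def test_null_model_recovered(self, invitro_growth):
        obs = interpolated_rate_profile(
            ModelParams(invitro_growth, InteractionParams(0.0, 0.0, weighted=True))
        )
        res = calibrate_interactions(obs, 1.0, self.GRID, self.GRID, invitro_growth)
        assert res.c_gr_hat == 0.0 and res.c_rg_hat == 0.0

    def test_reported_optimum_dominates_rescan(self, invitro_growth):
        truth = (0.4, 0.2)
        params = ModelParams(
            invitro_growth, InteractionParams(*truth, m=2.0, weighted=True)
        )
        obs = interpolated_rate_profile(params)
        res = calibrate_interactions(
            obs, 2.0, self.GRID, self.GRID, invitro_growth, keep_table=True
        )
        table = res.table.dropna()
        assert res.corr_product >= table["product"].max() - 1e-12

    def test_no_positive_point_signals(self, invitro_growth):
        # Observed shapes opposite to every searched model's: sensitive
        # rates falling where the simulated ones rise, resistant rates
        # rising where the simulated ones fall.
        obs = RateProfile(
            np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
            np.array([1.3, 1.2, 1.1, 1.0, np.nan]),
            np.array([np.nan, 0.4, 0.5, 0.6, 0.9]),
        )
        grid = np.array([0.3, 0.6])
        with pytest.raises(CalibrationError):
            calibrate_interactions(obs, 2.0, grid, grid, invitro_growth)


class TestAnchorCalibration:
    def test_deterministic_and_nonnegative(self):
        a = calibrate_to_anchor_rates(2.0)
        b = calibrate_to_anchor_rates(2.0)
        assert a == b
        assert a[0] >= 0.0 and a[1] >= 0.0

    def test_mixture_rates_move_toward_anchors(self, invitro_growth):
        """Calibrated constants move the 1:1 mixture rates toward the printed
        maxima (the sensitive rate up; the resistant one down -- shared-
        capacity crowding alone already overshoots the resistant anchor)."""
        c_gr, c_rg = calibrate_to_anchor_rates(2.0)
        params = ModelParams(
            invitro_growth, InteractionParams(c_gr, c_rg, m=2.0, weighted=True)
        )
        prof = interpolated_rate_profile(params, fractions=(0.0, 0.5, 1.0))
        base = interpolated_rate_profile(
            ModelParams(invitro_growth), fractions=(0.0, 0.5, 1.0)
        )
        # closer to each printed anchor than the non-interacting model gets
        assert abs(prof.k_sensitive[1] - 1.191) < abs(base.k_sensitive[1] - 1.191)
        assert abs(prof.k_resistant[1] - 0.6045) < abs(base.k_resistant[1] - 0.6045)
        assert prof.k_sensitive[1] == pytest.approx(1.191, rel=0.05)
        assert prof.k_resistant[1] == pytest.approx(0.6045, rel=0.05)
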