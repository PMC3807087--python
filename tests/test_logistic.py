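import numpy as np
import pytest

from roseshoot import (LogisticFitResult, OrganSeries, expansion_duration,
                       fit_logistic, leaflet_internode_offsets, logistic_length,
                       time_at_fraction)
from roseshoot.logistic import observed_final_length


def make_series(l_max=57.8, t_mid=154.3, w=5.93e-3, n=19, t_lo=20.0, t_hi=500.0,
                noise_sd=0.0, seed=0, kind="lea", rank=0.5):
    t = np.linspace(t_lo, t_hi, n)
    L = logistic_length(t, l_max, t_mid, w)
    if noise_sd > 0:
        L = np.clip(L + np.random.default_rng(seed).normal(0, noise_sd, n), 0, None)
    return OrganSeries("p", kind, rank, t, L)


def make_fit(l_max, t_mid, w, kind="lea", rank=0.5):
    return LogisticFitResult("p", kind, rank, l_max=l_max, t_mid=t_mid,
                             v_max=w * l_max, w_max=w, n_obs=19)


class TestFitLogistic:
    def test_noise_free_recovery(self):
        fit = fit_logistic(make_series())
        assert fit.l_max == pytest.approx(57.8, rel=1e-6)
        assert fit.t_mid == pytest.approx(154.3, rel=1e-6)
        assert fit.w_max == pytest.approx(5.93e-3, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.rmse == pytest.approx(0.0, abs=1e-8)

    def test_w_is_v_over_l_identity(self):
        fit = fit_logistic(make_series(noise_sd=1.0, seed=3))
        assert fit.w_max == fit.v_max / fit.l_max  # exact identity

    def test_curve_at_t_mid_is_half_final(self):
        fit = fit_logistic(make_series())
        assert logistic_length(fit.t_mid, fit.l_max, fit.t_mid, fit.w_max) \
            == pytest.approx(fit.l_max / 2)

    def test_sub_threshold_series_excluded(self):
        series = make_series(l_max=10.0, t_mid=100.0, w=9e-3, kind="int", rank=0.1)
        fit = fit_logistic(series)
        assert fit.excluded
        assert fit.l_max is None
        assert "12" in fit.reason

    def test_too_few_points_errors(self):
        s = make_series(n=4)
        with pytest.raises(ValueError):
            fit_logistic(s)

    def test_noisy_recovery_median_error(self):
        """Median relative error of l_max < 2% over 200 replicates (sd 1 mm)."""
        errs = []
        for seed in range(200):
            fit = fit_logistic(make_series(noise_sd=1.0, seed=seed))
            errs.append(abs(fit.l_max - 57.8) / 57.8)
        assert np.median(errs) < 0.02


class TestObservedFinalLength:
    def test_plateau_mean_ignores_rectified_noise(self):
        # flat 10.9 mm organ with one noisy reading at 13 must stay sub-threshold
        L = np.array([10.0, 11.0, 13.0, 11.0, 11.0, 10.0])
        assert observed_final_length(L) < 12.0

    def test_short_series_uses_all(self):
        assert observed_final_length([5.0, 7.0]) == pytest.approx(6.0)


class TestExpansionDuration:
    @pytest.mark.parametrize("w,expected", [(5.96e-3, 184.3), (9.04e-3, 121.5)])
    def test_ten_to_ninety_duration(self, w, expected):
        fit = make_fit(60.0, 200.0, w)
        assert expansion_duration(fit) == pytest.approx(expected, abs=0.05)

    def test_matches_numeric_inversion(self):
        from scipy.optimize import brentq
        fit = make_fit(57.8, 154.3, 5.93e-3)
        t10 = brentq(lambda t: logistic_length(t, 57.8, 154.3, 5.93e-3) - 5.78,
                     -2000, 3000, xtol=1e-10)
        t90 = brentq(lambda t: logistic_length(t, 57.8, 154.3, 5.93e-3) - 0.9 * 57.8,
                     -2000, 3000, xtol=1e-10)
        assert expansion_duration(fit) == pytest.approx(t90 - t10, abs=1e-6)

    def test_doubling_w_halves_duration(self):
        assert expansion_duration(make_fit(60, 200, 4e-3)) == pytest.approx(
            2 * expansion_duration(make_fit(60, 200, 8e-3)))

    def test_excluded_fit_errors(self):
        bad = LogisticFitResult("p", "int", 0.1, excluded=True)
        with pytest.raises(ValueError):
            expansion_duration(bad)


class TestOffsets:
    def test_identical_fits_zero_offsets(self):
        a = make_fit(57.8, 154.3, 5.93e-3)
        assert leaflet_internode_offsets(a, a) == pytest.approx((0.0, 0.0))

    def test_nested_internode_window_positive_offsets(self):
        lea = make_fit(57.8, 160.0, 5.93e-3)
        internode = make_fit(17.9, 165.0, 8.66e-3, kind="int")
        start, end = leaflet_internode_offsets(lea, internode)
        assert start > 0 and end > 0

    def test_against_dense_grid_scan_oracle(self):
        lea = make_fit(57.8, 160.0, 5.93e-3)
        internode = make_fit(17.9, 165.0, 8.66e-3, kind="int")
        t = np.linspace(-500, 900, 2_000_001)

        def crossing(fit, q):
            L = logistic_length(t, fit.l_max, fit.t_mid, fit.w_max)
            return t[np.searchsorted(L, q * fit.l_max)]

        start = crossing(internode, 0.1) - crossing(lea, 0.1)
        end = crossing(lea, 0.9) - crossing(internode, 0.9)
        got = leaflet_internode_offsets(lea, internode)
        assert got[0] == pytest.approx(start, abs=0.01)
        assert got[1] == pytest.approx(end, abs=0.01)

    def test_time_at_fraction_bounds(self):
        fit = make_fit(57.8, 154.3, 5.93e-3)
        with pytest.raises(ValueError):
            time_at_fraction(fit, 1.0)
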