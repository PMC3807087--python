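import numpy as np
import pytest

from roseshoot import (EvalConfig, OrganSeries, PredictedCurve, loo_crossvalidate,
                       msep, truncate_plateau)


def make_obs(lengths, t0=0.0, dt=20.0, kind="lea", rank=0.5):
    lengths = np.asarray(lengths, dtype=float)
    t = t0 + dt * np.arange(len(lengths))
    return OrganSeries("p", kind, rank, t, lengths)


class TestTruncatePlateau:
    def test_keeps_first_four_plateau_points(self):
        series = make_obs([10, 30, 40, 50, 58] + [60] * 10)
        out = truncate_plateau(series, final_length=60.0)
        assert len(out.t) == 9  # 5 below 0.97*60 + first 4 plateau points
        assert np.array_equal(out.t, series.t[:9])

    def test_short_plateau_unchanged(self):
        series = make_obs([10, 30, 50, 59, 60, 60, 60])
        out = truncate_plateau(series, final_length=60.0)
        assert np.array_equal(out.t, series.t)

    def test_all_below_threshold_unchanged(self):
        series = make_obs([5, 10, 20, 40])
        out = truncate_plateau(series, final_length=60.0)
        assert np.array_equal(out.length, series.length)

    def test_threshold_boundary_is_kept(self):
        # a point exactly at 0.97 * final counts as pre-plateau
        series = make_obs([0.97 * 60] * 6 + [60] * 6)
        out = truncate_plateau(series, final_length=60.0)
        assert len(out.t) == 10


class TestMSEP:
    def test_perfect_prediction_zero(self):
        series = make_obs([10, 30, 50, 58, 60, 60])
        curve = PredictedCurve("p", "lea", 0.5, 60.0, w=6e-3, t_mid=40.0)
        obs = make_obs(curve(series.t))
        assert msep(obs, curve, 60.0).msep == pytest.approx(0.0, abs=1e-20)

    def test_constant_offset_squares(self):
        curve = PredictedCurve("p", "lea", 0.5, 60.0, w=6e-3, t_mid=40.0)
        t = np.arange(0, 200, 20.0)
        obs = OrganSeries("p", "lea", 0.5, t, curve(t) + 2.0)
        rec = msep(obs, curve, final_length=100.0)  # no truncation triggered
        assert rec.msep == pytest.approx(4.0)
        assert rec.n_used == len(t)

    def test_three_point_brute_force(self):
        curve = PredictedCurve("p", "int", 0.5, 20.0, w=9e-3, t_mid=100.0)
        obs = make_obs([4.0, 11.0, 18.0], t0=50.0, dt=50.0, kind="int")
        rec = msep(obs, curve, final_length=20.0)
        expected = np.mean([(4.0 - curve(50.0)) ** 2,
                            (11.0 - curve(100.0)) ** 2,
                            (18.0 - curve(150.0)) ** 2])
        assert rec.msep == pytest.approx(expected)


class TestLeaveOneOut:
    def test_noise_free_s0_near_zero(self, small_noise_free_crop):
        crop, _ = small_noise_free_crop
        report = loo_crossvalidate(crop, "s0")
        assert report.rmsep_pooled["lea"] < 0.5
        assert report.rmsep_pooled["int"] < 0.5

    def test_noise_free_s2_stays_away_from_zero(self, small_noise_free_crop):
        # identical kinetics per rank, but phytomer counts still differ
        crop, _ = small_noise_free_crop
        report = loo_crossvalidate(crop, "s2")
        assert report.rmsep_pooled["lea"] > 0.5
        assert report.rmsep_pooled["int"] > 0.5

    def test_pooled_rmsep_matches_brute_force(self, default_crop, default_crop_fits):
        crop, _ = default_crop
        report = loo_crossvalidate(crop, "s1", fits=default_crop_fits)
        for kind in ("lea", "int"):
            msep_vals = [r.msep for r in report.records if r.kind == kind]
            assert report.rmsep_pooled[kind] == pytest.approx(
                np.sqrt(np.mean(msep_vals)))

    def test_rank_rmsep_matches_brute_force(self, default_crop, default_crop_fits):
        from roseshoot import rounded_rank
        crop, _ = default_crop
        report = loo_crossvalidate(crop, "s1", fits=default_crop_fits)
        for (kind, rr), value in report.rmsep_by_rounded_rank.items():
            vals = [r.msep for r in report.records
                    if r.kind == kind and rounded_rank(r.relative_rank) == rr]
            assert value == pytest.approx(np.sqrt(np.mean(vals)))

    def test_percent_final_denominator(self, default_crop, default_crop_fits):
        crop, _ = default_crop
        fits = default_crop_fits
        report = loo_crossvalidate(crop, "s1", fits=fits)
        keep = fits.organ_fits[~fits.organ_fits["excluded"]]
        for kind in ("lea", "int"):
            mean_final = keep[keep["kind"] == kind]["final_observed"].mean()
            assert report.rmsep_pct_final[kind] == pytest.approx(
                100 * report.rmsep_pooled[kind] / mean_final)

    def test_too_few_plants_rejected(self, small_noise_free_crop):
        crop, _ = small_noise_free_crop
        tiny = type(crop)(
            lengths=crop.lengths[crop.lengths["plant_id"].isin(["p000", "p001"])],
            appearance=crop.appearance[crop.appearance["plant_id"].isin(["p000", "p001"])],
            metadata=crop.metadata[crop.metadata["plant_id"].isin(["p000", "p001"])],
        )
        with pytest.raises(ValueError):
            loo_crossvalidate(tiny, "s0")

    def test_excluded_organs_carry_no_records(self, default_crop, default_crop_fits):
        crop, _ = default_crop
        report = loo_crossvalidate(crop, "s0", fits=default_crop_fits)
        fits = default_crop_fits.organ_fits
        excluded = set(map(tuple, fits[fits["excluded"]]
                           [["plant_id", "kind", "relative_rank"]].to_numpy()))
        for r in report.records:
            assert (r.plant_id, r.kind, r.relative_rank) not in excluded


def test_eval_config_simplified_w(default_crop, default_crop_fits):
    """The three-value w variant changes little: durations are near-stable."""
    crop, _ = default_crop
    full = loo_crossvalidate(crop, "s0", fits=default_crop_fits)
    simp = loo_crossvalidate(crop, "s0", EvalConfig(simplified_w=True),
                             fits=default_crop_fits)
    for kind in ("lea", "int"):
        assert simp.rmsep_pooled[kind] == pytest.approx(
            full.rmsep_pooled[kind], rel=0.5)
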