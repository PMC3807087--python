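"""Leave-one-out cross-validation with plateau-truncated (R)MSEP.

For each held-out plant, the crop-level components (rank profiles of w, t0
and L_m, and the coordination polynomials) are re-estimated from the
remaining plants; the held-out plant contributes only its own scenario
inputs (appearance times, observed finals, phytomer count).  Prediction
error per organ is the mean squared deviation over its observations, after
keeping at most four observations beyond 97 % of final length so the plateau
does not dominate.  RMSEP is the square root of MSEP averaged over organs,
reported per rounded rank, pooled per organ kind, and as a percentage of the
kind's mean observed final length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .appearance import fit_appearance
from .coordination import fit_coordination
from .io import Crop
from .logistic import (MIN_FINAL_LENGTH_MM, OrganSeries, fit_logistic,
                       observed_final_length)
from .profiles import RankProfile, smooth_profile, ProfileSet
from .scenarios import PredictedCurve, ScenarioInputs, simulate_s0, simulate_s1, simulate_s2
from .topology import rounded_rank

__all__ = ["EvalConfig", "MSEPRecord", "CVReport", "truncate_plateau", "msep",
           "CropFits", "fit_crop", "loo_crossvalidate"]


@dataclass(frozen=True)
class EvalConfig:
    simplified_w: bool = False
    plateau_threshold: float = 0.97
    plateau_keep: int = 4
    loess_span: float = 0.5
    loess_degree: int = 2
    min_final_mm: float = MIN_FINAL_LENGTH_MM
    min_obs: int = 5


@dataclass(frozen=True)
class MSEPRecord:
    plant_id: str
    kind: str
    relative_rank: float
    msep: float  # mm²
    n_used: int


@dataclass
class CVReport:
    scenario: str
    records: list
    rmsep_by_rounded_rank: dict  # (kind, rounded rank) -> mm
    rmsep_pooled: dict           # kind -> mm
    rmsep_pct_final: dict        # kind -> % of mean observed final length
    issues: list = field(default_factory=list)

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def to_json_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "rmsep_pooled_mm": self.rmsep_pooled,
            "rmsep_pct_final": self.rmsep_pct_final,
            "rmsep_by_rounded_rank_mm": {
                f"{k}@{r:.1f}": v for (k, r), v in self.rmsep_by_rounded_rank.items()
            },
            "n_records": len(self.records),
            "issues": self.issues,
        }


def truncate_plateau(series: OrganSeries, final_length: float,
                     threshold: float = 0.97, keep: int = 4) -> OrganSeries:
    """Drop plateau observations beyond the first ``keep`` above threshold.

    Observations with length <= threshold * final_length are all kept; of
    those above, only the first ``keep`` in chronological order remain.
    """
    if final_length <= 0:
        raise ValueError("final_length must be > 0")
    order = np.argsort(series.t)
    t, L = series.t[order], series.length[order]
    above = L > threshold * final_length
    keep_mask = ~above
    keep_mask[np.nonzero(above)[0][:keep]] = True
    return OrganSeries(series.plant_id, series.kind, series.relative_rank,
                       t[keep_mask], L[keep_mask])


def msep(obs: OrganSeries, pred: PredictedCurve, final_length: float,
         threshold: float = 0.97, keep: int = 4) -> MSEPRecord:
    """Mean squared prediction error over the plateau-truncated series."""
    trunc = truncate_plateau(obs, final_length, threshold=threshold, keep=keep)
    if len(trunc.t) == 0:
        raise ValueError("no observations left after plateau truncation")
    err = trunc.length - pred(trunc.t)
    return MSEPRecord(obs.plant_id, obs.kind, obs.relative_rank,
                      float(np.mean(err**2)), len(trunc.t))


@dataclass
class CropFits:
    """Cached per-plant estimates reused across cross-validation folds."""

    organ_fits: pd.DataFrame      # plant_id, kind, relative_rank, fitted params
    appearance_models: dict       # plant_id -> AppearanceModel (or None)
    issues: list


def fit_crop(crop: Crop, config: EvalConfig = EvalConfig()) -> CropFits:
    """Fit every organ's logistic and every plant's appearance model once.

    These estimates depend only on the plant's own data, so they are
    computed once and shared by all leave-one-out folds.
    """
    issues = []
    rows = []
    for series in crop.organ_series():
        final_obs = observed_final_length(series.length)
        if final_obs < config.min_final_mm:
            rows.append((series.plant_id, series.kind, series.relative_rank,
                         np.nan, np.nan, np.nan, final_obs, True, False))
            continue
        if len(series.t) < config.min_obs:
            issues.append(f"{series.plant_id} {series.kind}@{series.relative_rank:.3f}: "
                          f"only {len(series.t)} observations; organ skipped")
            continue
        fit = fit_logistic(series, min_obs=config.min_obs,
                           exclusion_threshold=config.min_final_mm)
        if not fit.converged:
            issues.append(f"{series.plant_id} {series.kind}@{series.relative_rank:.3f}: "
                          f"{fit.reason}")
            continue
        rows.append((series.plant_id, series.kind, series.relative_rank,
                     fit.l_max, fit.t_mid, fit.w_max, final_obs, False, True))
    organ_fits = pd.DataFrame(rows, columns=["plant_id", "kind", "relative_rank",
                                             "l_max", "t_mid", "w_max",
                                             "final_observed", "excluded", "fitted"])
    appearance_models = {}
    for pid, grp in crop.appearance.groupby("plant_id"):
        try:
            appearance_models[pid] = fit_appearance(
                (grp["relative_rank"].to_numpy(), grp["t_first_seen_cd"].to_numpy())
            )
        except ValueError as exc:
            appearance_models[pid] = None
            issues.append(f"{pid}: appearance fit failed ({exc})")
    return CropFits(organ_fits, appearance_models, issues)


def _smooth_with_peduncle(veg: pd.DataFrame, ped: pd.DataFrame, col: str,
                          config: EvalConfig, name: str) -> RankProfile:
    """LOESS over vegetative internodes; the peduncle is its own knot.

    The peduncle (i = 1) sits next to the short sub-peduncle internode with
    a genuine discontinuity in every parameter, so it must not be smoothed
    together with the vegetative gradient: its knot is the plain mean of the
    peduncle estimates.
    """
    prof = smooth_profile((veg["relative_rank"].to_numpy(), veg[col].to_numpy()),
                          span=config.loess_span, degree=config.loess_degree,
                          name=name)
    if len(ped) == 0:
        return prof
    knots_i = np.append(prof.knots_i[prof.knots_i < 1.0], 1.0)
    knots_v = np.append(prof.knots_v[prof.knots_i < 1.0], float(ped[col].mean()))
    return RankProfile(knots_i, knots_v, name=name)


def _fold_profiles(train_fits: pd.DataFrame, config: EvalConfig) -> ProfileSet:
    """Crop-level rank profiles re-estimated from the training plants."""
    profs = {}
    for kind in ("lea", "int"):
        sub = train_fits[train_fits["kind"] == kind]
        fitted = sub[sub["fitted"]]
        if kind == "lea":
            profs["w_lea"] = smooth_profile(
                (fitted["relative_rank"].to_numpy(), fitted["w_max"].to_numpy()),
                span=config.loess_span, degree=config.loess_degree, name="w_lea")
            profs["t0_lea"] = smooth_profile(
                (fitted["relative_rank"].to_numpy(), fitted["t_mid"].to_numpy()),
                span=config.loess_span, degree=config.loess_degree, name="t0_lea")
            # final lengths: observed finals, including sub-12-mm organs
            profs["lm_lea"] = smooth_profile(
                (sub["relative_rank"].to_numpy(), sub["final_observed"].to_numpy()),
                span=config.loess_span, degree=config.loess_degree, name="lm_lea")
        else:
            fveg = fitted[fitted["relative_rank"] < 1]
            fped = fitted[fitted["relative_rank"] == 1]
            profs["w_int"] = _smooth_with_peduncle(fveg, fped, "w_max", config, "w_int")
            profs["t0_int"] = _smooth_with_peduncle(fveg, fped, "t_mid", config, "t0_int")
            profs["lm_int"] = _smooth_with_peduncle(
                sub[sub["relative_rank"] < 1], sub[sub["relative_rank"] == 1],
                "final_observed", config, "lm_int")
    return ProfileSet(**profs)


def _fold_coordination(train_fits: pd.DataFrame, fits: CropFits):
    pairs = []
    for _, row in train_fits[train_fits["fitted"]].iterrows():
        model = fits.appearance_models.get(row["plant_id"])
        if model is None:
            continue
        t_app = max(float(model(row["relative_rank"])), 0.0)
        pairs.append((row["kind"], row["relative_rank"], t_app, row["t_mid"]))
    return fit_coordination(pd.DataFrame(pairs, columns=["kind", "relative_rank",
                                                         "t_app", "t_mid"]))


def _plant_inputs(crop: Crop, fits: CropFits, pid: str) -> ScenarioInputs:
    app = crop.appearance[crop.appearance["plant_id"] == pid]
    appearance = dict(zip(app["relative_rank"], app["t_first_seen_cd"]))
    sub = fits.organ_fits[fits.organ_fits["plant_id"] == pid]
    finals = {"lea": {}, "int": {}}
    for _, row in sub.iterrows():
        finals[row["kind"]][float(row["relative_rank"])] = float(row["final_observed"])
    return ScenarioInputs(plant_id=pid, n_phytomers=crop.n_phytomers(pid),
                          appearance=appearance, final_lea=finals["lea"],
                          final_int=finals["int"])


def loo_crossvalidate(crop: Crop, scenario: str, config: EvalConfig = EvalConfig(),
                      fits: Optional[CropFits] = None) -> CVReport:
    """Leave-one-out evaluation of a scenario over a whole crop."""
    if scenario not in ("s0", "s1", "s2"):
        raise ValueError(f"unknown scenario {scenario!r}")
    plant_ids = crop.plant_ids
    if len(plant_ids) < 3:
        raise ValueError("need at least 3 plants for leave-one-out evaluation")
    if fits is None:
        fits = fit_crop(crop, config)
    issues = list(fits.issues)

    series_by_key = {}
    for s in crop.organ_series():
        series_by_key[(s.plant_id, s.kind, round(s.relative_rank, 6))] = s

    records = []
    for pid in plant_ids:
        train = fits.organ_fits[fits.organ_fits["plant_id"] != pid]
        try:
            profiles = _fold_profiles(train, config)
        except ValueError as exc:
            issues.append(f"fold {pid}: profile estimation failed ({exc})")
            continue
        log: list = []
        inputs = _plant_inputs(crop, fits, pid)
        if scenario == "s0":
            coord, _ = _fold_coordination(train, fits)
            curves = simulate_s0(inputs, coord, profiles, simplified=config.simplified_w,
                                 appearance_model=fits.appearance_models.get(pid), log=log)
        elif scenario == "s1":
            curves = simulate_s1(inputs, profiles, simplified=config.simplified_w, log=log)
        else:
            curves = simulate_s2(inputs.n_phytomers, profiles, plant_id=pid,
                                 simplified=config.simplified_w, log=log)
        issues.extend(log)
        for curve in curves:
            if curve.constant:
                continue  # sub-12-mm organs carry no MSEP
            key = (pid, curve.kind, round(curve.relative_rank, 6))
            obs = series_by_key.get(key)
            if obs is None:
                continue
            final = observed_final_length(obs.length)
            if final < config.min_final_mm:
                continue
            records.append(msep(obs, curve, final, threshold=config.plateau_threshold,
                                keep=config.plateau_keep))

    by_rank: dict = {}
    pooled: dict = {}
    pct: dict = {}
    rec_df = pd.DataFrame([asdict(r) for r in records])
    if not rec_df.empty:
        rec_df["rounded"] = rec_df["relative_rank"].map(rounded_rank)
        for (kind, rr), grp in rec_df.groupby(["kind", "rounded"]):
            by_rank[(kind, float(rr))] = float(np.sqrt(grp["msep"].mean()))
        finals = fits.organ_fits[~fits.organ_fits["excluded"]]
        for kind, grp in rec_df.groupby("kind"):
            pooled[kind] = float(np.sqrt(grp["msep"].mean()))
            mean_final = float(finals[finals["kind"] == kind]["final_observed"].mean())
            pct[kind] = 100.0 * pooled[kind] / mean_final
    return CVReport(scenario=scenario, records=records, rmsep_by_rounded_rank=by_rank,
                    rmsep_pooled=pooled, rmsep_pct_final=pct, issues=issues)
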