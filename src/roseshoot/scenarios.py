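"""Simulation scenarios S0, S1, S2 for predicted organ-expansion curves.

All three scenarios predict every organ of a plant as a logistic of thermal
time; they differ in how much per-plant information enters:

* **S0** (reference): per-plant leaf-appearance times and observed final
  lengths.  Appearance observations are fitted with the two-phase model,
  adjusted appearance times (including the peduncle's virtual leaf) are
  mapped through the coordination polynomials to per-organ t0; w comes from
  the crop-level rank profile.
* **S1**: per-plant final lengths only; t0 is read from the crop-level t0
  rank profile (timing no longer varies between plants).
* **S2**: phytomer count only; final length, t0 and w all come from the
  rank profiles (a "mean plant" per phytomer count).

Organs whose final length is below 12 mm are carried as constant-length
curves (flagged) — they are never fitted or scored.  A ``simplified``
switch replaces the w profile with the three class-level constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .appearance import AppearanceModel, adjusted_appearance, fit_appearance
from .coordination import CoordinationParams, predict_t_mid
from .logistic import MIN_FINAL_LENGTH_MM, logistic_length
from .profiles import ProfileSet, simplified_w
from .topology import relative_rank

__all__ = ["ScenarioInputs", "PredictedCurve", "simulate_s0", "simulate_s1",
           "simulate_s2", "curves_to_frame"]


@dataclass(frozen=True)
class ScenarioInputs:
    """Per-plant, non-destructive model inputs.

    ``appearance`` maps relative rank -> first-seen time (°Cd); required for
    S0 only.  ``final_lea`` / ``final_int`` map relative rank -> observed
    final length (mm); required for S0/S1.  Rank keys must be consistent
    with ``n_phytomers``.
    """

    plant_id: str
    n_phytomers: int
    appearance: Optional[dict] = None
    final_lea: Optional[dict] = None
    final_int: Optional[dict] = None

    def ranks(self) -> np.ndarray:
        n = self.n_phytomers
        return np.array([relative_rank(r, n) for r in range(1, n + 1)])


@dataclass(frozen=True)
class PredictedCurve:
    """One organ's predicted expansion curve (logistic or flagged constant)."""

    plant_id: str
    kind: str
    relative_rank: float
    l_max: float                  # mm
    w: Optional[float] = None     # °Cd⁻¹; None for constant curves
    t_mid: Optional[float] = None  # °Cd
    constant: bool = False        # sub-12-mm organ held at final length

    def __call__(self, t):
        if self.constant:
            out = np.full_like(np.asarray(t, dtype=float), self.l_max)
            return float(out) if np.ndim(t) == 0 else out
        return logistic_length(t, self.l_max, self.t_mid, self.w)


def _make_curve(plant_id, kind, i, l_max, w, t_mid) -> PredictedCurve:
    if l_max < MIN_FINAL_LENGTH_MM:
        return PredictedCurve(plant_id, kind, i, l_max, constant=True)
    return PredictedCurve(plant_id, kind, i, l_max, w=w, t_mid=t_mid)


def _w_for(kind: str, i: float, profiles: ProfileSet, simplified: bool):
    if simplified:
        return simplified_w(kind, is_peduncle=(kind == "int" and i == 1))
    prof = profiles.w(kind)
    if not prof.covers(i):
        return None
    return prof(i)


def simulate_s0(inputs: ScenarioInputs, coord: CoordinationParams,
                profiles: ProfileSet, simplified: bool = False,
                appearance_model: Optional[AppearanceModel] = None,
                log: Optional[list] = None):
    """Reference scenario: per-plant appearance times + observed finals."""
    if inputs.appearance is None or inputs.final_lea is None or inputs.final_int is None:
        raise ValueError("S0 requires appearance times and final lengths")
    log = log if log is not None else []
    if appearance_model is None:
        items = sorted(inputs.appearance.items())
        try:
            appearance_model = fit_appearance(
                (np.array([k for k, _ in items]), np.array([v for _, v in items]))
            )
        except ValueError as exc:
            log.append(f"{inputs.plant_id}: appearance fit failed ({exc}); plant skipped")
            return []
    curves = []
    for kind, finals in (("lea", inputs.final_lea), ("int", inputs.final_int)):
        for i, l_max in sorted(finals.items()):
            if l_max < MIN_FINAL_LENGTH_MM:
                curves.append(PredictedCurve(inputs.plant_id, kind, i, l_max, constant=True))
                continue
            w = _w_for(kind, i, profiles, simplified)
            if w is None:
                log.append(f"{inputs.plant_id}: {kind} rank {i:.3f} outside w profile; skipped")
                continue
            t_app = adjusted_appearance(appearance_model, i)
            t_mid = predict_t_mid(coord, kind, i, max(t_app, 0.0))
            curves.append(_make_curve(inputs.plant_id, kind, i, l_max, w, t_mid))
    return curves


def simulate_s1(inputs: ScenarioInputs, profiles: ProfileSet,
                simplified: bool = False, log: Optional[list] = None):
    """Final lengths only; mid-expansion time depends on rank, not plant."""
    if inputs.final_lea is None or inputs.final_int is None:
        raise ValueError("S1 requires final lengths")
    log = log if log is not None else []
    curves = []
    for kind, finals in (("lea", inputs.final_lea), ("int", inputs.final_int)):
        t0_prof = profiles.t0(kind)
        for i, l_max in sorted(finals.items()):
            if l_max < MIN_FINAL_LENGTH_MM:
                curves.append(PredictedCurve(inputs.plant_id, kind, i, l_max, constant=True))
                continue
            w = _w_for(kind, i, profiles, simplified)
            if w is None or not t0_prof.covers(i):
                log.append(f"{inputs.plant_id}: {kind} rank {i:.3f} outside profiles; skipped")
                continue
            curves.append(_make_curve(inputs.plant_id, kind, i, l_max, w, t0_prof(i)))
    return curves


def simulate_s2(n_phytomers: int, profiles: ProfileSet, plant_id: str = "mean",
                simplified: bool = False, log: Optional[list] = None):
    """Mean plant for a given phytomer count; all parameters from profiles."""
    if n_phytomers < 2:
        raise ValueError("n_phytomers must be >= 2")
    log = log if log is not None else []
    curves = []
    ranks = np.array([relative_rank(r, n_phytomers) for r in range(1, n_phytomers + 1)])
    for kind in ("lea", "int"):
        lm_prof, t0_prof = profiles.lm(kind), profiles.t0(kind)
        kind_ranks = ranks[ranks < 1] if kind == "lea" else ranks
        for i in kind_ranks:
            if not lm_prof.covers(i):
                log.append(f"{plant_id}: {kind} rank {i:.3f} outside L_m profile; skipped")
                continue
            l_max = lm_prof(i)
            if l_max < MIN_FINAL_LENGTH_MM:
                curves.append(PredictedCurve(plant_id, kind, float(i), l_max, constant=True))
                continue
            w = _w_for(kind, float(i), profiles, simplified)
            if w is None or not t0_prof.covers(i):
                log.append(f"{plant_id}: {kind} rank {i:.3f} outside w/t0 profiles; skipped")
                continue
            curves.append(_make_curve(plant_id, kind, float(i), l_max, w, t0_prof(i)))
    return curves


def curves_to_frame(curves, t_grid) -> pd.DataFrame:
    """Evaluate curves on a thermal-time grid into a long predictions table."""
    t_grid = np.asarray(t_grid, dtype=float)
    rows = []
    for c in curves:
        L = c(t_grid)
        for t, y in zip(t_grid, L):
            rows.append((c.plant_id, c.kind, c.relative_rank, t, y))
    return pd.DataFrame(rows, columns=["plant_id", "kind", "relative_rank",
                                       "t_cd", "length_pred_mm"])
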