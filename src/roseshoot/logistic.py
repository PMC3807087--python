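"""Symmetric logistic fits to single-organ expansion time courses.

Each organ (terminal leaflet or internode, the peduncle counting as the
topmost internode) is fitted with

    L(t) = L_m / (1 + exp(4 * (v_m / L_m) * (t0 - t)))

where L_m is the final length (mm), t0 the thermal time at the inflexion
point ("mid-expansion"), and v_m the maximal expansion rate (mm/°Cd).  The
normalised maximal rate w_m = v_m / L_m (°Cd⁻¹) is inversely proportional to
the 10–90 % expansion duration: duration = ln(81) / (4 w_m).

Organs whose final length never exceeds 12 mm (basal scale-bearing internodes
and the occasional sub-peduncle internode) cannot be fitted accurately at
ruler resolution and are flagged as excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "OrganSeries",
    "LogisticFitResult",
    "logistic_length",
    "observed_final_length",
    "fit_logistic",
    "expansion_duration",
    "time_at_fraction",
    "leaflet_internode_offsets",
    "MIN_FINAL_LENGTH_MM",
]

#: Organs with final length below this are excluded from kinetic fitting.
MIN_FINAL_LENGTH_MM = 12.0

LEAFLET = "lea"
INTERNODE = "int"


@dataclass(frozen=True)
class OrganSeries:
    """Time course of one organ's length (thermal time °Cd, length mm)."""

    plant_id: str
    kind: str  # "lea" or "int"; the peduncle is "int" at relative rank 1
    relative_rank: float
    t: np.ndarray
    length: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in (LEAFLET, INTERNODE):
            raise ValueError(f"unknown organ kind {self.kind!r}")
        t = np.asarray(self.t, dtype=float)
        L = np.asarray(self.length, dtype=float)
        if t.shape != L.shape or t.ndim != 1:
            raise ValueError("t and length must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any(L < 0):
            raise ValueError("negative organ length")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "length", L)


@dataclass(frozen=True)
class LogisticFitResult:
    plant_id: str
    kind: str
    relative_rank: float
    l_max: Optional[float] = None   # mm
    t_mid: Optional[float] = None   # °Cd
    v_max: Optional[float] = None   # mm/°Cd
    w_max: Optional[float] = None   # °Cd⁻¹, = v_max / l_max
    r_squared: Optional[float] = None
    rmse: Optional[float] = None    # mm
    n_obs: int = 0
    excluded: bool = False
    converged: bool = True
    reason: str = ""
    final_observed: float = field(default=float("nan"))


def logistic_length(t, l_max: float, t_mid: float, w: float):
    """Evaluate the symmetric logistic with normalised maximal rate ``w``."""
    z = np.clip(4.0 * w * (np.asarray(t, dtype=float) - t_mid), -500.0, 500.0)
    out = l_max / (1.0 + np.exp(-z))
    return float(out) if np.ndim(t) == 0 else out


def observed_final_length(length, n_last: int = 3) -> float:
    """Observed final length (mm): mean of the last ``n_last`` readings.

    Series are measured until expansion has ceased, so the trailing readings
    sit on the plateau; averaging them suppresses ruler noise and rounding,
    which a plain max over readings would rectify into an upward bias.
    """
    L = np.asarray(length, dtype=float)
    if len(L) == 0:
        return float("nan")
    return float(np.mean(L[-min(n_last, len(L)):]))


def _initial_guess(t: np.ndarray, L: np.ndarray):
    l0 = 1.05 * np.max(L)
    half = 0.5 * np.max(L)
    above = np.nonzero(L >= half)[0]
    if len(above) == 0 or above[0] == 0:
        t0 = t[0]
    else:
        j = above[0]
        # linear interpolation of the first half-max crossing
        t0 = t[j - 1] + (half - L[j - 1]) * (t[j] - t[j - 1]) / (L[j] - L[j - 1])
    dL = np.diff(L) / np.diff(t)
    v0 = max(float(np.max(dL)), 1e-6) if len(dL) else 1e-3
    return np.array([l0, t0, v0])


def fit_logistic(series: OrganSeries, min_obs: int = 5,
                 exclusion_threshold: float = MIN_FINAL_LENGTH_MM) -> LogisticFitResult:
    """Nonlinear least-squares fit of (l_max, t_mid, v_max) to one organ.

    Deterministic given the series: the initial guess is data-driven and up
    to three jittered restarts (fixed jitter sequence) are attempted on
    failure.  Sub-threshold organs are returned flagged ``excluded`` and
    carry no parameters.
    """
    t, L = series.t, series.length
    final_obs = observed_final_length(L)
    base = dict(plant_id=series.plant_id, kind=series.kind,
                relative_rank=series.relative_rank, n_obs=len(t),
                final_observed=final_obs)
    if final_obs < exclusion_threshold:
        return LogisticFitResult(excluded=True,
                                 reason=f"final length {final_obs:.1f} mm < "
                                        f"{exclusion_threshold:g} mm", **base)
    if len(t) < min_obs:
        raise ValueError(f"need >= {min_obs} observations to fit, got {len(t)}")

    def resid(p):
        return logistic_length(t, p[0], p[1], p[2] / p[0]) - L

    p0 = _initial_guess(t, L)
    span = float(t[-1] - t[0])
    # loose physical bounds: they never bind for a healthy sigmoid but stop
    # near-flat series from running off to absurd parameters
    lower = np.array([1e-6, t[0] - 5.0 * span, 1e-9])
    upper = np.array([5.0 * float(np.max(L)) + 1e-6, t[-1] + 5.0 * span, np.inf])
    p0 = np.clip(p0, lower + 1e-9, upper - 1e-9)
    rng = np.random.default_rng(12345)  # fixed: restarts are deterministic
    sol, ok = None, False
    for attempt in range(4):
        start = p0 if attempt == 0 else p0 * (1.0 + 0.2 * rng.standard_normal(3))
        start = np.clip(start, lower + 1e-9, upper - 1e-9)
        try:
            res = least_squares(resid, start, bounds=(lower, upper),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if res.success and (sol is None or res.cost < sol.cost):
            sol, ok = res, True
            if attempt == 0:
                break
    if not ok:
        return LogisticFitResult(excluded=False, converged=False,
                                 reason="non-convergence after restarts", **base)

    l_max, t_mid, v_max = (float(x) for x in sol.x)
    residuals = resid(sol.x)
    sse = float(np.sum(residuals**2))
    sst = float(np.sum((L - np.mean(L)) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return LogisticFitResult(l_max=l_max, t_mid=t_mid, v_max=v_max,
                             w_max=v_max / l_max, r_squared=r2,
                             rmse=float(np.sqrt(sse / len(t))), **base)


def _require_fit(fit: LogisticFitResult) -> None:
    if fit.excluded or not fit.converged or fit.w_max is None:
        raise ValueError("fit is excluded or failed; kinetic summaries unavailable")


def expansion_duration(fit: LogisticFitResult) -> float:
    """Thermal time (°Cd) to grow from 10 % to 90 % of final length.

    For the symmetric logistic this is ln(81)/(4 w_max), independent of
    l_max and t_mid.
    """
    _require_fit(fit)
    return float(np.log(81.0) / (4.0 * fit.w_max))


def time_at_fraction(fit: LogisticFitResult, q: float) -> float:
    """Thermal time at which the fitted curve reaches fraction ``q`` of l_max."""
    _require_fit(fit)
    if not 0.0 < q < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    return float(fit.t_mid + np.log(q / (1.0 - q)) / (4.0 * fit.w_max))


def leaflet_internode_offsets(leaflet_fit: LogisticFitResult,
                              internode_fit: LogisticFitResult):
    """Timing offsets between a phytomer's leaflet and internode windows.

    Returns ``(t_int(10%) - t_lea(10%), t_lea(90%) - t_int(90%))``; both are
    positive when internode expansion is nested inside leaflet expansion.
    """
    start = time_at_fraction(internode_fit, 0.1) - time_at_fraction(leaflet_fit, 0.1)
    end = time_at_fraction(leaflet_fit, 0.9) - time_at_fraction(internode_fit, 0.9)
    return start, end
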