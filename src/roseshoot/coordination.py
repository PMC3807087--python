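"""Coordination between leaf appearance and organ mid-expansion.

The thermal time t0 at an organ's inflexion point is predicted from the
appearance time t_a of the leaf at the same phytomer:

    leaflets:              t0 = d_lea0 + d_lea1 * t_a + d_lea2 * t_a**2
    vegetative internodes: t0 = d_int0 + d_int1 * t_a          (i < 1)
    peduncles:             t0 = d_ped0 + d_ped1 * t_a          (i = 1)

The quadratic term for leaflets absorbs the gradual change of expansion
duration with rank; internodes have near-constant duration so a line
suffices, with a separate line for the much slower peduncle.  The shipped
defaults are the coefficients calibrated on the three study crops pooled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["CoordinationParams", "table4_defaults", "predict_t_mid", "fit_coordination"]


@dataclass(frozen=True)
class CoordinationParams:
    d_lea0: float  # °Cd
    d_lea1: float
    d_lea2: float  # °Cd⁻¹
    d_int0: float  # °Cd
    d_int1: float
    d_ped0: float  # °Cd
    d_ped1: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CoordinationParams":
        with open(path) as fh:
            return cls(**json.load(fh))


def table4_defaults() -> CoordinationParams:
    """Shipped calibrated coordination coefficients."""
    text = resources.files("roseshoot.data").joinpath("table4_defaults.json").read_text()
    return CoordinationParams(**json.loads(text))


def predict_t_mid(params: CoordinationParams, kind: str, i: float, t_app) -> float:
    """Predicted mid-expansion time (°Cd) for an organ from its leaf's t_a."""
    t_app = np.asarray(t_app, dtype=float)
    if np.any(t_app < 0):
        raise ValueError("appearance time must be >= 0")
    if kind == "lea":
        if i == 1:
            raise ValueError("peduncles (i = 1) bear no leaflet")
        out = params.d_lea0 + params.d_lea1 * t_app + params.d_lea2 * t_app**2
    elif kind == "int":
        if i == 1:
            out = params.d_ped0 + params.d_ped1 * t_app
        else:
            out = params.d_int0 + params.d_int1 * t_app
    else:
        raise ValueError(f"unknown organ kind {kind!r}")
    return float(out) if out.ndim == 0 else out


def _ols(X: np.ndarray, y: np.ndarray):
    model = sm.OLS(y, X).fit()
    return model.params, float(model.rsquared_adj)


def fit_coordination(pairs: pd.DataFrame):
    """Fit the three coordination sub-models from (kind, i, t_app, t_mid) pairs.

    Parameters
    ----------
    pairs
        DataFrame with columns ``kind`` ("lea"/"int"), ``relative_rank``,
        ``t_app`` and ``t_mid``.  Peduncles are internode rows at
        ``relative_rank == 1`` exactly.

    Returns
    -------
    (CoordinationParams, dict)
        Fitted coefficients and adjusted R² per sub-model ("lea", "int",
        "ped"); a sub-model with too few pairs is flagged unfitted (NaN
        coefficients and R²).
    """
    lea = pairs[pairs["kind"] == "lea"]
    vint = pairs[(pairs["kind"] == "int") & (pairs["relative_rank"] < 1)]
    ped = pairs[(pairs["kind"] == "int") & (pairs["relative_rank"] == 1)]

    nan3 = (np.full(3, np.nan), float("nan"))
    nan2 = (np.full(2, np.nan), float("nan"))
    if len(lea) >= 3:
        ta = lea["t_app"].to_numpy()
        c_lea, r2_lea = _ols(np.column_stack([np.ones_like(ta), ta, ta**2]),
                             lea["t_mid"].to_numpy())
    else:
        c_lea, r2_lea = nan3
    if len(vint) >= 2:
        ta = vint["t_app"].to_numpy()
        c_int, r2_int = _ols(np.column_stack([np.ones_like(ta), ta]),
                             vint["t_mid"].to_numpy())
    else:
        c_int, r2_int = nan2
    if len(ped) >= 2:
        ta = ped["t_app"].to_numpy()
        c_ped, r2_ped = _ols(np.column_stack([np.ones_like(ta), ta]),
                             ped["t_mid"].to_numpy())
    else:
        c_ped, r2_ped = nan2

    params = CoordinationParams(
        d_lea0=float(c_lea[0]), d_lea1=float(c_lea[1]), d_lea2=float(c_lea[2]),
        d_int0=float(c_int[0]), d_int1=float(c_int[1]),
        d_ped0=float(c_ped[0]), d_ped1=float(c_ped[1]),
    )
    return params, {"lea": r2_lea, "int": r2_int, "ped": r2_ped}
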