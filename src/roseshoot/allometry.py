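"""Whole-leaf area from terminal leaflet length and leaflet count.

All dimensions of a rose leaf's leaflets are strongly correlated, so one
dimension — terminal leaflet length L — plus the number of leaflets N_L
suffices to reconstruct whole-leaf area at any growth stage via the power
law A = a * L**2 * N_L**b.  The shipped coefficients (a = 0.287, b = 0.746)
were calibrated on 201 leaves; with this multiplicative form the residual
distribution does not depend on leaflet number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["LeafRecord", "DEFAULT_A", "DEFAULT_B", "leaf_area", "fit_allometry"]

DEFAULT_A = 0.287
DEFAULT_B = 0.746


@dataclass(frozen=True)
class LeafRecord:
    terminal_leaflet_length: float  # mm
    n_leaflets: int                 # odd, 1..9
    area: Optional[float] = None    # mm², present when used for fitting


def leaf_area(L, n_leaflets, a: float = DEFAULT_A, b: float = DEFAULT_B):
    """Whole-leaf area (mm²) from terminal leaflet length and leaflet count."""
    L = np.asarray(L, dtype=float)
    N = np.asarray(n_leaflets, dtype=float)
    if np.any(L < 0):
        raise ValueError("leaflet length must be >= 0")
    if np.any(N < 1):
        raise ValueError("leaflet count must be >= 1")
    if np.any(np.asarray(n_leaflets) % 2 == 0):
        warnings.warn("rose leaves normally have odd leaflet counts", stacklevel=2)
    out = a * L**2 * N**b
    return float(out) if out.ndim == 0 else out


def _model(X, a, b):
    L, N = X
    return a * L**2 * N**b


def fit_allometry(leaves):
    """Least-squares fit of (a, b) on the raw area scale.

    Parameters
    ----------
    leaves
        Sequence of :class:`LeafRecord` with areas, or a DataFrame with
        columns ``terminal_leaflet_length_mm``, ``n_leaflets``, ``area_mm2``.

    Returns
    -------
    (a, b, r_squared, residuals_by_n)
        ``residuals_by_n`` maps each leaflet count to its mean residual
        (mm²), for checking that errors do not depend on leaflet number.
    """
    if isinstance(leaves, pd.DataFrame):
        L = leaves["terminal_leaflet_length_mm"].to_numpy(dtype=float)
        N = leaves["n_leaflets"].to_numpy(dtype=float)
        A = leaves["area_mm2"].to_numpy(dtype=float)
    else:
        leaves = [lf for lf in leaves if lf.area is not None]
        L = np.array([lf.terminal_leaflet_length for lf in leaves], dtype=float)
        N = np.array([lf.n_leaflets for lf in leaves], dtype=float)
        A = np.array([lf.area for lf in leaves], dtype=float)
    if len(L) < 10:
        raise ValueError("need at least 10 leaves with measured area")
    if len(np.unique(N)) < 2:
        raise ValueError("exponent b unidentifiable with a single leaflet count")

    # log-scale regression provides the starting point for the raw-scale fit
    ok = (A > 0) & (L > 0)
    X = np.column_stack([np.ones(ok.sum()), np.log(N[ok])])
    coef, *_ = np.linalg.lstsq(X, np.log(A[ok]) - 2.0 * np.log(L[ok]), rcond=None)
    p0 = [float(np.exp(coef[0])), float(coef[1])]
    popt, _ = curve_fit(_model, (L, N), A, p0=p0, maxfev=20000)
    a, b = (float(x) for x in popt)

    pred = _model((L, N), a, b)
    sse = float(np.sum((A - pred) ** 2))
    sst = float(np.sum((A - np.mean(A)) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    resid = A - pred
    residuals_by_n = {int(n): float(np.mean(resid[N == n])) for n in np.unique(N)}
    return a, b, r2, residuals_by_n
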