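"""Piecewise-linear leaf-appearance model.

Leaf tips are scored 5–6 times per week, so the recorded first-seen time of a
leaf overshoots its true appearance time.  Appearance is therefore modelled,
per plant, as a continuous two-phase linear function of relative rank i:

    t_a(i) = alpha + beta * i                      for i <= c
    t_a(i) = alpha + beta * c + gamma * (i - c)    for i > c

alpha is the thermal time at which the first (most basal) leaf appeared, beta
and gamma are the appearance slopes (°Cd per unit relative rank) of the rapid
basal phase and the slow upper phase, and c the breakpoint rank between them.
Adjusted appearance times are read off the fitted function; the peduncle
(i = 1) bears no leaf but receives a "virtual leaf" time by extrapolating the
slow phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["AppearanceObservation", "AppearanceModel", "fit_appearance", "adjusted_appearance"]


@dataclass(frozen=True)
class AppearanceObservation:
    plant_id: str
    relative_rank: float
    t_first_seen: float  # °Cd since bud break


@dataclass(frozen=True)
class AppearanceModel:
    """Fitted parameters of the two-phase leaf-appearance function."""

    alpha: float  # °Cd, appearance time of the first leaf
    beta: float   # °Cd per unit relative rank, rapid phase
    gamma: float  # °Cd per unit relative rank, slow phase
    c: float      # breakpoint relative rank, in (0, 1)
    rss: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 < self.c < 1.0:
            raise ValueError("breakpoint c must lie strictly inside (0, 1)")

    def __call__(self, i):
        return adjusted_appearance(self, i)


def adjusted_appearance(model: AppearanceModel, i):
    """Evaluate the fitted appearance function at relative rank(s) ``i``.

    Continuous at the breakpoint; ``i = 1`` gives the peduncle's virtual-leaf
    time by linear extrapolation of the slow phase.
    """
    i = np.asarray(i, dtype=float)
    if np.any((i < 0) | (i > 1)):
        raise ValueError("relative rank outside [0, 1]")
    out = np.where(
        i <= model.c,
        model.alpha + model.beta * i,
        model.alpha + model.beta * model.c + model.gamma * (i - model.c),
    )
    return float(out) if out.ndim == 0 else out


def _solve_given_c(i: np.ndarray, t: np.ndarray, c: float):
    """Closed-form least squares for (alpha, beta, gamma) at a fixed breakpoint."""
    X = np.column_stack(
        [np.ones_like(i), np.minimum(i, c), np.clip(i - c, 0.0, None)]
    )
    coef, *_ = np.linalg.lstsq(X, t, rcond=None)
    rss = float(np.sum((X @ coef - t) ** 2))
    return coef, rss


def fit_appearance(obs, min_obs: int = 4) -> AppearanceModel:
    """Fit the two-phase appearance function to one plant's first-seen times.

    The model is linear in (alpha, beta, gamma) once the breakpoint c is
    fixed, so c is profiled: the residual sum of squares is minimised over a
    grid of candidate breakpoints spanning the interior ranks, then refined by
    bounded scalar minimisation around the best candidate.

    Parameters
    ----------
    obs
        Either a sequence of :class:`AppearanceObservation` or a pair of
        arrays ``(relative_ranks, t_first_seen)``.
    """
    if isinstance(obs, tuple) and len(obs) == 2:
        i = np.asarray(obs[0], dtype=float)
        t = np.asarray(obs[1], dtype=float)
    else:
        obs = list(obs)
        i = np.array([o.relative_rank for o in obs], dtype=float)
        t = np.array([o.t_first_seen for o in obs], dtype=float)

    if len(i) < min_obs:
        raise ValueError(f"need at least {min_obs} appearance observations, got {len(i)}")
    ranks = np.unique(i)
    if len(ranks) < 3:
        raise ValueError("appearance ranks are degenerate (fewer than 3 distinct ranks)")

    # candidate breakpoints: interior of the observed rank range
    lo, hi = ranks[1], ranks[-2]
    if hi <= lo:
        lo, hi = ranks[0] + 1e-6, ranks[-1] - 1e-6
    grid = np.unique(np.concatenate([ranks[(ranks >= lo) & (ranks <= hi)],
                                     np.linspace(lo, hi, 101)]))
    grid = grid[(grid > 0.0) & (grid < 1.0)]
    rss_grid = np.array([_solve_given_c(i, t, c)[1] for c in grid])
    k = int(np.argmin(rss_grid))

    # refine within the bracketing interval (RSS is smooth between data ranks)
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    best_c = grid[k]
    if b > a:
        res = minimize_scalar(
            lambda c: _solve_given_c(i, t, c)[1], bounds=(a, b), method="bounded",
            options={"xatol": 1e-12},
        )
        if res.fun <= rss_grid[k] + 1e-12:
            best_c = float(res.x)
    coef, rss = _solve_given_c(i, t, best_c)
    best_c = float(np.clip(best_c, 1e-9, 1 - 1e-9))
    return AppearanceModel(alpha=float(coef[0]), beta=float(coef[1]),
                           gamma=float(coef[2]), c=best_c, rss=rss)
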