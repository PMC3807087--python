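"""Rank-indexed parameter profiles and LOESS smoothing.

Per-organ kinetic estimates (w_m, t0, L_m) scatter around smooth trends in
relative rank i.  These trends are extracted by locally weighted polynomial
regression (LOESS, tricube weights) evaluated on a fixed rank grid, and are
then used as crop-level model parameters: w_m(i) for all scenarios, t0(i)
for S1/S2, L_m(i) for S2.  The shipped default :class:`ProfileSet` is the
calibration pooled over the three study crops.

Evaluation between grid knots is by linear interpolation; the 0.05 grid pitch
makes higher-order interpolation immaterial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "TABLE_GRID",
    "RankProfile",
    "ProfileSet",
    "table5_defaults",
    "smooth_profile",
    "loess",
    "simplified_w",
    "SIMPLIFIED_W",
]

#: Rank grid on which calibrated profiles are tabulated.
TABLE_GRID = np.array(
    [0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5,
     0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.93, 1.0]
)

#: Simplified one-value-per-organ-class normalised maximal rates (°Cd⁻¹):
#: terminal leaflets, vegetative internodes, peduncles.
SIMPLIFIED_W = {"lea": 5.96e-3, "int": 9.04e-3, "ped": 5.17e-3}


@dataclass(frozen=True)
class RankProfile:
    """Piecewise-linear profile of one parameter against relative rank."""

    knots_i: np.ndarray
    knots_v: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        ki = np.asarray(self.knots_i, dtype=float)
        kv = np.asarray(self.knots_v, dtype=float)
        if ki.shape != kv.shape or ki.ndim != 1 or len(ki) < 2:
            raise ValueError("profile needs >= 2 (i, value) knots")
        if np.any(np.diff(ki) <= 0):
            raise ValueError("knot ranks must be strictly increasing")
        object.__setattr__(self, "knots_i", ki)
        object.__setattr__(self, "knots_v", kv)

    @property
    def valid_range(self):
        return float(self.knots_i[0]), float(self.knots_i[-1])

    def covers(self, i: float) -> bool:
        lo, hi = self.valid_range
        return lo - 1e-12 <= i <= hi + 1e-12

    def __call__(self, i, clamp: bool = False):
        """Evaluate the profile; exact at knots, linear between them.

        Outside the knot range evaluation is an error unless ``clamp`` is
        set, in which case the boundary value is returned.
        """
        i = np.asarray(i, dtype=float)
        lo, hi = self.valid_range
        if not clamp and np.any((i < lo - 1e-12) | (i > hi + 1e-12)):
            raise ValueError(
                f"rank outside profile range [{lo:g}, {hi:g}] for {self.name or 'profile'}"
            )
        out = np.interp(np.clip(i, lo, hi), self.knots_i, self.knots_v)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ProfileSet:
    """The six crop-level profiles: w_m, t0 and L_m for each organ kind."""

    w_lea: RankProfile
    w_int: RankProfile
    t0_lea: RankProfile
    t0_int: RankProfile
    lm_lea: RankProfile
    lm_int: RankProfile

    def w(self, kind: str) -> RankProfile:
        return self.w_lea if kind == "lea" else self.w_int

    def t0(self, kind: str) -> RankProfile:
        return self.t0_lea if kind == "lea" else self.t0_int

    def lm(self, kind: str) -> RankProfile:
        return self.lm_lea if kind == "lea" else self.lm_int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(_profileset_to_table(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ProfileSet":
        with open(path) as fh:
            return _table_to_profileset(json.load(fh))


def _column_profile(grid, values, name, scale=1.0) -> RankProfile:
    vals = np.array([np.nan if v is None else float(v) for v in values])
    mask = np.isfinite(vals)
    return RankProfile(np.asarray(grid, dtype=float)[mask], vals[mask] * scale, name=name)


def _table_to_profileset(table: dict) -> ProfileSet:
    g = table["grid"]
    return ProfileSet(
        w_lea=_column_profile(g, table["leaflet"]["w_x1000"], "w_lea", scale=1e-3),
        t0_lea=_column_profile(g, table["leaflet"]["t0"], "t0_lea"),
        lm_lea=_column_profile(g, table["leaflet"]["lm"], "lm_lea"),
        w_int=_column_profile(g, table["internode"]["w_x1000"], "w_int", scale=1e-3),
        t0_int=_column_profile(g, table["internode"]["t0"], "t0_int"),
        lm_int=_column_profile(g, table["internode"]["lm"], "lm_int"),
    )


def _profileset_to_table(ps: ProfileSet) -> dict:
    grid = [float(g) for g in TABLE_GRID]

    def col(profile: RankProfile, scale=1.0):
        out = []
        for g in grid:
            j = np.nonzero(np.isclose(profile.knots_i, g, atol=1e-9))[0]
            out.append(round(float(profile.knots_v[j[0]]) * scale, 6) if len(j) else None)
        return out

    return {
        "grid": grid,
        "leaflet": {"w_x1000": col(ps.w_lea, 1e3), "t0": col(ps.t0_lea),
                    "lm": col(ps.lm_lea)},
        "internode": {"w_x1000": col(ps.w_int, 1e3), "t0": col(ps.t0_int),
                      "lm": col(ps.lm_int)},
    }


def table5_defaults() -> ProfileSet:
    """Shipped calibrated profiles (study-crop pooled LOESS estimates)."""
    text = resources.files("roseshoot.data").joinpath("table5_defaults.json").read_text()
    return _table_to_profileset(json.loads(text))


def loess(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray,
          span: float = 0.5, degree: int = 2) -> np.ndarray:
    """Locally weighted polynomial regression with tricube weights.

    At each evaluation point the ``ceil(span * n)`` nearest data points are
    fitted with a weighted polynomial of the given degree and the local fit
    is evaluated there.  Degree 1 matches statsmodels' lowess; degree 2 is
    the classical LOESS local quadratic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.atleast_1d(np.asarray(x_eval, dtype=float))
    n = len(x)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    k = max(int(np.ceil(span * n)), degree + 1)
    k = min(k, n)
    out = np.empty(len(x_eval))
    for m, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        idx = np.argpartition(d, k - 1)[:k]
        dmax = np.max(d[idx])
        if dmax <= 0:
            w = np.ones(k)
        else:
            w = (1.0 - np.minimum(d[idx] / dmax, 1.0) ** 3) ** 3
            w = np.maximum(w, 1e-12)  # keep boundary points in the design
        X = np.vander(x[idx] - x0, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y[idx] * sw, rcond=None)
        out[m] = coef[0]
    return out


def smooth_profile(points, span: float = 0.5, degree: int = 2,
                   grid=None, name: str = "") -> RankProfile:
    """LOESS-smooth per-organ estimates against rank onto the profile grid.

    Parameters
    ----------
    points
        Pair of arrays ``(i, y)`` or sequence of (i, y) tuples.
    grid
        Evaluation ranks; defaults to :data:`TABLE_GRID` restricted to the
        observed rank range.
    """
    if isinstance(points, tuple) and len(points) == 2:
        i = np.asarray(points[0], dtype=float)
        y = np.asarray(points[1], dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
        i, y = arr[:, 0], arr[:, 1]
    if len(i) < 5:
        raise ValueError("need >= 5 points to smooth a profile")
    if grid is None:
        grid = TABLE_GRID
    grid = np.asarray(grid, dtype=float)
    grid = grid[(grid >= np.min(i) - 1e-12) & (grid <= np.max(i) + 1e-12)]
    if len(grid) < 2:
        raise ValueError("observed rank range covers fewer than 2 grid points")
    vals = loess(i, y, grid, span=span, degree=degree)
    return RankProfile(grid, vals, name=name)


def simplified_w(kind: str, is_peduncle: bool = False) -> float:
    """Single normalised maximal rate per organ class (simplified variant)."""
    if kind == "lea":
        return SIMPLIFIED_W["lea"]
    if kind == "int":
        return SIMPLIFIED_W["ped"] if is_peduncle else SIMPLIFIED_W["int"]
    raise ValueError(f"unknown organ kind {kind!r}")
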