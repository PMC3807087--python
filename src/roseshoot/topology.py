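"""Thermal-time accounting and phytomer-position conventions.

All event times in the package are expressed in degree-days (°Cd) accumulated
above a base temperature since bud break of the cutting.  Phytomer position
along the primary shoot is expressed as a *relative rank* in [0, 1] so that
shoots with different phytomer counts can be compared; the flower peduncle is
the topmost phytomer and sits at relative rank 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "ThermalClock",
    "PhytomerPosition",
    "BASE_TEMP_C",
    "thermal_time",
    "relative_rank",
    "rounded_rank",
]

#: Base temperature (°C) for Rosa hybrida 'Radrazz' degree-day accumulation.
BASE_TEMP_C = 2.1


@dataclass(frozen=True)
class TemperatureSeries:
    """Daily mean air temperatures over a contiguous span of calendar days.

    Parameters
    ----------
    dates
        Calendar days, strictly increasing with no gaps (daily resolution).
    t_mean
        Daily mean air temperature (°C), one value per day.
    """

    dates: pd.DatetimeIndex
    t_mean: np.ndarray

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        t = np.asarray(self.t_mean, dtype=float)
        if len(dates) != len(t):
            raise ValueError("dates and t_mean must have the same length")
        if len(dates) == 0:
            raise ValueError("empty temperature series")
        deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
        if np.any(deltas != 1):
            raise ValueError("dates must be strictly increasing daily values with no gaps")
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite temperature value")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "t_mean", t)

    @classmethod
    def from_csv(cls, path) -> "TemperatureSeries":
        df = pd.read_csv(path, parse_dates=["date"])
        missing = {"date", "t_mean_c"} - set(df.columns)
        if missing:
            raise ValueError(f"temperature CSV missing columns: {sorted(missing)}")
        return cls(pd.DatetimeIndex(df["date"]), df["t_mean_c"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"date": self.dates, "t_mean_c": self.t_mean}).to_csv(path, index=False)


@dataclass(frozen=True)
class ThermalClock:
    """Per-plant degree-day clock: base temperature + bud-break origin."""

    budbreak_date: pd.Timestamp
    base_temp: float = BASE_TEMP_C

    def __post_init__(self) -> None:
        if not np.isfinite(self.base_temp):
            raise ValueError("base_temp must be finite")
        object.__setattr__(self, "budbreak_date", pd.Timestamp(self.budbreak_date))


def thermal_time(temps: TemperatureSeries, clock: ThermalClock, date) -> float:
    """Cumulative thermal time (°Cd) from bud break up to ``date``.

    Each elapsed day contributes ``max(0, t_mean - base_temp)``; days below
    the base temperature contribute nothing.  The day of bud break itself is
    the origin: ``thermal_time(..., budbreak_date) == 0``.
    """
    date = pd.Timestamp(date)
    bb = clock.budbreak_date
    if date < bb:
        raise ValueError(f"date {date.date()} precedes bud break {bb.date()}")
    if bb < temps.dates[0] or date > temps.dates[-1] + pd.Timedelta(days=1):
        raise ValueError("temperature series does not cover [budbreak, date]")
    # days contributing: bud break (inclusive) to date (exclusive)
    mask = (temps.dates >= bb) & (temps.dates < date)
    if date > bb and mask.sum() < (date - bb).days:
        raise ValueError("temperature series has missing days in [budbreak, date]")
    return float(np.sum(np.maximum(0.0, temps.t_mean[mask] - clock.base_temp)))


def relative_rank(r: int, n_phytomers: int) -> float:
    """Relative rank i = (r - 1)/(N_p - 1) of the phytomer at absolute rank r.

    Rank r = 1 is the shoot base, r = N_p the peduncle (i = 1).
    """
    if n_phytomers < 2:
        raise ValueError("n_phytomers must be >= 2")
    if not 1 <= r <= n_phytomers:
        raise ValueError(f"absolute rank {r} outside [1, {n_phytomers}]")
    return (r - 1) / (n_phytomers - 1)


def rounded_rank(i: float) -> float:
    """Relative rank rounded to the nearest tenth; ties round toward the top."""
    if not 0.0 <= i <= 1.0:
        raise ValueError("relative rank outside [0, 1]")
    return float(np.floor(i * 10.0 + 0.5) / 10.0)


@dataclass(frozen=True)
class PhytomerPosition:
    """A phytomer's absolute rank on a shoot of ``n_phytomers`` phytomers."""

    absolute_rank: int
    n_phytomers: int
    relative: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "relative", relative_rank(self.absolute_rank, self.n_phytomers)
        )

    @property
    def is_peduncle(self) -> bool:
        return self.absolute_rank == self.n_phytomers
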