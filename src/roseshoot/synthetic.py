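"""Synthetic crops of virtual rose bush plants, with exported ground truth.

The generator emulates the measurement campaign on real crops: each virtual
plant draws a phytomer count (10–16), per-plant leaf-appearance parameters,
and per-organ kinetic parameters built from the shipped calibrated profiles
and coordination polynomials, with three independent noise sources —

* multiplicative final-length noise per organ (size differences between
  plants at a rank are organ-local, not a whole-plant effect),
* additive timing noise on each organ's mid-expansion time,
* ruler-scale measurement noise with rounding on each length reading.

Observations are emitted on a regular visit grid (5–6 visits/week at a
constant daily thermal rate), starting only once the organ is visible —
early expansion is left-censored exactly as in the glasshouse protocol.
Exact per-organ parameters are exported as :class:`CropTruth` so recovery
tests can compare estimates against the generating truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .appearance import AppearanceModel
from .coordination import CoordinationParams, predict_t_mid, table4_defaults
from .io import Crop
from .logistic import MIN_FINAL_LENGTH_MM, logistic_length
from .profiles import ProfileSet, table5_defaults
from .topology import relative_rank

__all__ = ["CropConfig", "CropTruth", "generate_crop", "generate_leaf_table"]


@dataclass(frozen=True)
class CropConfig:
    """Study-condition parameters of the virtual crop.

    Appearance-phase parameters are drawn per plant; phyllochrons are in °Cd
    per leaf and converted to slopes against relative rank via (N_p - 1).
    Defaults emulate the variability of the measured crops: phytomer counts
    uniform on 10–16, slow-phase phyllochron 35 ± 7 °Cd, final lengths and
    timings centred on the shipped calibrated profiles.
    """

    n_plants: int = 30
    phytomer_min: int = 10
    phytomer_max: int = 16
    # appearance function (per-plant draws)
    alpha_mean: float = 15.0       # °Cd, first-leaf appearance
    alpha_sd: float = 6.0
    phyllochron_fast_mean: float = 6.0   # °Cd/leaf, preformed basal leaves
    phyllochron_fast_sd: float = 2.0
    phyllochron_slow_mean: float = 35.0  # °Cd/leaf, neoformed upper leaves
    phyllochron_slow_sd: float = 7.0
    c_mean: float = 0.45           # breakpoint relative rank
    c_sd: float = 0.07
    # organ-level noise
    size_cv: float = 0.10          # multiplicative sd on final length
    t_mid_sd: float = 18.0         # °Cd, additive sd on mid-expansion time
    appearance_noise_sd: float = 5.0  # °Cd, first-seen scoring error
    # observation protocol
    visit_interval_days: float = 7.0 / 6.0  # 6 visits per week
    thermal_rate: float = 18.1     # °Cd/day (20.2 °C mean at base 2.1 °C)
    measurement_sd: float = 0.8    # mm, ruler reading noise
    rounding_mm: float = 1.0       # ruler resolution; 0 disables rounding
    visibility_lag: float = 15.0   # °Cd between appearance and first reading
    # generating model
    profiles: ProfileSet = field(default_factory=table5_defaults)
    coordination: CoordinationParams = field(default_factory=table4_defaults)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.phytomer_min <= self.phytomer_max <= 30):
            raise ValueError("phytomer range must lie within [2, 30]")
        for name in ("alpha_sd", "phyllochron_fast_sd", "phyllochron_slow_sd",
                     "c_sd", "size_cv", "t_mid_sd", "appearance_noise_sd",
                     "measurement_sd", "rounding_mm", "visibility_lag"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.visit_interval_days <= 0 or self.thermal_rate <= 0:
            raise ValueError("visit cadence and thermal rate must be > 0")

    def zero_noise(self) -> "CropConfig":
        """Copy with all stochastic perturbations switched off."""
        return dataclasses.replace(
            self, size_cv=0.0, t_mid_sd=0.0, appearance_noise_sd=0.0,
            measurement_sd=0.0, rounding_mm=0.0,
            alpha_sd=0.0, phyllochron_fast_sd=0.0, phyllochron_slow_sd=0.0,
            c_sd=0.0,
        )


@dataclass
class CropTruth:
    """Generating parameters: per-plant appearance models, per-organ kinetics."""

    appearance: dict               # plant_id -> AppearanceModel
    organs: pd.DataFrame           # plant_id, kind, absolute_rank, relative_rank,
    #                                l_max, w, t_mid, constant

    def organ_params(self, plant_id: str, kind: str, absolute_rank: int):
        df = self.organs
        row = df[(df["plant_id"] == plant_id) & (df["kind"] == kind)
                 & (df["absolute_rank"] == absolute_rank)]
        if row.empty:
            raise KeyError((plant_id, kind, absolute_rank))
        return row.iloc[0]


def _draw_positive(rng, mean, sd, floor=1e-3):
    return max(float(rng.normal(mean, sd)), floor) if sd > 0 else float(mean)


def generate_crop(config: CropConfig = CropConfig()):
    """Generate one virtual crop; returns ``(Crop, CropTruth)``.

    Deterministic for a given config (all randomness flows from
    ``config.seed``).
    """
    rng = np.random.default_rng(config.seed)
    dt = config.visit_interval_days * config.thermal_rate  # °Cd between visits

    length_rows, appearance_rows, meta_rows = [], [], []
    truth_appearance, truth_rows = {}, []

    for p in range(config.n_plants):
        pid = f"p{p:03d}"
        n_p = int(rng.integers(config.phytomer_min, config.phytomer_max + 1))
        alpha = _draw_positive(rng, config.alpha_mean, config.alpha_sd, floor=0.0)
        beta = _draw_positive(rng, config.phyllochron_fast_mean,
                              config.phyllochron_fast_sd) * (n_p - 1)
        gamma = _draw_positive(rng, config.phyllochron_slow_mean,
                               config.phyllochron_slow_sd) * (n_p - 1)
        c = float(np.clip(rng.normal(config.c_mean, config.c_sd)
                          if config.c_sd > 0 else config.c_mean, 0.1, 0.9))
        model = AppearanceModel(alpha=alpha, beta=beta, gamma=gamma, c=c)
        truth_appearance[pid] = model
        meta_rows.append((pid, n_p))

        ranks = [(r, relative_rank(r, n_p)) for r in range(1, n_p + 1)]
        # leaf-appearance observations (all leaves; the peduncle bears none)
        for r, i in ranks[:-1]:
            t_obs = model(i)
            if config.appearance_noise_sd > 0:
                t_obs += rng.normal(0.0, config.appearance_noise_sd)
            appearance_rows.append((pid, i, max(t_obs, 0.0)))

        # organ kinetic truths
        organs = []
        for kind in ("lea", "int"):
            lm_prof = config.profiles.lm(kind)
            w_prof = config.profiles.w(kind)
            kind_ranks = ranks[:-1] if kind == "lea" else ranks
            for r, i in kind_ranks:
                if not lm_prof.covers(i):
                    continue  # basal scale leaves bear no terminal leaflet
                l_max = lm_prof(i)
                if config.size_cv > 0:
                    l_max *= max(1.0 + rng.normal(0.0, config.size_cv), 0.05)
                t_app = max(float(model(i)), 0.0)
                if l_max < MIN_FINAL_LENGTH_MM:
                    organs.append((r, i, kind, l_max, np.nan, np.nan, True, t_app))
                    continue
                w = w_prof(i, clamp=True)
                t_mid = predict_t_mid(config.coordination, kind, i, t_app)
                if config.t_mid_sd > 0:
                    t_mid += rng.normal(0.0, config.t_mid_sd)
                organs.append((r, i, kind, float(l_max), float(w), float(t_mid),
                               False, t_app))

        # observation horizon: last organ essentially at plateau, + spare visits
        ends = [t_mid + np.log(999.0) / (4.0 * w)
                for _, _, _, _, w, t_mid, const, _ in organs if not const]
        t_end = (max(ends) if ends else 300.0) + 4 * dt

        for r, i, kind, l_max, w, t_mid, const, t_app in organs:
            truth_rows.append((pid, kind, r, i, l_max, w, t_mid, const))
            t_first = t_app + config.visibility_lag
            v0 = int(np.ceil(t_first / dt))
            for v in range(v0, int(np.floor(t_end / dt)) + 1):
                t = v * dt
                L = l_max if const else logistic_length(t, l_max, t_mid, w)
                if config.measurement_sd > 0:
                    L += rng.normal(0.0, config.measurement_sd)
                if config.rounding_mm > 0:
                    L = np.round(L / config.rounding_mm) * config.rounding_mm
                length_rows.append((pid, kind, r, t, max(float(L), 0.0)))

    crop = Crop(
        lengths=pd.DataFrame(length_rows,
                             columns=["plant_id", "kind", "absolute_rank",
                                      "t_cd", "length_mm"]),
        appearance=pd.DataFrame(appearance_rows,
                                columns=["plant_id", "relative_rank",
                                         "t_first_seen_cd"]),
        metadata=pd.DataFrame(meta_rows, columns=["plant_id", "n_phytomers"]),
    )
    truth = CropTruth(
        appearance=truth_appearance,
        organs=pd.DataFrame(truth_rows,
                            columns=["plant_id", "kind", "absolute_rank",
                                     "relative_rank", "l_max", "w", "t_mid",
                                     "constant"]),
    )
    return crop, truth


def generate_leaf_table(n: int = 201, noise_cv: float = 0.0, seed: int = 0,
                        a: float = 0.287, b: float = 0.746) -> pd.DataFrame:
    """Synthetic leaf table for allometry fitting.

    Terminal leaflet lengths uniform on [5, 90] mm, leaflet counts in
    {1, 3, 5, 7}; areas follow the power law with multiplicative lognormal
    noise of coefficient of variation ``noise_cv``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L = rng.uniform(5.0, 90.0, size=n)
    N = rng.choice([1, 3, 5, 7], size=n)
    A = a * L**2 * N.astype(float)**b
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        A *= rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=n)
    return pd.DataFrame({
        "leaf_id": [f"leaf{j:04d}" for j in range(n)],
        "terminal_leaflet_length_mm": L,
        "n_leaflets": N,
        "area_mm2": A,
    })
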