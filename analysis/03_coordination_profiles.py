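#!/usr/bin/env python
"""Re-estimate crop-level parameters from the fitted organs.

Fits the coordination polynomials (mid-expansion vs leaf-appearance time)
and the LOESS rank profiles from the whole virtual crop, and compares them
with the shipped calibration they were generated from.  Reads scratch/crop/
(run 01 and 02 first).
"""

import json
from pathlib import Path

import numpy as np

from roseshoot import Crop, fit_crop, table4_defaults
from roseshoot.evaluation import EvalConfig, _fold_coordination, _fold_profiles

SCRATCH = Path("scratch/crop")
RESULTS = Path("results")


def main() -> None:
    crop = Crop.load(SCRATCH)
    fits = fit_crop(crop)
    config = EvalConfig()

    coord, r2 = _fold_coordination(fits.organ_fits, fits)
    profiles = _fold_profiles(fits.organ_fits, config)
    profiles.to_json(RESULTS / "profiles_refit.json")
    coord.to_json(RESULTS / "coordination_refit.json")

    shipped = table4_defaults()
    print("coordination refit (shipped in parentheses), adj R^2:",
          {k: round(v, 3) for k, v in r2.items()})
    for name in ("d_lea0", "d_lea1", "d_lea2", "d_int0", "d_int1", "d_ped0", "d_ped1"):
        print(f"  {name}: {getattr(coord, name):.5g} ({getattr(shipped, name):.5g})")

    # profile agreement at shared knots
    from roseshoot import table5_defaults
    ship = table5_defaults()
    for name in ("w_lea", "t0_lea", "lm_lea", "w_int", "t0_int", "lm_int"):
        a, b = getattr(profiles, name), getattr(ship, name)
        shared = [i for i in a.knots_i if b.covers(i)]
        dev = np.max(np.abs(a(np.array(shared)) - b(np.array(shared))))
        print(f"  {name}: max |refit - shipped| over {len(shared)} knots = {dev:.3g}")


if __name__ == "__main__":
    main()
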