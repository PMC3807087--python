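#!/usr/bin/env python
"""Predicted expansion curves for one plant under S0, S1 and S2.

Writes the three predicted-curve tables for the first plant of the virtual
crop to scratch/, and prints the parameters of its mid-rank organs so the
scenarios can be compared at a glance.  Reads scratch/crop/ (run 01 first).
"""

from pathlib import Path

import numpy as np

from roseshoot import (Crop, curves_to_frame, fit_crop, simulate_s0, simulate_s1,
                       simulate_s2, table4_defaults, table5_defaults)
from roseshoot.evaluation import _plant_inputs
from roseshoot.io import write_predictions

SCRATCH = Path("scratch")
CROP = SCRATCH / "crop"


def main() -> None:
    crop = Crop.load(CROP)
    fits = fit_crop(crop)
    pid = crop.plant_ids[0]
    inputs = _plant_inputs(crop, fits, pid)
    profiles = table5_defaults()
    coord = table4_defaults()
    grid = np.arange(0.0, 900.0, 25.0)

    curves = {
        "s0": simulate_s0(inputs, coord, profiles,
                          appearance_model=fits.appearance_models[pid]),
        "s1": simulate_s1(inputs, profiles),
        "s2": simulate_s2(inputs.n_phytomers, profiles, plant_id=pid),
    }
    for name, cs in curves.items():
        write_predictions(curves_to_frame(cs, grid), SCRATCH / f"pred_{name}.csv")
        mid = [c for c in cs if c.kind == "lea" and abs(c.relative_rank - 0.5) < 0.06]
        if mid:
            c = mid[0]
            print(f"{name}: leaflet near mid-rank -> final {c.l_max:.1f} mm, "
                  f"t_mid {c.t_mid:.0f} Cd, w {c.w*1e3:.2f}e-3/Cd")
    print("predicted-curve tables written to", SCRATCH)


if __name__ == "__main__":
    main()
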