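#!/usr/bin/env python
"""Fit every organ's logistic and every plant's leaf-appearance function.

Reports goodness of fit (R^2, RMSE) per organ kind and the nesting of
internode expansion inside the leaflet window at the same phytomer.
Reads the crop from scratch/crop/ (run 01 first).
"""

import json
from pathlib import Path

import numpy as np

from roseshoot import Crop, fit_crop, leaflet_internode_offsets
from roseshoot.evaluation import CropFits  # noqa: F401  (type of the cache)

SCRATCH = Path("scratch/crop")
RESULTS = Path("results")


def main() -> None:
    crop = Crop.load(SCRATCH)
    fits = fit_crop(crop)
    fits.organ_fits.to_csv(SCRATCH / "organ_fits.csv", index=False)

    # per-kind goodness of fit, via refitting summaries stored in the table
    from roseshoot import fit_logistic
    r2 = {"lea": [], "int": []}
    rmse = {"lea": [], "int": []}
    nobs = {"lea": [], "int": []}
    for series in crop.organ_series():
        fit = fit_logistic(series)
        if fit.excluded or not fit.converged:
            continue
        r2[series.kind].append(fit.r_squared)
        rmse[series.kind].append(fit.rmse)
        nobs[series.kind].append(fit.n_obs)

    # leaflet/internode timing offsets per phytomer
    by_key = {}
    for series in crop.organ_series():
        fit = fit_logistic(series)
        if not fit.excluded and fit.converged:
            by_key[(series.plant_id, series.kind, round(series.relative_rank, 6))] = fit
    starts, ends = [], []
    for (pid, kind, rank), fit in by_key.items():
        if kind != "lea":
            continue
        mate = by_key.get((pid, "int", rank))
        if mate is None:
            continue
        s, e = leaflet_internode_offsets(fit, mate)
        starts.append(s)
        ends.append(e)

    summary = {
        "n_fitted": {k: len(r2[k]) for k in r2},
        "mean_r_squared": {k: round(float(np.mean(r2[k])), 3) for k in r2},
        "mean_rmse_mm": {k: round(float(np.mean(rmse[k])), 2) for k in rmse},
        "mean_n_obs_per_curve": {k: round(float(np.mean(nobs[k])), 1) for k in nobs},
        "mean_offset_leaflet10_before_internode10_cd": round(float(np.mean(starts)), 1),
        "mean_offset_leaflet90_after_internode90_cd": round(float(np.mean(ends)), 1),
    }
    with open(RESULTS / "fit_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print("logistic fits:", summary["n_fitted"])
    print("mean R^2:", summary["mean_r_squared"], "mean RMSE:", summary["mean_rmse_mm"])
    print("internode window nested inside leaflet window:",
          summary["mean_offset_leaflet10_before_internode10_cd"], "Cd at 10%,",
          summary["mean_offset_leaflet90_after_internode90_cd"], "Cd at 90%")


if __name__ == "__main__":
    main()
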