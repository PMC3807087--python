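{
  "comment": "Calibrated rank profiles (LOESS estimates pooled over the three study crops). w is stored x1000 in 1/Cd, t0 in Cd since bud break, lm in mm. null = not estimated at that rank (sub-12-mm basal internodes carry only a final length; no leaflet exists at the peduncle rank).",
  "grid": [0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.93, 1.0],
  "leaflet": {
    "w_x1000": [null, null, null, 7.39, 7.16, 6.94, 6.72, 6.53, 6.31, 6.11, 5.93, 5.78, 5.66, 5.56, 5.53, 5.54, 5.60, 5.70, 5.79, 5.84, null],
    "t0": [null, null, null, 74.7, 82.4, 89.7, 97.1, 105.0, 116.6, 132.9, 154.3, 180.7, 211.6, 250.3, 281.9, 313.6, 340.2, 362.6, 381.4, 393.3, null],
    "lm": [null, null, null, 19.6, 27.1, 34.3, 41.5, 46.9, 52.5, 55.3, 57.8, 60.1, 62.7, 65.9, 68.4, 71.1, 73.1, 73.4, 72.2, 71.4, null]
  },
  "internode": {
    "w_x1000": [null, null, null, null, 11.72, 10.99, 10.35, 9.76, 9.27, 8.88, 8.66, 8.76, 8.86, 8.95, 8.97, 8.94, 8.77, 8.43, 7.94, 7.34, 5.19],
    "t0": [null, null, 23.7, 38.8, 54.9, 70.5, 86.1, 100.4, 118.8, 138.8, 162.6, 189.4, 217.7, 250.3, 277.0, 306.1, 334.8, 363.9, 394.6, 414.2, 457.6],
    "lm": [5.9, 7.0, 9.0, 10.4, 11.7, 12.5, 13.0, 13.3, 14.6, 16.1, 17.9, 20.4, 23.4, 28.2, 31.7, 33.6, 32.4, 26.1, 14.4, 8.0, 52.7]
  }
}
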