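# Default virtual-crop configuration (see roseshoot.synthetic.CropConfig).
# Profiles and coordination polynomials default to the shipped calibration.
n_plants: 30
phytomer_min: 10
phytomer_max: 16
alpha_mean: 15.0
alpha_sd: 6.0
phyllochron_fast_mean: 6.0
phyllochron_fast_sd: 2.0
phyllochron_slow_mean: 35.0
phyllochron_slow_sd: 7.0
c_mean: 0.45
c_sd: 0.07
size_cv: 0.10
t_mid_sd: 18.0
appearance_noise_sd: 5.0
visit_interval_days: 1.1667
thermal_rate: 18.1
measurement_sd: 0.8
rounding_mm: 1.0
visibility_lag: 15.0
seed: 0
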