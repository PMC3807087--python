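{
  "d_lea0": 61.5,
  "d_lea1": 1.62,
  "d_lea2": -0.00113,
  "d_int0": 70.6,
  "d_int1": 1.34,
  "d_ped0": 220.0,
  "d_ped1": 0.893
}
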