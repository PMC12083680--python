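{
  "la": {
    "activation_amplitude": 1.0,
    "activation_duration": 0.2,
    "activation_onset": 0.74,
    "la_a_res": 0.5,
    "la_b_res": 0.049,
    "la_ees": 0.45,
    "la_v0": 0.0,
    "wall_resistance": 0.008
  },
  "lv": {
    "activation_amplitude": 1.0,
    "activation_duration": 0.3,
    "activation_onset": 0.0,
    "lv_a_res": 0.8,
    "lv_b_res": 0.02,
    "lv_ees": 1.8818,
    "lv_v0": 10.0,
    "wall_resistance": 0.002
  },
  "pa": {
    "compliance": 0.8,
    "outflow_resistance": 0.08,
    "unstressed_volume": 50.0
  },
  "pv": {
    "compliance": 0.25,
    "outflow_resistance": 0.03,
    "unstressed_volume": 80.0
  },
  "ra": {
    "activation_amplitude": 1.0,
    "activation_duration": 0.2,
    "activation_onset": 0.74,
    "ra_a_res": 0.4,
    "ra_b_res": 0.12,
    "ra_ees": 0.25,
    "ra_v0": 5.0,
    "wall_resistance": 0.004
  },
  "rhythm": {
    "atrial_active": true,
    "av_delay": 0.16,
    "cycle_lengths": [
      1.0
    ]
  },
  "rv": {
    "activation_amplitude": 1.0,
    "activation_duration": 0.3,
    "activation_onset": 0.0,
    "rv_a_res": 0.3,
    "rv_b_res": 0.045,
    "rv_ees": 0.65,
    "rv_v0": 10.0,
    "wall_resistance": 0.002
  },
  "sa": {
    "compliance": 1.3708,
    "outflow_resistance": 0.4823,
    "unstressed_volume": 100.0
  },
  "sv": {
    "compliance": 0.8,
    "outflow_resistance": 0.1342,
    "unstressed_volume": 300.0
  },
  "total_volume": 1041.3402,
  "valves": {
    "aov_resistance": 0.014,
    "mv_resistance": 0.05,
    "puv_resistance": 0.02,
    "tv_resistance": 0.05
  }
}
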