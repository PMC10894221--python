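{
  "comment": "Default desk-scale calibration. Circuit values (supply, series resistors, coupling capacitors, pulse length) follow the measured hardware; sensing-capacitance scale and sensor gains are chosen so that every task stimulus keeps the network inside its capacitive-coupling locking range (about 8% natural-frequency spread at a 0.2 coupling ratio) while distinct stimuli land at distinct phase-locked states. Sensor baselines and gains are deliberately heterogeneous: a uniform capacitance scaling leaves relative phase patterns unchanged, so identical sensors could not separate the all-rest from the all-pressed mode.",
  "circuit": {
    "v_dd": 10.0,
    "r_load": 8200.0,
    "c_couple": 1e-10,
    "pulse_duration": 0.0003,
    "record_stride": 4
  },
  "splay_circuit": {
    "r_load": 10200.0,
    "c_parallel": 1e-09
  },
  "stretch_sensors": [
    {
      "kind": "stretch",
      "c_base": 5e-10,
      "gain": 0.03,
      "jitter_sigma": 0.001
    },
    {
      "kind": "stretch",
      "c_base": 5.03e-10,
      "gain": 0.045,
      "jitter_sigma": 0.001
    },
    {
      "kind": "stretch",
      "c_base": 5.06e-10,
      "gain": 0.06,
      "jitter_sigma": 0.001
    }
  ],
  "touch": {
    "reference_c": 5.75e-10,
    "reference_jitter_sigma": 0.001,
    "pressure_sensor": {
      "kind": "pressure",
      "c_base": 5e-10,
      "gain": 0.15,
      "jitter_sigma": 0.001
    }
  },
  "dm": {
    "j_e": 2.0,
    "j_m": -1.0,
    "alpha": 0.3,
    "beta": 0.7,
    "gamma": 0.641,
    "theta": 1.0,
    "tau_s": 100.0,
    "dt_dm": 0.5,
    "r_dec": 2.5
  },
  "training": {
    "target_pos": 1.0,
    "target_neg": -1.0,
    "rls_lambda": 100.0,
    "update_stride": 1,
    "train_window": 4e-05,
    "n_repeats": 2,
    "transient_cut": 0.00012,
    "n_taps": 3
  },
  "d2d": {
    "vth_range_full": [
      3.55,
      4.1
    ],
    "vhold_range_full": [
      1.52,
      1.96
    ],
    "default_scale": 0.25
  }
}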