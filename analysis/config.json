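{
  "out_root": "scratch/analysis_run",
  "simulate": {
    "n_male": 20,
    "n_female": 20,
    "grid_shape": [12, 12, 12],
    "n_volumes": 160,
    "tr_seconds": 2.6,
    "effect_d": 2.0,
    "seed": 10
  },
  "group": {
    "forming_threshold_p": 0.001,
    "n_perm": 500,
    "seed": 11
  },
  "mvpa": {
    "kernel": "linear",
    "cross_kernel": "rbf",
    "C": 1.0,
    "n_perm": 499,
    "seed": 12
  },
  "eyetrack": {
    "n_male": 15,
    "n_female": 15,
    "n_clips": 4,
    "clip_duration": 12.0,
    "seed": 13
  }
}
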