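{
  "stages": ["palm", "poses", "bret"],
  "seed": 7,
  "palm": {
    "sim": {
      "counts_per_size": {"1": 30, "2": 15, "3": 5},
      "min_center_sep_nm": 300.0,
      "cluster_radius_nm": 10.0,
      "loc_error_sd_nm": 5.0,
      "blink_rate": 0.0
    },
    "census": {
      "dedup_radius_nm": 20.0,
      "search_radius_nm": 50.0,
      "assignment_mode": "greedy_seed",
      "density_threshold_per_um2": 100.0
    },
    "dedup": false
  },
  "poses": {
    "sim": {
      "n_poses": 300,
      "tilt_range": [0.0, 0.8],
      "zoffset_range": [-12.0, 12.0]
    },
    "filter": {
      "tilt_max_rad": 0.4,
      "z_offset_max_A": 6.0,
      "keep_best": 4000
    },
    "rmsd_cutoff_A": 3.0
  },
  "bret": {
    "saturation": {
      "bretmax": 0.3,
      "bret50": 0.05,
      "noise_sd": 0.01,
      "replicates": 3
    },
    "kinetics": {
      "k_per_s": 0.02,
      "plateau": 0.05,
      "noise_sd": 0.002,
      "replicates": 3
    },
    "dose_response": {
      "ec50_m": 4.345e-6,
      "emax": 1.0,
      "baseline": 0.0,
      "noise_sd": 0.02,
      "replicates": 3
    }
  }
}
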