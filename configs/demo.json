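{
  "n_genes": 1000,
  "probes_per_gene_mean": 4.0,
  "fraction_expressed": 0.8,
  "hit_spec": [
    {
      "n_genes": 10,
      "s_normoxia": 0.0,
      "s_hypoxia": -0.5
    },
    {
      "n_genes": 10,
      "s_normoxia": -0.5,
      "s_hypoxia": 0.0
    }
  ],
  "passages": 10,
  "doublings_per_passage": 3.0,
  "bottleneck": 1000000,
  "measurement_cv": 0.2,
  "detection_floor": 0.001,
  "signal_scale": 10000.0,
  "fold_threshold": 5.0,
  "min_shrnas": 4,
  "efficacy_low": 0.7,
  "efficacy_high": 1.0,
  "hit_min_probes": null,
  "seed": 0,
  "growth": {
    "n0": 10000.0,
    "doublings": 7.0,
    "replicate_cv": 0.05,
    "n_replicates": 3
  },
  "qpcr": {
    "noise_sd": 0.1,
    "reference_gene": "ACTB",
    "reference_ct": 17.0,
    "base_ct_low": 18.0,
    "base_ct_high": 30.0,
    "control_folds": {
      "GLUT1": 7.0,
      "PDK1": 4.0
    }
  },
  "analysis": {
    "alpha": 0.05,
    "fold_min": 2.0,
    "use_welch": false,
    "require_direction": true,
    "pseudocount": 0.0,
    "n_negative_controls": 5,
    "expression_fn_rate": 0.0
  }
}
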