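{
  "description": "Logistic model for the HRD probability score over the six HRD-associated feature groups. Features are standardized as (value - mean) / scale before weighting. Editable; means/scales are cohort-reference constants for this package's feature definitions.",
  "intercept": -3.0,
  "features": {
    "sbs3_fraction": {"mean": 0.05, "scale": 0.10, "weight": 1.0},
    "sbs8_fraction": {"mean": 0.02, "scale": 0.05, "weight": 0.5},
    "id6_fraction": {"mean": 0.05, "scale": 0.10, "weight": 1.0},
    "rs_fraction": {"mean": 0.10, "scale": 0.15, "weight": 1.0},
    "mh_del_proportion": {"mean": 0.10, "scale": 0.15, "weight": 1.0},
    "loh_segment_count": {"mean": 5.0, "scale": 5.0, "weight": 0.5}
  }
}
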