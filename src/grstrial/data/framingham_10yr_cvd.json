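{
  "name": "framingham_10yr_general_cvd_2008",
  "description": "Sex-specific 10-year general cardiovascular risk equation (Cox model with log-transformed continuous covariates, published baseline survival and mean linear predictor). Risk = 1 - S0 ^ exp(lp - lp_mean).",
  "horizon_years": 10,
  "model": "baseline_survival",
  "sex": {
    "female": {
      "baseline_survival": 0.95012,
      "lp_mean": 26.1931,
      "covariates": [
        {"name": "age", "transform": "log", "beta": 2.32888, "range": [30, 74]},
        {"name": "total_chol", "transform": "log", "beta": 1.20904, "range": [100, 405]},
        {"name": "hdl_chol", "transform": "log", "beta": -0.70833, "range": [10, 100]},
        {"name": "systolic_bp", "transform": "log", "beta": 2.76157, "when": "bp_untreated", "range": [90, 200]},
        {"name": "systolic_bp", "transform": "log", "beta": 2.82263, "when": "bp_treated", "range": [90, 200]},
        {"name": "smoker", "transform": "identity", "beta": 0.52873},
        {"name": "diabetes", "transform": "identity", "beta": 0.69154}
      ]
    },
    "male": {
      "baseline_survival": 0.88936,
      "lp_mean": 23.9802,
      "covariates": [
        {"name": "age", "transform": "log", "beta": 3.06117, "range": [30, 74]},
        {"name": "total_chol", "transform": "log", "beta": 1.12370, "range": [100, 405]},
        {"name": "hdl_chol", "transform": "log", "beta": -0.93263, "range": [10, 100]},
        {"name": "systolic_bp", "transform": "log", "beta": 1.93303, "when": "bp_untreated", "range": [90, 200]},
        {"name": "systolic_bp", "transform": "log", "beta": 1.99881, "when": "bp_treated", "range": [90, 200]},
        {"name": "smoker", "transform": "identity", "beta": 0.65451},
        {"name": "diabetes", "transform": "identity", "beta": 0.57367}
      ]
    }
  }
}
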