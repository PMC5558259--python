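{
  "name": "framingham_30yr_cvd_competing_exponential",
  "description": "Sex-specific 30-year cardiovascular risk in a competing-risk form. Two proportional-hazards blocks (CVD event, competing non-CVD death) are reduced to constant hazards from their 30-year baseline survivals; 30-year risk is the event cumulative incidence under the combined hazard. Numeric entries are DOCUMENTED ILLUSTRATIVE DEFAULTS (event betas mirror the bundled 10-year table; baseline survivals and the death block are plausible-magnitude placeholders) and are user-overridable; the functional contract, not these numbers, is the tested behavior.",
  "horizon_years": 30,
  "model": "competing_exponential",
  "sex": {
    "female": {
      "event": {
        "baseline_survival": 0.85,
        "covariates": [
          {"name": "age", "transform": "log", "beta": 2.32888, "mean": 55, "range": [20, 74]},
          {"name": "total_chol", "transform": "log", "beta": 1.20904, "mean": 210, "range": [100, 405]},
          {"name": "hdl_chol", "transform": "log", "beta": -0.70833, "mean": 52, "range": [10, 100]},
          {"name": "systolic_bp", "transform": "log", "beta": 2.76157, "mean": 125, "range": [90, 200]},
          {"name": "bp_treated", "transform": "identity", "beta": 0.35, "mean": 0.15},
          {"name": "smoker", "transform": "identity", "beta": 0.52873, "mean": 0.18},
          {"name": "diabetes", "transform": "identity", "beta": 0.69154, "mean": 0.05}
        ]
      },
      "death": {
        "baseline_survival": 0.88,
        "covariates": [
          {"name": "age", "transform": "log", "beta": 3.2, "mean": 55},
          {"name": "systolic_bp", "transform": "log", "beta": 0.5, "mean": 125},
          {"name": "smoker", "transform": "identity", "beta": 0.6, "mean": 0.18},
          {"name": "diabetes", "transform": "identity", "beta": 0.5, "mean": 0.05}
        ]
      }
    },
    "male": {
      "event": {
        "baseline_survival": 0.78,
        "covariates": [
          {"name": "age", "transform": "log", "beta": 3.06117, "mean": 55, "range": [20, 74]},
          {"name": "total_chol", "transform": "log", "beta": 1.12370, "mean": 210, "range": [100, 405]},
          {"name": "hdl_chol", "transform": "log", "beta": -0.93263, "mean": 46, "range": [10, 100]},
          {"name": "systolic_bp", "transform": "log", "beta": 1.93303, "mean": 127, "range": [90, 200]},
          {"name": "bp_treated", "transform": "identity", "beta": 0.35, "mean": 0.15},
          {"name": "smoker", "transform": "identity", "beta": 0.65451, "mean": 0.22},
          {"name": "diabetes", "transform": "identity", "beta": 0.57367, "mean": 0.06}
        ]
      },
      "death": {
        "baseline_survival": 0.84,
        "covariates": [
          {"name": "age", "transform": "log", "beta": 3.2, "mean": 55},
          {"name": "systolic_bp", "transform": "log", "beta": 0.5, "mean": 127},
          {"name": "smoker", "transform": "identity", "beta": 0.6, "mean": 0.22},
          {"name": "diabetes", "transform": "identity", "beta": 0.5, "mean": 0.06}
        ]
      }
    }
  }
}
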