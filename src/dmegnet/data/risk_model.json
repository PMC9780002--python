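{
  "name": "pd1neg-gastric-10gene",
  "description": "Published 10-gene prognostic risk score for PD-1-negative gastric cancer; RiskScore = sum(coefficient_g * log2 expression_g), no intercept.",
  "genes": ["SELL", "EOMES", "IYD", "RP11-44K6.2", "JPH1", "TRIM29", "PCED1B", "TSPAN8", "CEACAM5", "PPP1R16B"],
  "coefficients": {
    "SELL": 0.621,
    "EOMES": 0.247,
    "IYD": -0.028,
    "RP11-44K6.2": 0.086,
    "JPH1": -0.4,
    "TRIM29": -0.084,
    "PCED1B": 0.348,
    "TSPAN8": -0.045,
    "CEACAM5": -0.084,
    "PPP1R16B": -0.944
  }
}
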