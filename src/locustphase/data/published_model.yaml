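# Published solitariness model (built-in asset, version 1.0).
# The linear predictor eta = intercept + sum(coefficients[k] * marker[k])
# is mapped to P-sol = exp(eta) / (1 + exp(eta)), the probability that
# the animal belongs to the solitary phase (solitary coded 1).
name: psol-published
version: "1.0"
intercept: 2.361
coefficients:
  TDM: -0.016
  FOM: -0.172
  AI: -0.005
threshold: 0.5
label_convention: "P-sol is the probability of the solitary phase (solitary = 1, gregarious = 0)"
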