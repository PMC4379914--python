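"""Score animals with the published logistic solitariness model.

P-sol = exp(eta) / (1 + exp(eta)) with
eta = 2.361 - 0.016*TDM - 0.172*FOM - 0.005*AI
is the probability that an animal belongs to the solitary phase.
"""

import pandas as pd

import locustphase as lp

geom = lp.GEOMETRY_PRESETS["open-area"]
model = lp.published_model()
print(f"model: intercept={model.intercept}, coefficients={model.coefficients}\n")

tables = []
for phase, seed in [("gregarious", 11), ("solitary", 12)]:
    cohort = lp.simulate_cohort(
        lp.CohortSpec(10, lp.default_phase_params(phase), seed=seed, arm_label=phase),
        geom,
    )
    tables.append(lp.features_table(cohort, geom))
scored = lp.score_features(pd.concat(tables, ignore_index=True), model)

print(scored[["animal_id", "arm_label", "TDM", "FOM", "AI", "P_sol", "predicted_label"]]
      .round(3).to_string(index=False))
med = scored.groupby("arm_label")["P_sol"].median()
print(f"\nmedian P-sol: gregarious={med['gregarious']:.3f}, solitary={med['solitary']:.3f}")
print("P-sol near 0 = gregarious-like behavior, near 1 = solitary-like.")
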