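"""Extract the eleven behavioral markers from simulated recordings.

The marker set mixes zone statistics (entries, latencies, durations),
thigmotaxis measures, and motility measures; the attraction index AI is
time near the stimulus group minus time at the opposite end.
"""

import locustphase as lp

geom = lp.GEOMETRY_PRESETS["open-area"]
cohort = lp.simulate_cohort(
    lp.CohortSpec(4, lp.default_phase_params("gregarious"), seed=3, arm_label="greg"),
    geom,
)
table = lp.features_table(cohort, geom)
print(table.round(2).to_string(index=False))

print(
    "\nEach row is one 6-min recording. TDM (cm) and FOM (bouts) capture"
    "\nmotility; AI > 0 means the animal stayed mostly on the stimulus side."
)
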