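"""Compare two treatment arms with the assay's statistics battery.

A receptor-agonist arm is modelled as a partial shift of solitary
animals toward the gregarious regime (lam = 0.45).  P-sol and AI are
compared by Mann-Whitney U; TDM and FOM by pooled Student t.
"""

import pandas as pd

import locustphase as lp

geom = lp.GEOMETRY_PRESETS["open-area"]
model = lp.published_model()

saline = lp.default_phase_params("solitary")
agonist = lp.blend_params(saline, lp.default_phase_params("gregarious"), 0.45)

tables = []
for label, params, seed in [("saline", saline, 21), ("agonist", agonist, 22)]:
    cohort = lp.simulate_cohort(
        lp.CohortSpec(25, params, seed=seed, arm_label=label), geom
    )
    tables.append(lp.features_table(cohort, geom))
scored = lp.score_features(pd.concat(tables, ignore_index=True), model)

a = scored[scored.arm_label == "saline"]
b = scored[scored.arm_label == "agonist"]
for marker, test in [("P_sol", "MWU"), ("TDM", "t"), ("FOM", "t"), ("AI", "MWU")]:
    if test == "t":
        res = lp.student_t(a[marker], b[marker])
    else:
        res = lp.mann_whitney_u(a[marker], b[marker])
    print(f"{marker:6s} {res.test_name:15s} statistic={res.statistic:9.3f} "
          f"p={res.p_value:.4f}  ({res.method_detail})")

print(
    "\nA small p for P-sol says the agonist arm shifted toward the"
    "\ngregarious phase; the marker tests say which behaviors moved."
)
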