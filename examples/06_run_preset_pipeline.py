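"""Run a full scenario preset: isolation time course with Dop2 blockade.

Saline-injected gregarious controls drift toward the solitary phase as
isolation lengthens; the receptor-blockade arms are held at the
gregarious regime.  The pipeline simulates every arm, scores P-sol,
and compares saline vs blockade at each time point by Mann-Whitney U.
"""

import locustphase as lp

plan = lp.scenario_presets()["dop2-blockade-psol"]
report = lp.run_experiment(plan, seed=1)

print("median P-sol per arm:")
for label in sorted(report.arm_summaries):
    s = report.arm_summaries[label]
    print(f"  {label:15s} median={s['P_sol']['median']:.3f} "
          f"[q1={s['P_sol']['q1']:.3f}, q3={s['P_sol']['q3']:.3f}] n={s['n']}")

print("\nsaline vs blockade at each isolation time (MWU on P-sol):")
for entry in report.comparisons:
    print(f"  {entry['groups'][0]:12s} vs {entry['groups'][1]:14s} "
          f"U={entry['statistic']:6.1f} p={entry['p_value']:.4f}")

print(
    "\nControls climb toward P-sol ~ 0.8 by 60 min while blockade arms stay"
    "\nnear 0, so the U tests separate the arms at the later time points."
)
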