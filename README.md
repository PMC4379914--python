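# locustphase

Behavioral-phase phenotyping of locusts from arena trajectories.

Migratory locusts (*Locusta migratoria*) switch between two density-dependent
behavioral phases: **gregarious** animals are highly motile and attracted to
conspecifics, **solitary** animals are weakly motile and avoidant. The
standard laboratory readout is the conspecific attraction–avoidance assay: a
single animal is recorded for 6 minutes in a rectangular arena whose far
chamber holds a group of stimulus locusts, its track is reduced to eleven
behavioral markers, and a binary logistic regression converts those markers
into **P-sol**, the probability that the animal belongs to the solitary
phase. This package implements that full analysis chain as a tested,
reusable library:

- **`locustphase.arena`** — arena geometry, the stimulus/opposite/middle
  zone partition, the near-wall band, and track-file IO (delimited
  `time,x,y` text plus a cohort manifest).
- **`locustphase.simulate`** — synthetic cohorts: a two-state (pause/move)
  biased persistent random walk with reflective boundaries, calibrated
  gregarious/solitary parameter presets, parameter blending for treatment
  arms, and log-normal molecular time courses (brain dopamine, receptor
  mRNA) with eight replicates per time point.
- **`locustphase.features`** — the eleven markers: EFISA, LFOISA, TDCW,
  EFCW, EFIOSA, LFOIOSA, MDTSG, TDM, TDMV, FOM and AI.
- **`locustphase.classifier`** — the logistic solitariness model. The
  published coefficients ship as a built-in asset:

      eta   = 2.361 − 0.016·TDM − 0.172·FOM − 0.005·AI
      P_sol = e^eta / (1 + e^eta)

  plus maximum-likelihood refitting (Newton iteration with separation
  detection), forward marker selection, and per-class classification rates.
- **`locustphase.stats`** — Mann–Whitney U (exact enumeration for small
  tie-free samples, tie-corrected normal approximation otherwise), pooled
  Student t, one-way ANOVA, and Tukey's HSD, all computed from first
  principles.
- **`locustphase.pipeline`** — experiment plans (simulated or file-backed
  arms), the fixed test-to-marker mapping (P-sol and AI by MWU, TDM/FOM by
  t or ANOVA+Tukey), deterministic seeded reports, and frozen scenario
  presets emulating receptor-pharmacology and isolation/crowding designs.

A thin CLI (`locustphase simulate|extract|score|compare|run|presets`) wraps
the same functions for shell use.

## Worked example

```python
import pandas as pd
import locustphase as lp

geom = lp.GEOMETRY_PRESETS["open-area"]      # 25 x 30 cm open test area
model = lp.published_model()

tables = []
for phase, seed in [("gregarious", 11), ("solitary", 12)]:
    cohort = lp.simulate_cohort(
        lp.CohortSpec(10, lp.default_phase_params(phase), seed=seed,
                      arm_label=phase), geom)
    tables.append(lp.features_table(cohort, geom))
scored = lp.score_features(pd.concat(tables, ignore_index=True), model)
print(scored.groupby("arm_label")["P_sol"].median())
```

prints

```
arm_label
gregarious    0.002
solitary      0.856
```

i.e. the simulated gregarious cohort scores near 0 (gregarious-like) and
the solitary cohort near 1 (solitary-like) under the published model.
Comparing the two arms with `lp.mann_whitney_u` on P-sol gives p ≪ 0.001.
The `examples/` directory holds one short narrative script per capability
(simulation, marker extraction, scoring, arm comparison, time-course ANOVA,
full preset pipeline); each prints the numbers it computes and a line on
what they mean.

## Notes

The arena recordings behind the originally published model are not public,
so the classification rates printed alongside that model are not
recomputable; this package's synthetic cohorts are a calibrated stand-in
whose limitations are discussed in `docs/methods.md`.
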