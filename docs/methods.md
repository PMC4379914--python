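# Methods

This note documents the models, conventions and numerical choices behind
`locustphase`, in the order the analysis chain runs.

## Arena geometry and zones

The assay arena is a 40 × 30 cm rectangle whose two 7.5 × 30 cm end
chambers are walled off (one holds the stimulus group), leaving a
25 × 30 cm open test area. Because the animal can only occupy the open
area, the default geometry preset (`"open-area"`) defines the stimulus and
opposite zones as fractions (default 25%) of the 25 cm open extent; a
`"full-arena"` preset (40 cm) is provided because it is equally defensible
to refer the zone fractions to the full footprint, and nothing in the
marker definitions decides between them. Users comparing against external
numbers should state which preset they used.

Coordinates: origin at the lower corner of the stimulus-side wall, x
increasing away from the stimulus group, units cm and seconds. Zone
membership along x is half-open (`[lo, hi)`) except at the far arena
boundary, which is closed; this makes stimulus/opposite/middle an exact
partition of the arena (verified by grid sweep) with deterministic
tie-breaks on shared edges, and lets the two end zones tile the arena
exactly when the zone fraction is 0.5.

The near-wall band (thigmotaxis zone for TDCW/EFCW) is every point within
`wall_margin` of a wall. The margin is not a published quantity; the
default is 3 cm, about one fourth-stadium body length, and it is
configurable and logged in every pipeline report. The reference point for
mean distance to the stimulus group (MDTSG) is the centre of the
stimulus-side wall, since the stimulus chamber spans the full arena width
behind that wall.

Default sampling step is 0.04 s (25 samples/s, typical of video
tracking); recordings default to 360 s.

## Marker conventions

Occupancy is sample-based with no sub-sample boundary interpolation: the
interval between samples *i* and *i+1* carries the zone of sample *i*
(sample-and-hold). Durations are therefore multiples of the sampling step
and the stimulus, opposite and middle durations sum exactly to the
recording duration — which also fixes the attraction index bounds
AI ∈ [−duration, +duration]. A consequence worth knowing: the final
sample contributes entries and latency but no occupancy time.

Entries count out→in transitions of the occupancy sequence, with a
recording that starts inside the zone counting as one entry. Latency of
first occurrence is the time of the first in-zone sample; a zone never
visited is censored to the full recording duration. (Edge case: a first
visit on the very last sample yields a latency numerically equal to the
censoring value.)

Movement bouts: instantaneous speed is the step displacement divided by
the step, smoothed by a centred moving average (default 5 samples);
maximal runs at or above the speed threshold (default 0.5 cm/s) lasting at
least the minimum bout length (default 1 s) are bouts. FOM is the number
of bouts — i.e. "frequency of movement" is read as bout starts per
recording, not samples-in-motion, an assumption the original tracking
software's settings leave open — and TDMV the summed bout durations. All
frequency markers are raw counts per 6-min recording, because the
solitariness model's coefficients act on whole-recording values. The
three bout parameters are explicit (`BoutConfig`), configurable, and
logged with every pipeline run, since they materially affect FOM/TDMV.

## The solitariness model

The published model retains TDM, FOM and AI with
η = 2.361 − 0.016·TDM − 0.172·FOM − 0.005·AI and
P-sol = e^η/(1+e^η), the probability of solitary phase (solitary coded 1,
gregarious 0). The printed right-hand side is the linear predictor η, not
the probability: a probability could not take an unbounded affine form,
and the logistic transform is the only reading on which P-sol lies in
(0, 1). Classification uses threshold 0.5 with ties to solitary.
P-sol is evaluated through a numerically stable logistic, so extreme
markers saturate to 0/1 without overflow.

Refitting is straight Newton–Raphson on the log-likelihood: max 50
iterations, convergence when the largest coefficient change falls below
1e-8. Complete separation — which the phase contrast produces readily,
since well-separated cohorts differ in TDM by an order of magnitude — is
not an error: iteration stops and a flag is set once any slope magnitude
exceeds 50 without convergence (on marker scales of cm and counts, |β|>50
has no behavioral interpretation). Rank-deficient designs raise instead.
The fit is cross-checked against an independent maximum-likelihood
implementation in the test suite.

Forward marker selection starts from the intercept-only model and greedily
adds the candidate that most improves the criterion, with ties broken by
the canonical marker order. The default criterion is BIC rather than AIC:
each greedy round maximises over up to eleven approximately-χ²(1)
likelihood improvements, so an AIC penalty admits two to four pure-noise
markers in a null design, while BIC keeps the false-selection rate near
zero. AIC and overall classification accuracy are available as
alternatives (accuracy ties frequently on small cohorts, which is why it
is not the default).

## Synthetic cohorts

No public recordings of the assay exist, so the package ships a minimal
generative model — the package's own construction, chosen so all eleven
markers are non-degenerate and the phase contrast is controlled by
interpretable parameters:

* a two-state pause/move Markov chain (per-second rates `p_start_move`,
  `p_stop_move`; stationary moving fraction p/(p+q), which simulations
  verify);
* while moving, truncated-normal (at zero) step lengths with mean
  `speed_mean·dt`;
* heading evolves as a wrapped persistent walk (turning-angle spread
  `(1 − persistence)·π·√dt`) blended with a unit drift toward/away from
  the stimulus wall (weight |`stimulus_bias`|, sign giving direction) and
  a unit drift toward the nearest wall (weight `wall_affinity`);
* reflective boundaries; the animal starts paused at the arena centre
  with uniform random heading.

The frozen phase presets encode the qualitative contrast the assay was
built to measure. Gregarious: rates 0.05/0.08 s⁻¹, speed 2.0 ± 0.6 cm/s,
bias +0.5, wall affinity 0.2 — giving, over 6 min, total distance ~250–300
cm, ~10 bouts and a strongly positive AI. Solitary: rates 0.012/0.15 s⁻¹,
speed 0.8 ± 0.3 cm/s, bias −0.5, wall affinity 0.5 — total distance
~20–30 cm, a few bouts, non-positive AI. These values are calibrations,
not measurements: the source assay reports no quantitative motility for
either phase. They place the two regimes on opposite sides of the
published model (median P-sol ≈ 0.005 vs ≈ 0.85 in seeded runs).

Treatment arms (agonist, antagonist, RNAi, isolation time points) are
modelled as field-wise linear interpolation between the two presets
(`blend_params`); isolation time courses ramp the blend weight with time.
This is a deliberate simplification: arms are parameter shifts by
construction, with no mechanistic neurochemistry coupling dopamine to
behavior. Passing tests therefore demonstrate that the *analysis*
recovers contrasts and time-course shapes that are present by
construction — they say nothing about real locusts, real tracker noise
(identity swaps, jitter, missing frames), or real between-animal
heterogeneity, none of which the generator emulates.

Molecular time courses draw replicates as `mean·exp(ε)`,
ε ~ N(0, σ²) with σ = √log(1+cv²) so the coefficient of variation equals
`cv` (default 0.2) — multiplicative, positive-valued noise typical of
chromatographic and qPCR quantification. Default design: time points 0,
1, 4, 16, 32 h with eight replicates each. The shipped profiles encode
the qualitative shapes of the emulated designs (e.g. a five-fold receptor
mRNA induction peaking at 4 h of crowding; a dopamine fall within 1 h of
isolation).

Seeding: a single cohort seed expands into stable per-animal substreams
via `SeedSequence(entropy=seed, spawn_key=(animal_index,))`, so cohort
results are independent of generation order and bit-identical across
runs and platforms at fixed seed.

## Statistics

All tests are two-sided; the source analysis plan does not state
sidedness or tie handling, so the conventions below match the defaults of
the commercial package it used. Statistics are computed from first
principles; only reference distributions (normal, t, F, studentized
range) come from scipy.

* **Mann–Whitney U**: U = #{aᵢ < bⱼ} + ½·ties. Both orientations are
  reported; the headline statistic is min(U, n₁n₂−U), since which one the
  original reports cannot be determined from printed values. The p-value
  is exact — full enumeration of the null rank distribution by the
  classical recurrence — when n₁n₂ ≤ 400 and the data are tie-free;
  otherwise a tie-corrected normal approximation with continuity
  correction. The mode used is recorded per call.
* **Student t**: pooled variance, df = n₁+n₂−2 (the analysis plan never
  invokes a Welch correction; Welch is available). Zero pooled variance
  is flagged degenerate: t = 0, p = 1 for equal means, p = 0 otherwise.
* **One-way ANOVA**: F = MS_between/MS_within with (k−1, N−k) df; zero
  within-group variance flagged (F = ∞ or 0).
* **Tukey HSD**: studentized-range statistic per pair with the common
  within-group mean square (Tukey–Kramer standard error when group sizes
  differ); family-wise p from the studentized range distribution.

Identities verified in the tests: two-group F equals t²; two-group Tukey
equals the pooled t (q = √2·|t|); exact U equals brute-force enumeration
over all label assignments for every size pair ≤ 6; and all four tests
reject at ~5% under seeded null simulations (for the discrete exact U
test the achievable level at n = 20 per group is 0.049).

## Pipeline

`run_experiment` composes the stages in the assay's order and applies the
fixed test-to-marker mapping (P-sol → MWU; TDM/FOM → t for two arms,
ANOVA + Tukey for arm families; AI → MWU). Default simulated cohort size
is 30 animals per arm — the emulated designs imply roughly 20–35 per arm
without stating exact counts — at full recording scale (360 s, 0.04 s
step). Reports carry medians with quartiles for P-sol and the retained
markers, every test result, and a provenance block (plan hash, seed,
geometry, bout configuration, model source, package version); report
bodies contain no timestamps and are byte-identical across identical
seeded runs. Arm sub-seeds derive from the run seed and arm position; an
arm may also pin an explicit seed (which is how a null comparison of two
identical arms is expressed).

## Problem sizes used in the checks

The test suite and acceptance script run at desk scale: cohorts of 8–100
animals, recordings of 60–360 s, 1000-trajectory invariance sweeps at 60
samples each, 2000-replicate null calibrations, and a 2000-animal
coefficient-recovery fit. These sizes keep every property statistically
resolvable (e.g. ±0.005 binomial error on a 5% rejection rate) while the
whole suite runs in well under a minute of simulation time.

## Known limitations

* The generator is a phenomenological stand-in; see above for what
  passing tests do and do not show.
* The originally published 89.2%/91.2% per-class classification rates
  were computed on unreleased recordings and are not recomputable; the
  package reports its own rates on synthetic cohorts instead.
* Whether the published zone markers were computed over the 25 cm open
  area or the 40 cm footprint is unknowable; both presets are provided
  and no default is claimed to match the original.
* Occupancy has no sub-sample interpolation, so zone durations are
  quantised at the sampling step.
* Marker selection on small cohorts is unstable under any criterion;
  the BIC default controls false selection but will also miss weak true
  signals at small n.
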