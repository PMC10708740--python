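# Methods

## The fusion model

A work trial is a repeated lift → carry → static-hold cycle. Each
stage is scored with the observational method best matched to its
biomechanics: the NIOSH revised lifting equation (lifting index LI)
for the lift, OWAS action category for the carry, and the RULA grand
score for the static assembly hold. The three indices live on
incommensurable scales, so a composite needs both a normalisation and
a weighting:

1. **Normalisation.** Column-wise min-max over the trial set maps each
   index to [0, 1] without altering its distribution shape. A constant
   column maps to all zeros by convention. The consequence worth
   noting: normalised scores, and therefore the fused value, are
   *relative to the trial set*; adding a trial can change every other
   trial's value. That is inherent to the method, not an artefact.
2. **Entropy weighting.** Weights are objective functions of the data:
   per column, share probabilities over trials (0·ln 0 = 0), Shannon
   entropy scaled by 1/ln n, utility d = 1 − e, weights normalised to
   sum 1. High dispersion → low entropy → high weight. The pipeline
   order is fixed as *normalise first, then shares*: feeding raw
   scores to the entropy step instead changes the NIOSH entropy by
   ~0.1 and no longer reproduces the reference weight table, so the
   normalise-first variant is the one implemented.
3. **Time weighting.** Fatigue accumulates with time under load, so
   the fused value weights each stage by its measured duration:
   eⱼ = Σ rᵢⱼwᵢtᵢ / Σ tᵢ. The value is homogeneous of degree zero in
   the durations — only stage-time *proportions* matter — and is
   bounded by maxᵢ wᵢ.

Weights are always recomputed from the supplied matrix; the reference
weight values serve only as test expectations.

### A note on the reference per-trial fatigue table

The embedded per-trial fatigue values (`table4_fatigue`) cannot be
regenerated from the embedded score matrix by any choice of stage
durations: each fused value is a convex combination of the three
rᵢⱼ·wᵢ terms, and for two thirds of the trials the reference value
lies *below* the smallest such term. The original values were
evidently computed with additional unscored time in the denominator or
from higher-precision scores than the printed ones. The table is
therefore used exclusively as an input fixture to the correlation and
ANOVA validation, never as a reproduction target.

## Scoring engines

* **NIOSH.** HM = 25/H (1 for H ≤ 25 cm, 0 beyond 63 cm),
  VM = 1 − 0.003|V − 75|, DM = 0.82 + 4.5/D (1 for D ≤ 25 cm),
  AM = 1 − 0.0032·A, FM from the standard frequency table (three work
  duration classes × two vertical bands, linear interpolation between
  tabulated frequencies), CM from the coupling table. A multiplier of
  zero means the task is outside the equation's domain; LI is then
  reported as an infinite-risk sentinel with an explanatory note
  rather than a number that invites ranking.
* **OWAS.** Back digit from trunk flexion/twist/side-bend thresholds
  (bent > 20°, twisted > 20°, both → digit 4), arms digit from the
  count of upper arms elevated above 90°, legs digit from support
  flags and knee flexion, load digit from the standard <10 / 10–20 /
  >20 kg bands (so an exactly 20 kg part is load class 2). The action
  category comes from the published 4×3×7×3 classification matrix,
  shipped as a CSV resource and covered by an exhaustive domain test.
* **RULA.** Tables A, B and C as published, with muscle-use and force
  additions and the ≥8 / ≥7 row/column caps. Frame-based scoring
  brackets angles into the worksheet's bands and assesses the
  worse-scoring arm. The static assembly stage defaults to
  muscle-use = 1 (posture held beyond a minute). With a >10 kg load
  both force additions are 3, which saturates the grand score at high
  trunk flexion — expected behaviour for this task, which is why the
  monotonicity tests exercise the unloaded dynamic case.

The per-trial aggregation of cycle scores (max, mean or mode) is left
to the caller; the original recording platform did not state which it
logged, so `aggregate()` offers all three and defaults to the
conservative max.

## Synthetic data

The generator emulates one motion-capture trial of the laboratory
protocol: cycles of a 4 s lift, a 3 m carry at 1 m/s, and a 10 s
static hold, sampled at 60 Hz, with seeded bounded noise (Gaussian,
clipped at 3σ) on every channel. Trunk flexion follows a half-sine
during the lift — maximum angular velocity at the segment boundaries,
which is also what makes rule-based boundary detection sharp — and
settles at a height-dependent bent posture during the hold (deeper for
a lower vehicle body: 51° at 15 cm vs 33° at 45 cm at the defaults).
Test and acceptance runs use 2–3 cycles (34–51 s of trace); a full
30-min session is ~106 cycles and is generated the same way when
wanted.

What the generator does **not** emulate: sensor drift and soft-tissue
artefacts, inter-subject anthropometry, fatigue-induced posture decay
within a session, or any coupling between seat weight and movement
speed. Passing tests therefore demonstrate that the pipeline recovers
what the generator encodes, not that the segmentation thresholds are
correct for real capture data — on real data the thresholds are
configuration to be tuned against labelled recordings.

The stage segmenter classifies walking-flag frames as carrying, then
splits the remaining runs by smoothed trunk-flexion rate (0.25 s
moving average, 15°/s threshold): sustained motion is lifting,
stillness is the hold. Still runs shorter than 2 s merge into lifting
(the zero-velocity instant at the top of a lift is not a hold); motion
runs shorter than 1.5 s merge into static (settling into the bent
posture is a transition, not a lift). Worst observed boundary error on
48 generated trials spanning the factor grid: 0.13 s.

The oximetry pair generator produces 10-min, 1 Hz pre/post recordings:
the pre trace fluctuates inside the ±0.5 % resting band (slow
sinusoidal drift plus jitter, clipped at ±0.45 %), the post trace
plateaus at baseline + slope·fatigue with the same noise. The default
slope of −15 % per unit fatigue reproduces the observed range of
desaturation (−2.3 % to −18.5 %) over fatigue levels in [0, 1].

## Oximetry processing

rSO₂ = 100·C_HbO₂/(C_HbO₂ + C_HbR); scale-invariant in the
concentrations, clamped against float round-off at the 100 % boundary.
Baselines come from the longest window of ≥ 60 s whose peak-to-peak
spread is ≤ 1 % (motivated by the ±0.5 % resting fluctuation), ties
broken toward the latest window; the window statistic is the mean,
with median and last-sample alternatives exposed. The pre/post
difference is post − pre, so desaturation is negative.

## Energy model

E_pos = K_pos·T_pos·W in kcal, with K_pos in kcal/(min·kg) from an
editable CSV of typical published metabolic-cost coefficients
(lifting 0.100, loaded walking 0.080, walking 0.055, deep bend
standing 0.035, bent standing 0.030, bending 0.040, standing 0.022,
sitting 0.020). An optional load factor (1 + load/W) scales
load-carrying terms; it is off in the raw formula and on when pricing
an assembly trial. A 30-min trial at the cohort body mass of 68.28 kg
prices at roughly 120–145 kcal — a physiologically plausible 4–5
kcal/min. The commercial simulation totals in the embedded comparator
table (~1200–1900 kcal per 30 min) imply implausible metabolic rates
and likely use proprietary per-shift conventions; consequently only
the *ordering* of trial energies is validated (Spearman ρ ≈ 0.95
against the comparator table), never magnitudes.

## Statistics

Shapiro–Wilk and Pearson delegate to scipy; the balanced two-way
ANOVA (height × weight with interaction, 12 error df in the 2×3×3
design) is fitted via an OLS decomposition, with the classical
cell/marginal-means computation kept as an independent oracle in the
test suite. Only balanced complete layouts are accepted — all
sum-of-squares types coincide there, so no type ambiguity arises. A
constant response reports F = 0, p = 1 by convention instead of NaN.

`reproduce_reference_analysis()` recomputes the full validation
battery from the embedded tables. Reproduction status at the default
tolerances: entropy values to 3 d.p. and weights to 0.01 percentage
points (the reference OWAS weight of 41.194 % recomputes as 41.200 %,
a discrepancy of the reference's own rounding); both correlations to
3 d.p.; the rSO₂ ANOVA F values within 1 % relative. The fatigue- and
energy-response F values recompute 9–11 % below the reference —
consistent with the reference analysis having used higher-precision
data than its printed tables — and are reported with their relative
deviation as documented approximations, not pass/fail gates.

## Known limitations

* Normalisation and weights are trial-set relative (see above).
* Segmentation thresholds are stand-ins pending labelled real data.
* MEE coefficients are generic; absolute kcal are not comparable
  across coefficient sets.
* The static stage treats the torso as fixed and ignores finger/hand
  micro-movements; a finer upper-limb decomposition would need a
  different scoring method than RULA's coarse brackets.
* No fatigue-level discretisation is provided — the fused value is
  continuous and relative, and binning it into named levels would
  require external calibration data.
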