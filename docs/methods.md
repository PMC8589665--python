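# Methods

`bistate` implements a quantitative pipeline for a two-state account of
attentional bias in PTSD: patients are modelled as alternating between an
emotional *undermodulatory* state (amygdala-dominant; attention toward
threat; re-experiencing symptoms) and an *overmodulatory* state
(vmPFC-dominant; attention away from threat; avoidance symptoms).  The
pipeline links three data levels — trial-level breaking-CFS (b-CFS)
detection times, per-patient symptom-cluster scores, and study-level
meta-analytic outcomes — through a small set of statistics described below.

## 1. Symptom normalization and imbalance

Instruments score clusters on different ranges, so every cluster score is
mapped affinely onto [0, 1] using the instrument's minimum/maximum possible
scores.  DSM-IV instruments report a single combined avoidance/numbing
cluster; DSM-5 instruments report the two separately, and the pipeline sums
raw avoidance + numbing scores and bounds before normalizing, which makes
the combined score identical in meaning across editions.

Two derived statistics:

- **imbalance** = `avoid_norm − re_norm` ∈ [−1, 1] — the sign says which
  modulatory pole dominates a patient (positive: avoidance/overmodulation);
- **symptom sum** = `re_norm + avoid_norm` ∈ [0, 2] — how strongly *both*
  poles are expressed, used as a proxy for how far apart the two states sit
  within one patient.

Scale bounds are never hard-coded: a CAPS (DSM-IV, 0–8 per item) preset is
provided, but every input table declares its own bounds, because published
study tables rarely state instrument ranges and silent assumptions would be
invisible.  The symptom sum is computed on normalized scores for consistency
with the imbalance definition.  Missing optional clusters are represented as
absent values, never as zero.

A sensitivity variant (`augmented_avoidance`) replaces the combined
avoidance score with avoidance + depersonalization/derealization before
normalization, probing whether results depend on treating dissociative
symptoms as overmodulatory.

## 2. b-CFS scoring

A session is 6 face identities × 2 expressions × 4 positions = 48 trials;
the outcome is the suppression-breaking reaction time (ms).  Filtering:
incorrect trials are dropped, and any trial with RT more than 5 sample SDs
*above* its subject-by-expression mean is dropped as an extreme outlier,
with the mean and SD computed leave-one-out over the condition's other
correct trials.  Leave-one-out is not a refinement but a necessity: within a
condition of n trials the largest achievable include-the-point z score is
(n−1)/√n — about 4.7 at the 24 trials per condition of a full session — so
a 5 SD rule whose statistics include the candidate could never exclude
anything.  The rule is deliberately one-sided and deliberately minimal —
within-patient RT variability is part of the signal under the two-state
model, so no further trimming is applied.  An excluded fraction ≥ 3%
triggers a warning rather than an error.

Kept trials are paired into *dyads* (one angry + one neutral trial sharing
face identity and position); cells missing a member are dropped whole.
Each dyad carries a signed bias.  Two sign conventions exist because the
source literature is not internally consistent about them:

- `toward_positive` (default): `bias = RT(neutral) − RT(angry)`, so a
  positive bias means the threat face broke suppression *faster* —
  attention toward threat;
- `literal`: the negation (angry − neutral).

Per-subject indices: TAB (mean of all biases), AB_TOWARD / AB_AWAY (means of
the strictly positive / strictly negative biases, AB_AWAY stored as an
absolute value), within-class SDs, ABV (SD of all biases), and pct_toward
(share of signed dyads that are positive).  Exact zero biases count in
TAB/ABV but in neither sign class.  All indices are translation-invariant in
RT, and flipping the sign convention swaps the toward/away quantities and
negates TAB.

### The orientation of the imbalance–TAB correlation

Within a two-state model, attention-toward-threat goes with re-experiencing;
therefore a toward-positive TAB must correlate *negatively* with
`avoidance − re-experiencing` imbalance.  An avoidance-dominated patient
detects threat slowly, which is a *positive* angry-minus-neutral difference.
The pipeline therefore computes the imbalance–TAB correlation on the
angry-minus-neutral ("literal") orientation by default
(`imbalance_tab_orientation = "literal"`), which is the orientation under
which the two cohort-level results — a positive imbalance–TAB correlation
and re-experiencing predicting AB_TOWARD — are simultaneously coherent.
Setting `"convention"` correlates imbalance against the toward-positive TAB
instead; the model then predicts a negative r of the same magnitude, and the
report records which orientation was used.

## 3. Reaction-time bimodality

Per patient, angry and neutral RTs are pooled after recentring each
expression condition to the pooled grand mean (`rt′ = rt − mean_cond +
grand_mean`), so an expression main effect cannot masquerade as bimodality.
The recentring formula is one reading of "normalizing the condition-mean
difference"; it preserves the pooled mean and equates condition means, which
is the property the downstream mixture analysis needs.

Gaussian mixtures with k = 1 and k = 2 are fitted to the normalized RTs on
the raw millisecond scale (no log transform).  k = 1 uses the closed-form
MLE.  k = 2 runs expectation–maximization with unconstrained component
variances, 20 restarts (tolerance 1e-6 on the log-likelihood, at most 500
iterations), one restart initialized by splitting the k = 1 solution at
±1 SD and the rest from random pairs of observations; a scale-aware variance
floor (1e-6 × sample variance) prevents single-point collapse.  If the best
k = 2 likelihood would fall below the k = 1 likelihood the degenerate
equal-components solution is reported instead, so the nesting inequality
logL₂ ≥ logL₁ holds by construction.  Model comparison uses
AIC = 2·k_params − 2·logL (2 vs 5 parameters, so the penalty difference is
exactly 6): the two-component model is called **bimodal** only when
AIC(k=1) − AIC(k=2) > 2; smaller differences are reported as unimodal, and a
non-converged two-component fit yields **indeterminate** (a case the rule
itself does not define but an implementation must).

The ΔAIC > 2 rule is lenient: on pure-Gaussian 48-trial samples it calls
bimodality in roughly a fifth of replicates (measured by the test suite,
bounded below 25%), while on two-component samples separated by ≥ 4σ it
detects bimodality in well over 90% of replicates.  Those operating
characteristics, not a hypothesis test's nominal level, are what the verdict
means.

Peak locations come from k-means (k = 2) on the normalized RTs with a
*single* random initialization per run — deliberately, so the documented
seed-to-seed variability exists — and the peak distance is the absolute
difference of the ascending centres.  The correlation between peak distance
and symptom sum is therefore iterated (default 100 times) with fresh
initialization seeds spawned deterministically from a master seed; the mean
and range of r and of the one-tailed p are reported.

## 4. Inferential statistics

- Correlations are Pearson with **one-tailed** p values against a stated
  direction (`p = P(T_{n−2} ≥ t_obs)` for the positive direction); this
  mirrors directional a-priori hypotheses and is used everywhere in the
  pipeline.  No multiple-testing correction is applied anywhere; the report
  flags the number of tests performed instead.
- Variables containing outliers (any point more than 2 sample SDs from the
  mean) trigger a Spearman robustness re-run (average ranks for ties).
- Stepwise regression is forward selection with backward pruning on
  standardized variables: at each step the candidate with the largest |t|
  enters if its p < `p_enter` (default 0.05); any included predictor whose
  p rises above `p_remove` (default 0.10) is then dropped.  These thresholds
  are the common automatic-selection defaults; the procedure is exploratory
  by construction, and its null family-wise selection rate at n = 20 with
  three candidates is measured by the test suite (liberal: above 5%, below
  25%).  For reporting, unselected candidates get the standardized β and p
  they would have if added singly to the final model — which is how one
  coefficient table can show both selected and unselected predictors.
- Group comparison is the pooled-variance two-sample t with Hedge's
  d = Cohen's d × (1 − 3/(4·df − 1)).
- Required per-group sample size uses the normal approximation
  `ceil(2·(z_{1−α/2} + z_power)² / d²)` with defaults α = 0.05 (two-tailed)
  and power 0.80; d = 0.60 gives 44 per group.

## 5. Meta-analysis harmonization

Study-level records hold population-mean cluster scores (with bounds) and
one outcome: a dot-probe TAB in ms or an amygdala BOLD response.  Reported t
statistics are converted to z by probability matching,
`z = Φ⁻¹(F_t(t; df))`, clamped to ±8 — the standard definition of that
conversion; no particular software routine is replicated.  Left- and
right-amygdala analyses never share records; populations missing a
hemisphere are simply absent from that analysis.  The meta statistic is the
unweighted one-tailed Pearson correlation between population imbalance and
the outcome over ≥ 3 retained populations: an unweighted correlation over
population means, not an inverse-variance pooled effect size, because that
is what the method defines.

## 6. The synthetic-data generator

The generator exists so every stage is testable with no external data; it
encodes the *minimal* stochastic process consistent with the two-state
account, with all parameters exposed:

- a hidden two-state Markov chain per patient over the 48 trials, with
  per-state stay probabilities (drawn per patient from configured ranges in
  cohort mode).  The state dwell-time scale is a free parameter: the theory
  allows alternation on time scales from trials to weeks, and the generator
  exposes stay probability rather than asserting a time scale;
- reaction times
  `rt = base + offset·1[over] − δ_u·1[angry]·1[under] + δ_o·1[angry]·1[over] + ε`,
  with Gaussian noise by default (an optional right-skewed lognormal noise
  flag exists for robustness checks) and a 100 ms physical floor;
- **state-dependent threat effects**: δ_u (angry speedup when under) and
  δ_o (angry slowdown when over) are scaled by independent per-patient
  severity draws.  This is the load-bearing design choice.  With a single
  shared threat effect and heterogeneity only in state occupancy u, the
  sign-class means work out to AB_TOWARD ≈ δ + (1−u)·offset and
  AB_AWAY ≈ δ + u·offset (mixed-state dyads carry the full state separation
  in both directions), so AB_TOWARD would *anti*-correlate with
  re-experiencing and the documented coupling pattern could never be
  recovered.  Per-state severities make the toward-class magnitude track
  δ_u and the away-class magnitude δ_o, which is also the model's own
  story: a deeper under state means both faster threat detection and more
  re-experiencing;
- symptom couplings: the re-experiencing mean grows with
  (realized under-occupancy) × δ_u, avoidance with (over-occupancy) × δ_o,
  hypervigilance is uncoupled by default (so that the stepwise analyses
  probe a clean re/avoidance pattern; the coupling is a config field), and
  depersonalization/derealization couples weakly to the over side.  Scores
  get Gaussian noise and are clipped to CAPS-like bounds (re 0–40, combined
  avoidance 0–56, hypervigilance 0–40, dissociative 0–16); defaults put
  totals near 80, the severity region of a treated PTSD cohort;
- correctness is Bernoulli(1 − error_rate) with a 2% default, keeping
  exclusions below the 3% warning band.

Default dynamics (stay probabilities ≈ 0.6–0.76, slight over-state
predominance) put the mean share of toward dyads near 46–48% with per-patient
values spanning roughly 30–65%, and the default effect sizes make 48-trial
sessions bimodal for nearly all patients — the operating regime the analysis
is designed for.  `strong_coupling_config()` widens the severity spread and
shrinks symptom noise for parameter-recovery tests; `zero_coupling_config()`
severs the symptom couplings (scores become pure noise) for null checks.
Ground truth (state sequences, occupancies, severities, true peak
separations, pre-noise cluster means) is returned alongside and written to a
separate JSON never read by analysis stages.

Meta tables are generated by drawing population imbalances uniformly,
building outcomes as `ρ·z(imbalance) + √(1−ρ²)·noise` so the planted
population correlation is exactly the target, and emitting a configurable
fraction of imaging outcomes as t statistics with drawn dfs chosen so that
probability matching recovers the underlying z exactly.

### What the generator does not emulate

Real b-CFS data have right-skewed RT distributions (the default here is
Gaussian per state, so mixture recovery has an exact oracle), trial-order
effects (fatigue, practice), state dynamics possibly slower than one
session, item effects of specific face identities, and measurement
structure in symptom instruments beyond cluster totals.  Passing tests
demonstrate that the *pipeline* recovers the structure it assumes when that
structure is present and stays quiet when it is absent — not that real
patients obey this generative process.

## 7. Pipeline, determinism, and problem sizes

Reports are plain JSON dictionaries fully determined by (inputs, config,
master seed): per-subject bias and bimodality blocks, error-rate comparison,
imbalance–TAB correlation with robustness re-run, four stepwise blocks
(AB_TOWARD, AB_AWAY and their within-class SDs), multicollinearity table,
the iterated distance–sum correlation, and the augmented-avoidance
sensitivity re-run.  No timestamps are embedded, so identical runs are
byte-identical.  Configuration is a YAML-loadable dataclass whose defaults
equal the method's stated constants (5 SD exclusion, ΔAIC threshold 2, 100
k-means iterations, one-tailed tests); CLI flags override file values.

The test suite and the acceptance script run everything at the sizes the
method itself uses — 48 trials per patient, 20-patient cohorts, 16
behavioral and 8 imaging populations — with replicate counts of 200 for the
mixture operating characteristics and 500 for meta calibration, which keeps
a full run in the minutes range on one core.

## Known limitations

- The two-component EM maximizes a locally multimodal likelihood; with 20
  restarts on 48 points, convergence to the global optimum is empirical,
  not guaranteed.
- The ΔAIC > 2 verdict has a ~20% false-positive rate at n = 48; per-patient
  verdicts should be read as a population-level pattern, not individual
  diagnoses.
- Forward stepwise selection is exploratory; its selection p values are not
  valid post-selection inference.
- The normal-approximation sample-size formula ignores the t correction
  (about one participant per group at these sizes).
- The sign-orientation ambiguity of dot-probe TABs across published studies
  cannot be resolved from study tables alone; the meta stage assumes a
  consistent orientation in its inputs.
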