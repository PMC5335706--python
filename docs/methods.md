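# Methods

## The estimation problem

Given patients treated with one of three neoadjuvant regimens (A, TA,
TxA), each with an observed binary response (pCR/RD), expression of ~2×10⁴
array probes and a handful of clinical covariates, PRES asks: which
regimen would maximize each patient's chance of pCR? The difficulty is
that each patient is observed under one regimen only, arms are unbalanced
(roughly 139/730/210), pCR is rare (8.6–30.5% per arm), and data come from
multiple cohorts with batch structure. PRES answers with three per-arm
response models, a binned calibration step that converts raw model
probabilities into empirically grounded "pCR scores", and an argmax
assignment rule with a small toxicity concession toward the least toxic
regimen.

## Per-arm response models

**Screening.** Within one arm, each probe gets a Welch two-sample t-test
(pCR vs RD; Welch–Satterthwaite degrees of freedom); probes with p ≤ 0.05
survive (boundary inclusive — the conventional reading of a 0.05
significance level). Probes with zero variance in either group are
untestable and logged. No multiplicity correction is applied at this
stage: the screen is a recall-oriented filter, not an inference.

**Random sampling screening (RSS).** The survivors are re-ranked for
stability: B draws (default 200), each taking a response-stratified 70%
patient subsample and a random probe subset of size min(|passers|, 200),
fit a random forest and rank the drawn probes by impurity importance.
A probe's selection frequency is the fraction of its draws in which it
ranked in the top q = 50. The denominator is the number of draws that
*included* the probe, since a probe cannot rank in a draw that excluded
it; with the default subset size the two denominators coincide. Final
order: descending frequency, then ascending mean rank, then ascending
screen p-value, then probe ID — a fully deterministic chain given the
seed.

**Probe-count selection.** For k over a grid (default {0, 2, 4, 8, 13,
16, 24, 32, 50, 100}), a forest on the clinical encoding plus the top-k
probes is scored by stratified 5-fold cross-validation: held-out
predictions thresholded at 0.5, F₀.₅ per fold, folds averaged. k* is the
argmax, ties broken toward the smallest k (parsimony). k = 0 is the
clinical-only reference model, so the gene model's added value is always
visible in the trace. F₀.₅ weights precision twice as heavily as recall;
under 10–30% prevalence, precision is the quantity the assignment step
consumes (a bin's score *is* a precision), so optimizing for it is the
coherent choice.

**Clinical encoding.** Age enters numerically (missing ages imputed with
the training median); each receptor status (ER/PR/HER2) expands to two
indicators, `is_positive` and `is_known`, so "unknown" is representable
without imputing a status. Cell lines, which have no clinical record,
are scored with all-unknown statuses and the training-median age.

**Out-of-fold probabilities.** Training patients are never scored by a
model that saw them: a 10-fold stratified protocol refits the *entire*
pipeline — screen, RSS, k-selection, forest — inside each fold. This full
nesting is the conservative reading of "predicted without that patient's
information"; reusing a globally screened probe list would leak label
information into every fold's feature set.

**Forest settings.** 1000 trees, scikit-learn defaults otherwise,
probability = fraction of trees voting pCR. All sizes (trees, RSS draws,
folds, grid) are exposed in `PipelineConfig`; a `desk_scale()` profile
shrinks them for interactive use.

## Probability-interval calibration

Out-of-fold probabilities are partitioned into five equal-width bins on
[0, 1]: [0, .2), [.2, .4), [.4, .6), [.6, .8), [.8, 1]. Fixed-width bins
(not quantiles) are used so that bin labels are comparable across
regimens and runs. A bin's pCR score is its observed pCR fraction — the
binomial MLE of the response rate among patients the model maps there. By
construction Σ_bins n_b·score_b equals the group's pCR count exactly; this
conservation identity is asserted in the tests on every fitted table.
Boundary values belong to the upper bin (1.0 stays in the last). Empty
bins carry an undefined score and are never imputed; a probability landing
in an empty bin falls back to the nearest defined bin, ties toward the
lower (more conservative) bin. Per-bin uncertainty on the calibration
curve is a Wilson score interval. The first bin's NPV (true RD over
negative calls) and the upper bins' PPVs (= their scores) are reported.

## Assignment rule

Each patient's three probabilities map to three scores. In `max_score`
mode the highest score wins. In `toxicity` mode (default), A is assigned
whenever its score is within 0.01 of the best taxane score — read as "A
wins if score_A ≥ max(score_TA, score_TxA) − 0.01", which coincides with
the per-regimen reading whenever A is not already the maximum. An exact
TA/TxA tie keeps the patient's original regimen if it is one of the tied
pair, otherwise TA — the tie-break that minimizes treatment switching.
Patients whose arm lacked a trainable model are assigned among the
regimens with defined scores; every patient receives a regimen.

Two exact guarantees follow algebraically and are asserted at test time:
the `max_score` expected pCR count (sum of assigned scores) dominates any
single-regimen assignment computed from the same tables, and the
`toxicity` count is within 0.01·N of that maximum (per-patient loss is
bounded by the margin). Overtreatment = received TA/TxA though A scored at
least as well; undertreatment = received A though a taxane scored strictly
better.

**Bootstrap CI.** Each defined bin's score is redrawn from a Gaussian
centred on the score with sd √(score·(1−score)/n_bin) truncated to [0, 1]
(the binomial standard error of the bin proportion — the natural choice
for an MLE of a proportion); assigned patients inherit their bin's redrawn
score and the replicate rate is recorded; the CI is the 2.5/97.5
percentile pair over 1000 replicates.

## Validation harnesses

**LOSO.** Each cohort is held out in turn; screening, models and PI
tables are rebuilt from the remaining cohorts only; held-out patients are
scored with the *full* training models (not OOF — they are external to
the training set) and mapped through training-derived tables. A training
split lacking a regimen arm (or lacking enough patients per class for the
OOF folds) skips that arm's model with a logged reason, and held-out
patients are assigned among the remaining regimens. Mutating held-out
responses cannot change any training artifact; the tests assert this by
flipping every held-out response and comparing assignments.

**Strata.** The HER2-negative stratum reruns the identical pipeline on
the filtered patients; the HER2−/ER− stratum additionally drops the A arm
(that comparison concerns the two taxane regimens). The stratified run is
literally the whole pipeline applied to the pre-filtered dataset — one
code path, asserted by a composition-identity test.

**Cell-line check.** The TA model predicts pCR probabilities for a panel
of taxane-sensitive and -resistant lines; a one-sided Welch test of
H₀: P_resist = P_sensitive against H₁: P_resist < P_sensitive is
reported. With zero variance in both groups the statistic degenerates to
t = 0, p = 0.5 (flagged).

## Synthetic data generator

The generator emulates the seven-cohort neoadjuvant design: the default
layout reproduces the published per-cohort arm sizes (arm totals
139/730/210, many cohorts missing arms) and targets arm prevalences
8.6/19.7/30.5%; `small_design()` builds balanced desk-scale layouts.

Per patient i and regimen r, a latent chemosensitivity z_ir ~ N(0, 1)
(independent across regimens) drives both outcome and expression:

    logit p_ir = α_r + λ·z_ir + γ·c_i                     (λ default 2.0)
    x_ij = μ_j + b_c(i),j + s_rj·effect·z_ir + ε_ij       (ε ~ N(0, 1))

for probe j in regimen r's signature (signs s_rj random; default
signature sizes 4/13/30; effect default 0.8 — the log2 shift per standard
deviation of sensitivity, yielding a pCR-vs-RD group shift of roughly
1.3–1.7× that), plus cohort-by-probe batch shifts b ~ N(0, 0.3²) and
probe baselines μ_j ~ N(0, 0.5²). Clinical covariates (age; ER/PR/HER2
with a 5% unknown fraction) enter with modest effects (ER+ −0.5, HER2+
+0.3 on the logit; −0.01 per year from age 50) — directions consistent
with the clinical literature on chemosensitivity of receptor-negative
tumors. The intercept α_r is solved numerically per arm so the mean true
probability over the arm's patients equals the configured prevalence
target (with no effects this reduces to α = logit(prevalence)). The
observed regimen is randomized independently of expression, isolating
method behaviour from confounding; the observed response is Bernoulli at
the received regimen's true probability. The latent-factor formulation
was chosen over a direct logistic-in-expression model because only the
factor model can realize the documented effect-size semantics (a fixed
per-probe expression shift) for large signatures: with 30 probes entering
a logistic sum the achievable marginal shift per probe is capped well
below 0.8 by saturation.

What the generator does **not** model: probe-level array artifacts (GC
content, saturation), correlated probe blocks beyond the planted
signatures, non-random treatment assignment, overlap between regimen
signatures (configurable but off by default), and survival endpoints.
Passing tests on this generator therefore demonstrate that the pipeline
recovers planted structure under its own assumptions — not that the
published patient-level rates are reproduced, which would require the
original cohorts.

`GroundTruth` carries each patient's true probability under all three
regimens, so any assignment policy has an exact oracle value (mean true
probability under the assigned regimen); PRES is compared against the
best single-regimen policy on that oracle.

## Design-table arithmetic

The published design table prints, per cohort-arm cell, the patient count
and the pCR percentage. Rounding count × percentage recovers the integer
pCR counts (12/144/64 per arm, 220 total), and re-aggregating reproduces
every printed marginal rate exactly (8.6/19.7/30.5/20.4% per arm and
total; 20.1…37.7% per cohort). This arithmetic anchors the generator's
default prevalence targets and is checked in the acceptance suite.

## Problem sizes and numerical choices

Repeated-seed recovery checks run at 600 patients per arm, 1000–2000
probes, effect 0.8, with a scaled pipeline profile (20 RSS draws, 50-tree
forests, 3-fold selection and OOF); the package's dominance and
conservation guarantees are exact at any size, and the power-style checks
(screening recall, policy gain over the best single regimen) are
comfortably cleared at this scale. Seeds: every stage consumes a child
seed derived from the run seed and a stage label via a CRC-keyed
`SeedSequence`, so stages are independently reproducible. Ties are broken
deterministically everywhere (smallest k; lower bin; A-before-TA-before-
TxA after the original-regimen preference). Degenerate inputs — zero-
variance probes, empty bins, single-class arms, missing arms — are
rejected or flagged explicitly rather than silently imputed.

## Known limitations

- The RSS reconstruction matches the published intent (narrowing the
  candidate list by repeated-subsample importance ranking) but its exact
  published settings are not available; all knobs are exposed.
- Calibration bins with few patients give noisy scores; the truncated-
  Gaussian CI accounts for bin-size uncertainty but not for model refit
  variability.
- The toxicity margin (0.01) encodes a lexicographic preference, not a
  utility model of toxicity.
- Arms too small to support stratified folds (e.g. a 4-patient cohort
  arm) contribute no model; their patients are assigned among the
  remaining regimens.
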