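# Methods

## The problem

In oncology trials, patients are often dichotomized into responders
(best overall response CR or PR) and non-responders (SD or PD), and a
classifier predicting that status is thresholded at probability 0.5 to
make the call. A fixed 0.5 cutoff is rarely optimal, particularly when
responders are a minority. `respseg` implements a data-driven
alternative: search a family of cross-validation (CV) techniques for the
probability cutoff that maximizes the F1 score of the out-of-fold
predictions, pool models from two training trials into a single scoring
system, and segment a third (test) trial against the pooled cutoff. The
segmentation is then judged the way a trialist would judge it: by
classification metrics against the observed response, and by whether the
predicted groups separate in overall survival.

## Features

Each patient contributes five encoded baseline covariates — sex
(female=0/male=1), age bin (18–<65 / 65–75 / >75 as ordinal 0/1/2),
weight class (≤75 / >75 kg as 0/1), smoking status (never/former/current
as ordinal 0/1/2), race (caucasian=0/non-caucasian=1) — and the percent
change in the sum of longest tumor diameters at the first four
post-baseline visits, `100·(size_i − baseline)/baseline`. The four-visit
percent-change trajectory is reduced by PCA (default 2 components,
configurable 1–4); scores enter the design matrix after the covariates.
Age and weight are modeled as single ordinal/binary covariates so each
contributes one coefficient; continuous values in input files are binned
on read. Patients missing any of the four visits are excluded from
modeling with a logged count — the method is explicitly an
early-trajectory (landmark visit 4) method and imputation is out of
scope.

PCA numerical choices: loadings are eigenvectors of the sample
covariance (ddof=1), components ordered by decreasing variance, and each
component's largest-magnitude loading element is forced positive (first
index on ties) so results are identical across linear-algebra backends.
A rank check raises rather than silently returning degenerate
components. Each training trial's own PCA basis feeds its own model fit;
the test trial is projected with a PCA fit on the pooled training
trajectories. Pooling is the default because nothing in the two-trial
construction singles out one training basis for the test data, and the
pooled basis is the deterministic choice that uses no test information;
a per-trial option exists for sensitivity analysis.

## Cutoff search

Seven CV families are searched, 47 configurations at the defaults:
LOOCV; leave-pair-out with p=2; a single 75/25 hold-out; K-fold with
K=3..10; repeated K-fold with K=3..10 × 2..4 repeats; stratified K-fold
with K=3..5; repeated stratified K-fold with K=3..5 × 2..4 repeats. For
each configuration an unpenalized logistic regression (convergence
tolerance 1e-8) is refit per training fold and probabilities are
collected out-of-fold; patients seen in several validation folds
(repeated CV, leave-pair-out) are aggregated by arithmetic mean. The
technique's best cutoff maximizes F1 of "responder iff probability >
cutoff" (strict inequality; F1 defined 0 when nothing is predicted
positive) over the candidate set {0} ∪ {observed probabilities}, which
realizes every achievable confusion matrix — a unit-tested equivalence
against exhaustive 10,001-point grid search. Ties break toward the
smallest maximizing cutoff, favoring sensitivity.

Across techniques the configuration with the **maximum best cutoff** is
selected by default. Maximum F1 is the statistically natural criterion
and is implemented (`rule="max_f1"`), but maximum-cutoff is the default
because it is the stated selection rule of the approach this package
operationalizes; both are reported side by side in logs. Tie-breaks:
larger F1, then enumeration order.

Degenerate cases: single-class training folds are skipped with a logged
warning (an error only if every fold is skipped); (quasi-)separated fits
fall back to a vanishingly small ridge penalty (1e-6 on the slopes) so
coefficients stay finite; stratified configurations whose smallest class
has fewer members than K are reported as per-technique failures without
aborting the grid. Leave-pair-out enumerates all C(n,2) pairs up to
2,000 and switches to 2,000 seeded random distinct pairs beyond that —
full enumeration at trial scale (≈180k pairs at n=600) would dominate
runtime for no statistical benefit. All randomness flows from one master
seed; per-technique seeds are derived with `SeedSequence([seed, index])`.

## Scoring and segmentation

The final per-trial coefficients come from refitting the logistic model
on the **full** training trial: the CV search only selects the technique
and its cutoff. (Eq.-style per-feature coefficients are defined per
training dataset, not per fold; fold-averaged coefficients are available
behind a flag in the cutoff-search results.) The pooled scoring model
averages the two trials' coefficient vectors element-wise, and the
pooled cutoff is Bcut = (bcut₁ + bcut₂)/2 — the division by two *is* the
averaging; the threshold is applied once. A test patient's score is the
pooled linear predictor, their probability its inverse logit, and they
are a predicted responder iff probability > Bcut (strict; boundary cases
are non-responders). The standard comparator shares the feature pipeline
and the pooled full-data fits but fixes the threshold at 0.5 and never
invokes the CV engine (tested by instrumentation). Probabilities, not
raw scores, are compared with the cutoff, since cutoffs live in (0,1).

## Evaluation

* **Classification**: accuracy, MSE (for 0/1 predictions the
  misclassification rate, so accuracy + MSE = 1 exactly), specificity,
  precision, recall; zero-denominator ratios are reported as 0 with an
  explicit flag rather than NaN.
* **Kaplan–Meier / log-rank**: product-limit curves per predicted group,
  medians with 95% CIs via the log–log transform, two-group log-rank
  chi-square (1 df).
* **Cox PH**: partial likelihood with Efron tie handling (the library
  standard), hazard ratios with 95% Wald CIs, partial-likelihood AIC.
  Covariates: sex, age, weight, smoking, race, the retained PCs, and the
  predicted group.
* **AFT**: parametric maximum likelihood with right censoring, Weibull
  by default (lognormal selectable); effects are reported as *time
  ratios* exp(coef) — AFT effects are sometimes mislabeled hazard ratios
  in clinical tables, and this package does not repeat that.
* **AIC comparison**: same-kind fits under the two segmentations are
  compared; lower AIC wins, equality is a declared tie.

Survival estimation is delegated to `lifelines`; the test suite checks
it against hand-computed product-limit values, permutation-null
uniformity of the log-rank p-value, and parameter-recovery simulations
(Cox at true HR 0.668, Weibull AFT at true acceleration 1.25, n=3000).

## Synthetic trials

The generator emulates the schema and coarse statistics of the
registry trials this method targets, not their actual data:

* prevalences (defaults): male 0.78, caucasian 0.95, weight >75 kg 0.60,
  smoking never/former/current 0.07/0.48/0.45, age bins 0.55/0.36/0.09;
* baseline size lognormal (median 60 mm, log-sd 0.4); a latent shrinkage
  rate r ~ N(−3, 8) %/visit gives percent change r·j + N(0, 4) at visit
  j, clipped to [−95, 150] so sizes stay positive;
* BOR from a logistic model on the encoded covariates plus the mean
  percent change (slope −0.12/%, so shrinking tumors respond); the
  intercept is calibrated numerically (Brent root-finding on the sampled
  linear predictor) to hit the target responder prevalence, default 0.35
  and configurable — class imbalance is a first-class knob precisely
  because it is what moves the F1-optimal cutoff away from 0.5;
* overall survival from a Weibull proportional-hazards model (shape 1.2,
  scale 400 days) with responder log-HR log(0.668) and mild covariate
  effects; independent Uniform(0, τ) administrative censoring with τ
  calibrated by quantile to the target censoring fraction (default
  0.25);
* a triplet helper draws two training trials and one test trial
  (600/140/600 patients by default, a reduced-scale echo of the real
  trials' 962/146/670) from one generating process with per-trial seeds
  derived from the master seed.

What the generator does **not** emulate: RECIST lesion-level structure,
visit-schedule irregularity and dropout, site effects, covariate
correlations, non-proportional hazards, informative censoring. Passing
tests therefore demonstrate correctness and the method's qualitative
behavior (cutoffs move off 0.5 under imbalance; no inflated type-I error
under a null process), not performance claims about the restricted
trials.

## Problem sizes used in the automated checks

The cutoff-search oracle check uses 200 random instances of n ≤ 200; the
survival parameter recoveries use n = 3000; the behavioral simulation
studies use 50 runs (imbalanced, prevalence 0.2) and 100 runs (global
null) at the default 600/140/600 trial sizes with a reduced technique
grid (hold-out, K-fold K∈{5,10}, stratified K∈{3,5}) — one
representative of each affordable family, since the study's subject is
the pooled cutoff's behavior, not the grid itself. The acceptance script
runs the full 47-technique grid once at the default sizes.

## Known limitations

* The maximum-cutoff selection rule is faithful to the approach's
  statement but can prefer a conservative technique whose F1 is not
  best; use `rule="max_f1"` where the statistical criterion matters.
* Cutoffs estimated from small trials (n ≲ 150) are noisy; the pooled
  Bcut inherits that noise.
* No recalibration between trials (no Platt/isotonic scaling, no
  per-trial intercept), and no missing-visit imputation.
* With an extreme Bcut, a segmentation can be degenerate (one group);
  survival contrasts are then reported as unavailable rather than
  fabricated.
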