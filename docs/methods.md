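# Methods

## Model and procedure

`permwell` estimates, for each predictor of a continuous questionnaire
outcome, the share of predictive information a learner loses when that
predictor's link to the outcome is broken. The primitive is held-out
permutation importance: with a model fitted on training rows, shuffle one
column of the *test* fold (target and all other columns left in place) and
record the increase in test MSE over the unshuffled baseline. Shuffling
preserves the column's marginal distribution, so the difference isolates
the model's reliance on that predictor rather than on its distribution.
The signed difference may be negative (shuffling can accidentally improve
a noisy fit); signs are kept at this stage.

One run of the aggregation takes a (train, test) pair from a repeated
k-fold plan, computes the signed importance vector (each feature shuffled
`n_perm_repeats = 10` times, the differences averaged), then applies
absolute value and unit-sum normalisation *within the run*. Normalising
before averaging is deliberate and not equivalent to averaging raw
importances and normalising once: each run contributes an equal-weight
probability vector regardless of its fold's absolute MSE scale, so folds
with large error variance cannot dominate. The per-learner column is the
arithmetic mean of the 100 normalised vectors (10 repetitions x 10 folds),
and the Average column is the row-wise mean across learner columns; both
inherit the unit sum exactly (up to double-precision accumulation, checked
post hoc to 1e-9 and never re-normalised).

Assumptions worth stating: rows are exchangeable (no clustering or repeated
measures), outcomes are continuous totals, and importance is defined
relative to whatever each learner family actually fits — two learners may
legitimately disagree, which is why the consensus Average and the per-learner
columns are both reported.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k_folds` | 10 | held-out folds per repetition; near-equal sizes, first `n mod k` folds one row larger |
| `n_reps` | 10 | independent reshuffles of the full data; 100 iterations total |
| `n_perm_repeats` | 10 | shuffles per feature per iteration; variance reduction of the MC estimate |
| `learners` | all six | OLS, KNN (k=5, Euclidean), SVR (RBF), CART, random forest (100 trees), gradient boosting — backing-toolkit defaults, recorded and overridable via `LearnerSpec` |
| `standardize` | off | per-training-fold feature standardisation (leakage-free); off to match toolkit defaults |
| `alpha` | 0.05 | baseline screening level, Welch two-sided, no multiplicity correction (switchable to pooled-variance) |
| `random_state` / `seed` | 0 | master seed; see seeding scheme |

Folds are not stratified: outcomes are continuous, and plain shuffled
near-equal folds match the "evenly chopped after a random shuffle" design.

## Seeding scheme

All randomness derives from one master integer via
`SeedSequence(master, spawn_key=(purpose, *indices))`:
predictor draws, outcome noise, item compositions, CV shuffles
(per repetition), permutation shuffles (per iteration k and feature i,
repeats drawn sequentially from the feature's stream) and stochastic
learner fits (keyed by algorithm identity and iteration, so reordering the
learner list cannot change any column). Identical seed implies bit-identical
tables; permutation streams are shared across learners so their columns are
paired on the same shuffles.

## Degenerate inputs and numerical choices

- An all-zero importance vector (e.g. a constant-prediction fit on a
  degenerate fold) normalises to the uniform vector 1/p with a logged
  warning and a counter in the fitted estimator and run manifest; aborting
  a 100-iteration run for one degenerate fold would be worse. A genuine
  fitting error, by contrast, aborts with (repetition, fold, learner)
  context — no silent skipping.
- A single-row test fold makes every shuffle the identity, so the
  importance vector is exactly zero (and then uniform after the fallback).
- Outcome values are clipped (not rounded) to the instrument scale; the
  clipped count is logged and kept in `Series.attrs`.
- Top-k ties break by questionnaire order, making rankings stable.
- Accumulation is in double precision throughout.

## Instrument scorers

PHQ-9 and GAD-7 totals are item sums (items 0-3), EQ-5D-5L is the raw
level sum (5 best - 25 worst; no utility tariff), EQ-VAS passes through,
and BRS is the item mean after reverse-coding items 2, 4, 6 (the standard
form's negatively worded items; reversal is configurable down to none
because published analyses do not always state it). Severity bands: PHQ-9
0-4/5-9/10-14/15-19/20-27; BRS <3.00 low, 3.00-4.30 normal, >4.30 high
(the 1/6-step mean grid never lands between adjacent edges). GAD-7 admits
two published conventions that disagree at a total of 5; the tabulated
ranges 0-5/6-10/11-15/16-21 are the default and the 5/10/15 cut-off variant
is a switch.

## Synthetic generator

The generator emulates the documented *marginal* structure of a
1173-respondent university wellbeing survey: 17 independent Bernoulli
predictors at the published dichotomised prevalences (e.g. adversity 0.866,
exercise 0.303, social distancing 0.934), and continuous outcomes
`y = intercept + X·effects + N(0, noise_sd)` clipped to the instrument
scale, with an optional single pairwise interaction term and an optional
ordinal (1-5) coding for the five-point frequency items. Default
per-outcome effect profiles place weight on the factors the field's
analyses rank highest and are calibrated so latent means and SDs
approximate published descriptives (PHQ-9 10.9 +- 6.2, and so on).

What it deliberately does not model: the real joint dependence among
predictors (no copulas or latent-trait simulation), item-level response
processes, and respondent heterogeneity. Passing tests therefore
demonstrate that the pipeline recovers *planted, additive* signal under
independent predictors — they do not certify behaviour under strong
predictor correlation, where permutation importance is known to split
credit across correlated proxies.

## Validation and problem sizes

The test suite checks the generator's calibration (n = 1e5, tolerance
0.01), OLS recovery of noiseless planted effects to 1e-8, exact band edges
for every integer total of every instrument, unit-sum conservation at
1e-9 at every level, bitwise reproducibility of output files, agreement of
the Monte-Carlo importance with the exhaustive expectation over all
permutations of small folds (and with an independent reference
implementation), recovery of planted effects 4/3/2 (noise SD 3, n = 1200)
in >= 95% of 20 replicates, and top-5 concordance with the two-step
baseline. End-to-end checks run at reduced geometry (2x5-fold CV, the three
fastest learner families) chosen as the package's smoke configuration; the
full 10x10 six-learner geometry is exercised on smaller n.

Known limitation, verified empirically: under a *null* outcome the
per-dataset chance associations (OLS coefficients of order sigma/sqrt(n))
persist across all CV iterations of that one dataset, so a single dataset's
Average column deviates from the uniform 1/17 by up to ~0.08 — uniformity
holds in expectation *over datasets* (tested at tolerance 0.04 over ten
null datasets), not per dataset, and unit-sum normalisation makes the
per-dataset deviation invariant to n and noise scale. Rankings on null data
are therefore noise and should be read jointly with effect screens, never
as evidence on their own.
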