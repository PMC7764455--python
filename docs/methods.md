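# Methods

This note documents the models, conventions and defaults behind `ffqopt`,
and what its synthetic experiments do and do not demonstrate.

## Scoring model

A non-quantitative FFQ records, per food item, an ordinal consumption
frequency on an 8-level scale anchored at "rarely or never" (code 0) and
ending at "5+ a day" (code 7). A nutrient target's daily amount is the sum
over its contributing items of a per-item, per-frequency gram contribution:
contributions are 0 at code 0 and non-decreasing in frequency, so amounts
are non-negative and monotone in every answer. Amounts map onto discrete
diet-quality scores through two cutoffs; **both boundary amounts belong to
the middle class** (the published phrasing "80 g to 240 g" is inclusive, so
80 g and 240 g both score 2). Whether a higher amount is better is a
per-target field (`direction`), never hard-coded: for vegetables, fruit,
fiber or protein higher is better, while for fat, sugar or salt the outer
classes swap.

The bundled ESFFFQ fixture carries the published vegetable amount table and
cutoffs. The published subset table names only 19 of the 27 item tags; the
remaining 8 were reconstructed from the instrument's stated food groups and
are listed under `reconstructed_items` in the fixture so the provenance of
every tag is explicit.

## Standardization

Answers are centered and scaled to unit variance before feeding learners or
correlations. The **population variance convention** (divide by *n*) is
used, matching the common unit-variance scaler, and is documented so tests
can assert exact z-scores. Zero-variance columns (questions whose answers
never vary) are emitted as all zeros with a warning rather than NaN, so
downstream models never see non-finite values. Fitted statistics are
returned and can be re-applied, giving the transform-only contract needed
to standardize test folds with training-fold statistics.

## Imputation baselines

*Zero imputation* sets unanswered questions to "rarely or never". Because
contributions are non-negative, this can only underestimate the true
amount — strictly, whenever a dropped contributing item was answered above
code 0.

*MICE* fills unanswered questions by chained equations. In this package the
missingness is by design (whole columns unanswered), so the conditional
model for a dropped column cannot be learned from the incomplete matrix
itself; `mice_impute` therefore accepts a complete training matrix (the
training fold in the benchmark) from which per-column linear models are
fitted. Point predictions are cycled in questionnaire order until the
largest change falls below `tol` (default 1e-3) or `max_iter` (default 10)
rounds elapse. Defaults: **m = 5** imputations, each adding Gaussian noise
at the training residual scale before rounding and clipping predictions to
the valid code range (answers are categorical codes; the amount lookup
requires valid codes). Pooling averages the per-imputation amounts and
re-maps the pooled amount to a score — for a deterministic downstream
function of the data, Rubin-style pooling of point predictions reduces to
this average. All of m, the iteration budget and the pooling rule are
package choices; the seed is recorded in outputs and fixed seeds give
bit-identical imputations.

## Subset construction

Pearson correlations are computed between standardized answers (Pearson is
affine-invariant, so this equals the raw-code correlation); zero-variance
columns are assigned r = 0 against everything, as Pearson is undefined for
them. Thresholding uses **|r|** by default — a strong negative correlation
is an equally redundant question — with a signed-only mode available.

Each subset F_i is built **from F_{i−1}**, which makes the nesting relation
F₀ ⊇ F₁ ⊇ … ⊇ Fₙ structural rather than incidental. Within a pass, pairs
above the threshold are processed in decreasing |r| (ties broken by
questionnaire order), skipping pairs that already lost a member. Which
member of a pair is dropped is a pluggable rule; the default drops the
later item in questionnaire order, for determinism and auditability, with a
higher-mean-|r| alternative selectable. Every removal is recorded as a
(kept, removed, r) audit triple. Thresholds are config inputs: the original
ladder 0.40/0.30/0.25/0.20/0.10 was chosen so subset sizes fall roughly
linearly, and no automatic threshold chooser is provided.

## Benchmark protocol

One shuffled, balanced k-fold plan (default k = 5) is shared by every
model, subset and target. Learners are fitted per fold on the standardized
kept columns of the training rows — the scaler is fitted on the training
fold only, the leakage-safe default; a single global standardization is the
documented alternative — against ground truth computed from the full
questionnaire: quality scores for classification, gram amounts for
regression. Rosters are sklearn at default settings with no tuning, for a
fair comparison: logistic/linear regression, k-nearest neighbors, decision
tree, SVM, bagging, gradient boosting, random forest, and a voting ensemble
of the other seven. Seeded learners receive the run seed.

The two baselines enter the metric table like any other method: their
"prediction" is the deterministic amount/score computed after imputing the
test fold's dropped columns (MICE models fitted on the training fold). On
the full questionnaire there is nothing to impute, so both baselines
reproduce the ground truth exactly — classification metrics 1.0 and
regression errors 0 — which is why they always tie at the top there.

Classification measures are precision, recall and F1, support-weighted
across the three score classes by default (macro selectable) because score
classes are imbalanced in realistic cohorts; regression measures are MAE,
MSE, RMSE and R². Fold values are recorded individually; the fold mean is
the q_j that enters ranking. Degenerate cells (single-class training folds)
yield a constant prediction with a warning rather than aborting the run.

## PROMETHEE ranking

Only the V-shaped preference function is implemented (one of the six
classical families; the interface accepts alternatives). Defaults: equal
weights ω_j = 1, making π the plain mean of per-measure preferences; and
per-measure indifference threshold **Q_j = the largest observed pairwise
difference** in the decision matrix at hand, so the linear branch spans the
observed range (1.0 when a measure is constant, keeping the preference 0).
Both are injectable — the Q and ω behind the published rank tables are not
stated, which is one reason those exact rank values are not reproducible
even in principle. Net-flow ties receive fractional (average) ranks, the only
convention that produces tied 1.5-style values; ties are never broken by
alternative order. Rank tables carry an `avg` column: the fractional
ranking of each alternative's mean rank across contexts. Cross-target
aggregation takes the cell-wise mean of ranks and fractionally re-ranks
each column.

## Synthetic cohorts

Ordinal answers are generated through a Gaussian copula: latent
multivariate-normal rows with a specified correlation matrix (uniform
background plus planted pairs; non-PSD specs are repaired by eigenvalue
clipping with a warning), thresholded per item at cut-points realizing the
marginal level probabilities. Defaults: cohort size **289** (the study's 92
project + 197 survey respondents); mildly right-skewed marginals
(0.25, 0.20, 0.15, 0.12, 0.10, 0.08, 0.06, 0.04 across the 8 levels) — the
real marginals are unpublished, so this choice is explicitly arbitrary; a
`noise` dial (default 0) shrinking all latent correlations toward
independence. Generated amount tables reuse the published vegetable gram
ladder rescaled by a seed-deterministic per-item weight in [0.3, 1.0], with
cutoffs at the 1/3 and 2/3 quantiles of the induced amount distribution so
all three score classes are populated; a target named `vegetable` over
(salad, vegetables) returns the published tables verbatim. Ground truth is
recomputed through the scoring module, so it is bit-consistent with the
pipeline by construction.

What the generator does **not** emulate: real dietary patterns (food-group
co-consumption beyond pairwise correlation), demographic covariates, and
respondent-driven non-response. Passing tests therefore demonstrate that
the machinery is correct and that the qualitative claims (zero imputation
underestimates; learners overtake baselines on reduced subsets when kept
questions carry information about dropped ones) hold under controlled
conditions — not that any particular subset of the real ESFFFQ is optimal.

## Problem sizes and numerical choices

Test experiments run scaled down: planted-pair recovery uses 20 replicates
of 2000-respondent cohorts; the learner-vs-baseline property uses 20
replicates of 250-respondent, 12-item cohorts with a 3-learner roster; the
benchmark smoke tests use 120 respondents and 10 items. The experiment
orchestrator fans one master seed out into independent streams (fold plan,
learners, MICE, generator) via `numpy.random.SeedSequence`, so reruns are
byte-identical. Floating-point conventions worth knowing: RMSE is computed
as √MSE from the same MSE record; flow conservation Σφ = 0 holds to 1e-9;
correlation matrices are clipped to [−1, 1] after computation.

## Known limitations

- Per-target amount tables other than the vegetable one are not published;
  real-data use requires supplying them in the questionnaire file.
- The MICE baseline uses linear conditional models on ordinal codes;
  proper ordinal (e.g. proportional-odds) conditionals are not implemented.
- Ranking reproduces the published *scheme*, not the published *ranks*:
  those depend on the unavailable respondent answers and unstated Q/ω.
- `recommend_questions` assumes the answered set is a prefix of the nested
  chain; budgets falling strictly between two subsets use the largest fully
  covered subset's best model.
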