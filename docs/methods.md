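# Methods

## Scoring model

The Berlin Questionnaire assigns each respondent three category scores
and a high/low OSA-risk label:

* **Category 1 (snoring, B1–B5)** — positive when ≥2 items give a
  positive symptom response.
* **Category 2 (daytime somnolence, B6–B8)** — positive when ≥2 of the
  three items are positive. B9 is a frequency follow-up to B8 and does
  not enter the category score.
* **Category 3 (hypertension/obesity)** — positive when B10 = Yes or
  BMI > 30 kg/m².
* **High risk** ⇔ at least two categories positive.

The positive-answer rule table follows the original instrument: Yes for
the yes/no items (B1, B4, B8, B10); "3–4 times a week" or "Every day"
for the frequency items B3, B6, B7; "Louder than talking" or louder for
B2; and "1–2 times a week" or more often for witnessed breathing pauses
(B5). "Do not know" and missing answers never count as positive, and a
category is evaluated from whatever items were answered (partially
missing respondents are scored, not dropped — the instrument itself
imposes no completeness requirement, and dropping would discard the
structurally missing follow-ups). Every positive set is upward-closed in
level order, which makes the label monotone: escalating any single
answer, or raising BMI, can never turn a high-risk respondent low-risk.
This invariant is property-tested.

Ordinal encoding assigns each level its position in presentation order.
Two conventions for "Do not know" are implemented: `as_missing` (the
default; drops it and re-indexes, so yes/no items code No=0, Yes=1) and
`as_middle` (keeps the literal middle position). The default is the
convention under which the closed-form grouped scores reproduce the
reference values for the hypertension item (AUROC 0.74, F 0.80); the
alternative is retained for sensitivity analysis. The reference pair for
B1 (0.88 / 1.9) is *not* reproduced by either convention applied to the
grouped counts (closed form gives ≈0.85/2.10 and ≈0.87/2.05); it likely
derives from individual-level or classifier-based computation, so no
check asserts it.

## Discrimination scores

For one variable with class samples x₁ (low) and x₂ (high):

* Fisher score `F = (x̄₁ − x̄₂)² / (σ₁² + σ₂²)` with population
  (divide-by-n) variances. Degenerate cases: both variances zero with
  different means → ∞; with equal means → 0.
* Rank AUROC = (#{high > low pairs} + ½·#ties) / (n₁·n₂), identical to
  the tie-corrected Mann–Whitney U scaled by n₁·n₂. Orientation is fixed
  by the coding direction (more symptomatic → higher code → scores
  toward the high class); it is never flipped to max(a, 1−a), so values
  below 0.5 indicate reversed coding rather than being cosmetically
  hidden.

Both are computed either from individual values or in closed form from
level × class counts; the two routes are tested for exact agreement on
random tables, and the AUROC is cross-checked against an independent
Mann–Whitney implementation.

## Group statistics

Contingency tables track missing respondents separately from level
counts. Percentages use the full class total (answered + missing) as the
base and are displayed rounded half-up, with raw values retained. Test
routing is deterministic: Pearson chi-square without continuity
correction for L×2 tables; Fisher's exact test for 2×2 tables with any
expected cell below 5; rank tests (Mann–Whitney, Kruskal–Wallis beyond
two groups) available for ordinal scales. No multiple-testing correction
is applied.

## Selection protocol

One protocol run on a cohort of n features:

1. Stratified split into P1 (feature selection, ⌊0.70·N⌋ rows) and P2
   (quality assessment, the rest).
2. At each step, `inner_reps` (R, default 100) repetitions each shuffle
   P1, and for every candidate feature evaluate the internal criterion —
   stratified 3-fold cross-validated AUROC on P1 (configurable;
   `inner_cv=1` gives a single stratified 70/30 holdout) — with that
   feature left out. The feature whose removal loses least is
   *downvoted*; within a repetition ties keep the earliest item. The
   step removes the feature with the highest tally, ties again breaking
   toward earlier item order (determinism).
3. Each surviving subset is scored on P2 as mean ± SD of the AUROC over
   `eval_reps` (default 50) reseeded refits on P1.
4. Iterate to a single feature, yielding the AUROC-vs-cardinality curve
   (one point per cardinality n..1) and a removal order.
5. `outer_runs` (default 60) repetitions over fresh splits are
   aggregated into per-feature selection frequencies of the size-k best
   subsets (k default 3) and their normalised pair co-occurrence matrix
   (unordered pair counts divided by total pair count, so the upper
   triangle sums to 1).
6. Candidate reduced questionnaires are evaluated by `eval_reps`
   repetitions of stratified `cv_folds`-fold (default 5) cross-validation
   on the full cohort, out-of-fold scores pooled per repetition.

The classifier contract is `fit` / `score` / `with_seed`; the default
backend is XGBoost (100 rounds, depth 3, learning rate 0.1, histogram
trees, single-threaded), chosen because sparsity-aware split finding
consumes missing answers natively — no imputation anywhere in the
pipeline. Two deliberate choices around stochasticity:

* The default scorer uses stochastic gradient boosting
  (`subsample=0.8`). A fully deterministic learner makes "mean ± SD over
  reseeded refits" collapse to SD = 0, leaving the protocol's
  uncertainty estimate vacuous; row subsampling is the minimal,
  standard source of refit variability.
* The downvote criterion uses the deterministic variant
  (`subsample=1.0`) of the same scorer. Votes should compare feature
  information, with variability coming from the protocol's prescribed
  resampling (shuffles, inner splits) rather than from fit noise;
  paired leave-one-out comparisons on a common inner split are sharper
  that way.

All randomness derives from a single seed through
`numpy.random.SeedSequence`; the full protocol is reproducible
bit-for-bit given (dataset, seed).

## Synthetic cohort generator

No individual-level data exists for the reference survey, so analyses
run on synthetic cohorts drawn from its published grouped tables
(387 nurses: 311 low / 76 high risk). Per subject: a latent class
Bernoulli(0.20); each item drawn independently from that item's
class-conditional distribution with the unanswered mass as an explicit
outcome; a BMI group from the class-conditional BMI-group table and
continuous BMI uniform within the group's range (18–18.5, 18.5–25,
25–30, 30–46 kg/m², the survey's printed span); follow-up skip logic
(B1 = No ⇒ B2 missing, B8 = No ⇒ B9 missing). The usable label is always
recomputed by the scorer — the latent class is a sampling device kept
only for diagnostics — so synthetic data preserves the deterministic
label–feature relationship of the real study. Under the defaults the
recomputed high-risk fraction tracks the 20% latent prevalence closely
and is stable across seeds (property-tested over 20 seeds).

Calibration is verified by per-item, per-class chi-square goodness of
fit at n = 20,000; gated follow-up items are checked conditional on the
gate being open, since only there does the configured distribution
apply. (The real survey is internally inconsistent about skip logic —
many respondents answered B2 despite B1 = No — so marginal missingness
and skip logic cannot both be reproduced exactly; the generator honours
skip logic.)

A few published cells are internally inconsistent (class sums ≠ 311/76,
or a count recoverable only from its percentage); they are transcribed
as printed and flagged rather than repaired, except one high-risk cell
of the stimulant-use item whose count is absent entirely and is
reconstructed from its printed percentage.

**Known limitation — within-class independence.** Only per-class
marginals are published, so items are sampled independently given the
latent class. Real snoring items (B1–B4) are strongly correlated, which
is precisely what lets three real items carry nearly all the label
information. Under independence the large-sample ceiling of the best
3-item subset is AUROC ≈ 0.94 against 1.0 for the full feature set
(whose function the label is); at the study size n = 387 finite-sample
effects narrow that gap, but passing protocol tests on synthetic data
demonstrate the machinery's shape and recovery properties, not the real
data's effect sizes. A post-processing hook for a dependence model can
be layered on the generator; the default remains independence.

## Desk-scale problem sizes

Heavier checks run at reduced scale, chosen as study-representative
while keeping the suite quick: protocol properties use the default
synthetic cohort (n = 387), R = 20 downvote repetitions, 10 evaluation
refits, 10 outer splits, and a 30-round boosted-tree probe; planted
recovery uses 20 runs at n = 400 with one label-defining feature among
five noise features; generator calibration uses n = 20,000. Exact
Fisher-test agreement with hypergeometric enumeration is established
for every 2×2 table with N ≤ 40 via canonical representatives under
row/column swaps and transposition (an algebraic symmetry of the
hypergeometric pmf, itself spot-verified on random tables).

## Numerical conventions

* Percentages: rounded half-up for display; raw retained.
* SDs of AUROC repetitions: population (ddof = 0); a single repetition
  reports SD 0.
* Stratified splits guarantee |P1| = ⌊0.7N⌋; a split leaving a class
  empty is resampled with the next seed and logged.
* Downvote and removal ties break toward earlier questionnaire item
  order.
* All derived seeds are kept below 2³¹.
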