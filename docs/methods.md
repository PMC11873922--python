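# Methods

## The modelling problem

Patients attending A&E at least three times in a year are classified into
low (< 5 visits), mid (5–10) and high (> 10) attendance classes from
demographic, deprivation, episode-count and long-term-condition (LTC)
features. The class distribution is severely imbalanced (roughly 77 / 21 / 2
percent), which drives three design threads: sample weighting, a
value-weighted loss, and evaluation that reports both macro and
support-weighted aggregates.

## Synthetic cohort generator

The generator's defaults are the study conditions: 17,437 patients, class
counts 13,474 / 3,615 / 348, 9,730 patients with exactly three visits (hence
3,744 with exactly four), attendance mean 4.14 and SD 2.81, and a feature
set mirroring the published variable list (gender, six ordinal age groups,
SIMD quintile skewed so ~77% fall in the two most deprived quintiles,
homelessness and deceased flags, six over-dispersed episode counts, ten LTC
flags plus their sum). Generation is four stages off one seeded
`numpy.random.Generator`, in documented order, so a config + seed is
bit-reproducible:

1. **Features** — independent draws per column: Bernoulli flags,
   categorical ordinals, gamma-Poisson (negative-binomial) episode counts.
   `total_ltcs` is computed, never drawn.
2. **Class assignment** — a latent risk `z·β + ε` over standardized
   features with signed coefficients β and `ε ~ N(0, 1)`; the top-348 rows
   by risk become class 2, the next 3,615 class 1, the rest class 0.
   Rank-based assignment makes the printed class sizes exact for every seed
   and decouples effect planting from count calibration. The noise keeps
   classes entangled, as real cohorts are.
3. **Count calibration** — class 0 is pinned at 9,730 threes / 3,744
   fours. The class-1 (support 5–10) and class-2 (support 11–60)
   distributions are truncated geometrics whose decay rates are solved (by
   bracketed root-finding, no RNG) so that the full mixture's mean and SD
   equal 4.14 / 2.81 to < 0.01 / 0.02. The within-class family is
   under-determined by two moments; the geometric is one admissible choice,
   and the 60-visit ceiling leaves enough tail mass to reach the SD given
   the bulk at 3–4 visits. Infeasible targets raise a calibration error
   naming the violated moment.
4. **Count draws** — stratified quota allocation: each visit count gets
   `floor(n·p)` guaranteed copies and the fractional remainders are
   allocated by systematic probability-proportional sampling (each value
   gains at most one extra copy, with the exact expected rate), then the
   values are randomly permuted across the class's rows. Compared to
   independent draws this removes almost all sampling noise from the
   realised moments — the 348-row heavy-tailed high class would otherwise
   move the cohort SD by ±0.08 between seeds — while keeping the
   row-to-count assignment random.

**Planted effects.** Coefficient signs follow the cross-model consensus
reported for such cohorts: acute inpatient episodes strongly positive, then
digestive conditions, male gender, alcohol, respiratory, self-harm and
mental-health episodes; age group, SIMD quintile, deceased flag, home care,
cancer and cardiac conditions negative. Magnitudes were fixed once so that
all five model families recover the strong-effect signs, and are frozen in
`default_effect_coefficients`. Effects with `|β| ≥ 0.15`
(`MIN_RELIABLE_EFFECT`) are guaranteed sign-recoverable in ≥ 19/20 seeds;
weaker planted effects (e.g. homelessness at 0.10) are real but not
reliably detectable at this cohort size, mirroring how marginal risk
factors behave in practice.

**What the generator does not emulate:** feature correlations (columns are
independent given the class structure), temporal patterns (time of
attendance, episode ordering), geographic structure beyond SIMD, and
missing data. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that planted signal of realistic shape is
recovered — not that real NHS records would yield the same accuracy or
ranking.

## Pre-processing

- **Variable removal**: externally supplied tables drop the SPARRA
  admission-risk score (derived from other columns in the table) and local
  authority (duplicates SIMD's geographic signal). The target column is
  protected from exclusion.
- **Binning**: classes as above; counts below three raise an
  inclusion-criterion error rather than binning silently.
- **Splitting**: seeded 70/30 random split by default, floor convention
  for the test size, optional per-class stratification. No cross-validation
  protocol is imposed.
- **Weighting**: inverse class frequency uses the balanced convention
  `w_c = N / (3 n_c)` (so weights sum to N); the value strategy uses
  `w_i = v_i / v̄` with the training-cohort mean as normaliser, keeping loss
  magnitudes comparable to unit-weight training.
- **Standardization** is fitted on training rows only and applied to both
  partitions; zero-variance columns get scale 1 with a warning.

## Model suite

One wrapper, `FrequentAttendanceClassifier`, fixes the conventions per
family: LR (LBFGS, iteration cap 100,000), RF (100 trees, Gini), SVM (RBF,
cost 1, kernel width `1/(d·Var)`, probabilities from a cross-validated
Platt calibration of the decision values because ROC analysis needs
scores), k-NN (k = 18, Euclidean; sklearn's voting breaks ties toward the
smaller class index), MLP (below). LR, RF and SVM receive
inverse-class-frequency sample weights in their objectives; k-NN has no
native weighting; the MLP is weighted by attendance values through its
loss. All scale-sensitive families (everything but the forest) are fitted
on internally standardized features; the wrapper consumes and predicts from
raw tables so that occlusion semantics stay in raw feature space.

## Value-hot focal loss and the MLP

The per-sample loss is `(v_i/v̄)·(1−p_true)^γ·(−log p_true)`, the canonical
composition of value-hot weighting with the focal term; γ defaults to 2
(the usual focal convention) and the normaliser to the mean attendance
count. Exact reductions hold and are tested: γ = 0 with unit values gives
cross entropy to 1e-12; all values equal to the normaliser gives plain
focal loss. `p_true = 0` is clamped at 1e-12 with a warning. The analytic
logit gradient is checked against central finite differences to 1e-5.

The MLP is a numpy implementation: hidden layers of affine → batch norm →
ReLU → dropout, a softmax head, Adam updates on the loss plus L1/L2 weight
penalties (weights only, not biases or batch-norm parameters). Defaults —
hidden sizes (64, 32), dropout 0.2, L2 1e-4, L1 0, learning rate 1e-3,
batch 256, up to 200 epochs with early stopping (10% validation split,
patience 20) — are frozen, exposed as constructor parameters. He
initialisation; every stochastic element (init, shuffling, dropout,
validation split) draws from one seeded generator, so fits are
deterministic. An empty hidden tuple yields softmax regression, which is
tested to match an unpenalized multinomial-LR fit within 0.05 log-loss.
Non-finite losses abort with diagnostics. Batches of fewer than two rows
are skipped (batch norm needs a variance).

## Evaluation

3×3 confusion matrices (rows actual, columns predicted), one-vs-rest
precision/recall/F1 per class, and both macro and support-weighted
aggregates — always both, explicitly labelled, since imbalanced three-class
summaries are ambiguous otherwise. One-vs-rest ROC per class with
trapezoidal AUC; macro AUC is their unweighted mean. A class never
predicted gets precision 0 with a warning so aggregates stay finite.

## Shapley-value risk factors

The attribution target defaults to the expected attendance class
`Σ_c c·p_c(x)` — a single monotone risk scalar that produces one signed
value per feature; per-class probability mode is available.

- **Zero-input occlusion**: `φ_j = mean[score(x) − score(x with x_j := 0)]`
  over the evaluated rows. Substitution happens in raw feature space (the
  model wrapper re-standardizes internally): raw zero means "absent".
  Substituting in standardized space would mean "set to the cohort mean",
  a different and weaker notion. Ordinals (age group, SIMD) are zeroed
  as-is even though 0 is outside their coded range — the operation is
  uniform across features by design.
- **Permutation sampling**: Monte-Carlo over feature orderings; features
  not yet added take values resampled independently per column from the
  evaluated cohort's empirical marginals (or a fixed background vector).
  φ_j is the mean score change when j is added, averaged over rows and
  orderings, with a standard error across orderings. Seeded.
- **Exact oracle**: full subset enumeration with the Shapley kernel
  weights, guarded to ≤ 12 features (2^d coalition evaluations, vectorised
  into one model call). Default background is the all-zero raw vector,
  matching the occlusion notion of absence. Used only for validation:
  efficiency/dummy/symmetry hold to 1e-9, permutation estimates converge
  to it within Monte-Carlo error, and for additive scores with zero
  background all three methods coincide.

**Cohort targeting**: importances are computed on sub-cohorts selected by
actual class — low/mid ({0, 1}: factors that would escalate attendance)
and high ({2}: factors whose mitigation could reduce it). The model is
probed, never refitted, per cohort. Features with `|φ| ≤ 0.01` are dropped
from the ranked report; ties break by feature name.

## Pipeline

`run_pipeline` chains generate/load → validate → exclude → split → fit each
family → evaluate → rank risk factors per cohort, writing the cohort CSV,
split manifest, per-model evaluation JSONs, a combined confusion CSV (one
block of model rows per actual class), a metrics CSV and risk-factor CSVs,
plus a manifest with config hash, seeds, package version and per-stage
wall time. Any stage failure aborts with the stage name; partial outputs
and a failure marker are retained. Given the config and seeds, all outputs
are byte-deterministic.

## Problem sizes

The test suite exercises the generator at the full 17,437-patient scale
(generation takes well under a second) and fits models on proportionally
scaled cohorts — 2,000 rows for contract tests and 4,000 rows for the
end-to-end sign-recovery check, the scaled-down variant of the full-size
condition; `GeneratorConfig.scaled(n)` preserves class proportions and the
within-class composition, so the scaled cohorts are the same study design
at smaller n.

## Known limitations

- Independent feature marginals understate the collinearity (e.g. between
  LTC flags and total LTCs beyond the sum identity, or age and LTC burden)
  that complicates attribution on real records.
- The zero-input method inherits occlusion's blindness to interaction
  structure; the permutation estimator ignores feature dependence when
  resampling marginals. Both are approximations whose error relative to
  exact Shapley values is bounded only empirically here.
- k-NN probabilities are neighbour-vote fractions and therefore coarse;
  its ROC curves have few distinct thresholds at k = 18.
- The weak-effect regime (|β| < 0.15) is deliberately left unreliable;
  conclusions about such features require larger cohorts.
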