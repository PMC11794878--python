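# Methods

## The ranking model

ACRFS is a filter feature-selection method: it orders features by their
marginal association with a binary label and cuts the ordering at a
threshold rank. Three association statistics ("solvers") are computed per
feature, chosen to cover complementary structure:

- **Mutual information** (any dependence). The feature is discretized into
  at most `mi_bins` quantile bins (default 10; a feature with fewer distinct
  values than bins is used as-is, making the estimate exact for discrete
  data) and the plug-in estimator
  I = Σᵢⱼ pᵢⱼ log₂(pᵢⱼ/(pᵢ·p·ⱼ)) is evaluated on the joint histogram with
  0·log(0/q) ≡ 0. Base-2 logs are a reporting choice: any base rescales
  monotonically and leaves every rank unchanged. Quantile binning makes the
  value invariant to strictly increasing rescalings of the feature.
- **Chi-square** (per-class mass). The default `frequency` mode treats the
  per-class sums of a non-negative feature as observed counts, the class
  proportions of the total mass as expected counts, and computes
  χ² = Σ(O−E)²/E with df = n_classes − 1; features are ranked by the
  survival-function p-value ascending, which at fixed df is equivalent to
  ranking by the statistic descending. This mode matches how the test is
  conventionally applied to raw positive-valued measurements. A `binned`
  mode builds a quantile-binned contingency table instead
  (df = (bins−1)(classes−1)) for data that can be negative.
- **Pearson correlation** (linear dependence). Ranked by |r| by default:
  a strong negative linear association is exactly as informative for
  classification as a positive one, and published coefficient tables for
  this kind of pipeline contain negative entries among *influential*
  features. A `signed` mode exists for literal replication attempts. A
  zero-variance feature returns r = 0 with a warning rather than an error,
  so one degenerate column cannot abort a whole scoring pass.

Each solver's scores become a **dense 1-based ranking** (best = 1, ties
share a rank, no gaps). Dense ranking is essential to the aggregation: it
keeps the per-solver rank ranges comparable even when solvers produce
different numbers of distinct scores. The per-feature ranks are averaged
arithmetically across solvers — no weighting, as none is justified a
priori — and the averages are densely re-ranked (smaller mean = better)
into the finalized rank vector. Dense finalization preserves ties; an
`ordinal` option breaks ties by feature order for strict top-k selection.

Averaging *ranks* rather than raw coefficients is the crux: the three
statistics live on incompatible scales (bits, p-values, correlations), and
rank fusion is invariant to any monotone transformation of each solver's
scores.

## Selection and categorization

A feature is selected iff its finalized rank ≤ TVR (threshold value rank,
default 20). Under dense ranking, boundary ties are all selected, so the
subset may exceed TVR features; this is deliberate — rank ≤ TVR is the only
selection rule, and silently dropping tied features would be arbitrary.

Categorization extends selection into a three-tier hierarchy: primary
(rank ≤ TVR — by construction exactly the selected set), secondary (the
next `secondary_width` ranks, default 5), and less influential (the rest).
The published piecewise bounds for this scheme (ranks 1–19 / 20–24 / 25–29
on 30 features) leave the last rank uncategorized and disagree with the
selected-set size by one; the default boundaries here reconcile the
categorization with the selection rule while a `literal_bounds` mode applies
the printed bounds verbatim (top interval closed) for transparency.

## Class balancing

Classic SMOTE: the minority class is oversampled to the majority count; each
synthetic sample is x + u·(x′ − x) with x a uniformly chosen minority
sample, x′ one of its k nearest minority neighbors (Euclidean; k = 5
default, clamped to minority_count − 1 with a warning), and u uniform on
[0, 1]. Base index, neighbor choice, and u come from a single seeded
generator, so output is reproducible. Original rows precede all synthetic
rows unchanged.

Placement is configurable because the order is genuinely ambiguous in
descriptions of such pipelines: `post_select` (default) balances the data
only for classifier evaluation after the subset is chosen; `pre_rank`
balances before solver scoring. By default balancing happens before the
train/test split, replicating the common (if leaky) practice; the
`leakage_safe` flag splits first and oversamples the training partition
only, which is the methodologically sound order — synthetic points
interpolated from test-set rows otherwise leak label information into
training.

## Evaluation harness

`split_dataset` performs a seeded stratified split (default 75/25). Metrics
are computed in closed form from the confusion counts with label 1 positive:
accuracy; precision and recall macro-averaged over both classes by default
(`positive_class` reports class-1 values); F1 as the harmonic mean of the
*reported* precision and recall — note this differs from the other common
macro-F1 convention (mean of per-class F1s); Cohen's kappa with
marginal-product chance agreement; and MCC. Any 0/0 metric is reported as 0
with a warning (the common degenerate-case convention). On a symmetric
confusion matrix (fp = fn), kappa and MCC coincide — a useful closed-form
cross-check.

The before/after harness trains each classifier on the full feature set and
on the selected subset with identical balance and split seeds, so the
feature set is the only difference between arms. The six reference models
(RF, GNB, DT, KNN, SVM, SGD) are thin adapters over scikit-learn estimators
at library defaults — their internals are not this package's contribution —
behind a two-method `fit`/`predict` contract that accepts any user model.
An adapter failure is recorded per model rather than aborting the run.
Features are deliberately not standardized: the pipeline evaluates feature
*selection*, and scale-sensitive models (SGD, SVM) showing larger deltas on
raw features is part of the observed behavior, not an artifact to remove.

## Synthetic data

The generator emulates a diagnostic biopsy table: 357 majority (benign-like)
and 212 minority (malignant-like) samples with 30 continuous features in
three planted tiers — 20 primary, 5 secondary, 5 noise with standardized
between-class mean differences 1.5, 0.5, and 0.05. Features are
class-conditional Gaussians with unit variance, centered at a positive
baseline (10.0) so that frequency-mode chi-square — which requires
non-negative mass, as real morphometric measurements are — applies; at this
baseline the probability of a negative draw is negligible (~10⁻²³).
Within-tier equicorrelation (default 0.3, via a shared per-sample factor)
mimics the redundancy of mean / standard-error / worst triplets derived
from the same underlying measurement without making tiers collinear. Column
order is shuffled so tier membership is not encoded positionally.

What the generator does **not** emulate: the skewness and heavy tails of
real morphometric features, heteroscedastic class-conditional variances,
cross-tier correlation, and measurement outliers. Passing tests on this
generator therefore demonstrate that the pipeline's machinery is correct
and that clearly separated effect tiers are recovered; they do not certify
performance on any particular real dataset.

`tier_recovery` scores a ranking as the fraction of planted primary
features with finalized rank ≤ k; a random permutation scores k/n in
expectation, perfect recovery scores 1. With default settings, mean
recovery at k = 20 over 20 seeds exceeds 0.90 (in practice it is 1.0).

## Numerical and design choices

- Missing cells are imputed with the per-column mean of observed values;
  an entirely missing column is a hard error naming the column. Labels are
  encoded deterministically: lexicographically smaller raw value → 0.
- All ranks are 1-based everywhere.
- MI's 0·log 0 terms are handled by `xlogy`; p-values come from
  `scipy.stats.chi2.sf` directly (no continuity correction in binned mode,
  matching the plain statistic).
- Reports round-trip through CSV at 17 significant digits.
- Problem sizes in the test suite and acceptance script (569×30 datasets,
  20 seeds, 10⁴ random confusion matrices, the full 2×2 table sweep) were
  chosen to exercise every contract at the generator's native scale while
  keeping a full run in the tens of seconds.

## Known limitations

- The aggregation is an unweighted mean over exactly the configured solvers;
  no stability/bootstrap analysis of the ranking is provided.
- Frequency-mode chi-square is undefined for features with negative values;
  use `chi2_mode="binned"` for such data.
- No hyperparameter tuning, cross-validation, or significance testing of
  before/after metric deltas; the harness is a controlled comparison, not a
  benchmark suite.
- Exact replication of any previously published run on real data is not
  attainable in principle when that run's oversampling seed, split seed, and
  classifier settings are unspecified; agreement is expected only to within
  a few percentage points.
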