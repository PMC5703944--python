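# Methods

## Model and procedure

`synpair` screens gene pairs for synergy with a conversion-plus-t-score
strategy. The data are an m-gene × n-sample expression matrix X_ij with a
binary phenotype Y_i ∈ {0, 1} (convention: 0 = cancerous, 1 = normal; the
label mapping applied at load time is recorded on the dataset and logged).
Each gene's values are replaced by their within-gene sample ranks R_ij,
which makes the screen invariant to any strictly increasing per-gene
distortion (background level, quantization, monotone normalization
differences). A pair (p, q) is collapsed into a single feature vector Z by
one of five conversion types: sum, diff, mul, sign (the four classical
doublet/top-scoring-pair conversions) and abs, Z_i = |R_ip − R_iq|. The
association of Z with Y is measured by a two-sample t statistic, and pairs
are ranked by |t|; individually discriminant genes are ranked by the same
statistic on their raw values.

The abs conversion is the methodological point: when the phenotype depends
on the *disparity* of two genes (Y ≈ |X₁ − X₂|, the diagonal-band pattern),
each gene is marginally uninformative, every symmetric-in-sign conversion
(sum, mul) and every monotone conversion (diff, sign) produces a Z whose
class-conditional means coincide, and only |R_p − R_q| converts the pattern
into a mean shift a t-test can see. The interaction-information module
provides the information-theoretic reference: such pairs have
I(X₁;X₂;Y) = I(X₁,X₂;Y) − I(X₁;Y) − I(X₂;Y) > 0.

## The t statistic

Default is the Welch (unequal-variance) form,
t = (m₀ − m₁) / √(v₀/n₀ + v₁/n₁), with sign convention mean(class 0) −
mean(class 1); a pooled-variance Student t is selectable
(`t_variant="pooled"`). For ranking, only |t| matters, and on the scales
involved Welch vs pooled changes rankings negligibly; Welch is the safer
default when class variances differ. A converted feature that is constant
within both classes scores 0 if the class means agree and ±∞ if they do
not; infinities rank above all finite scores (a perfectly separating,
zero-variance feature is maximal evidence, not an error) and are flagged by
the sentinel value itself. Ties in |t| break toward the lexicographically
smaller (p, q) so output is reproducible bit-for-bit.

Group means and variances are accumulated as per-row sums and sums of
squares with a fixed per-row reduction order, which makes the blockwise
scan's scores identical — to the last bit — to scoring pairs one at a time,
independent of `block_size`. The scan enumerates canonical pairs (p < q)
lazily in blocks of `block_size` (default 512) pairs, so memory is
O(block_size · n) rather than O(m²); a 10⁴-gene matrix (~5×10⁷ pairs) never
materializes more than one block of converted vectors.

## Ranks and ties

Ranks are 1-based; ties receive the average of the ranks they span, which
keeps every gene's rank sum at exactly n(n+1)/2 and the abs conversion's
range within [0, n−1]. Integer competition ranking is available
(`ties="competition"`) for users who want the top-scoring-pair convention.
Tie handling on continuous expression data is essentially irrelevant
(ties have measure zero) but matters for quantized data. By default ranks
are computed once on all samples before cross-validation, reproducing the
screen-then-validate protocol in which pairs are ranked on the full
dataset; the estimators also compose into a pipeline (`nested=True` in the
harness) that re-ranks and re-screens within each training fold, the
selection-bias-safe variant. The two modes are labelled in every report
and never mixed.

## Interaction information

The reference synergy measure discretizes each feature into equal-frequency
bins (default 4) and uses the plug-in (maximum-likelihood) mutual
information in bits; interaction = I(X₁,X₂;Y) − I(X₁;Y) − I(X₂;Y) holds
exactly by construction. Base-2 logarithms make the balanced XOR triple
land exactly at (0, 0, 1, +1) bits. There is no bias correction: plug-in
MI is upward-biased at small n and the joint term (up to 16 cells per
class) more so than the marginals, so small positive interactions at
n ≲ 200 should not be over-read. Four bins is a deliberate compromise —
coarse enough that the 4×4×2 joint table is well populated at the sample
sizes screened here, fine enough to register the diagonal-band pattern.
This module is a per-pair reference measure, not a genome-wide screen; the
whole point of the conversion strategy is to avoid estimating the
three-variable information for every pair.

## Simulator

The generator plants the architecture the abs conversion targets:
feature columns i.i.d. U(0, 1), continuous phenotype
y = Σ_ind x_j + Σ_pairs |x_{2j−1} − x_{2j}|, and binary labels by median
split (strictly above the midpoint median → class 1), which is exactly
balanced for even n since the draws are continuous. Defaults follow the
study conditions: n = 200 samples, k = 1..10 pairs with no noise columns
for the converted-vs-unconverted grid; noise columns (independent U(0, 1))
are added for recovery experiments. What it does *not* emulate:
correlated genes, heavy-tailed or batch-structured expression, label
noise, class imbalance. Passing tests on these data show the screen
recovers planted rank-disparity structure under clean conditions; they say
nothing about power under correlated backgrounds.

## Cross-validation harness

Accuracy is (TP+TN)/(TP+FP+TN+FN) × 100, computed per fold from the test
fold's confusion counts and averaged over stratified five-fold CV with
seeded shuffling (stratification protects the small simulated datasets
from single-class folds). The classifier registry holds seven models:

| name | settings | rationale |
|------|----------|-----------|
| svm_rbf | C=1, gamma variance-scaled | sklearn's scale heuristic; adapts to feature spread |
| svm_linear | C=1 | — |
| svm_poly | degree 3, C=1, gamma=1/d | LIBSVM's default gamma convention |
| svm_sig | C=1, gamma=1/d | LIBSVM default; variance-scaled gamma saturates tanh |
| random_forest | 100 trees | accuracy indistinguishable from larger forests at n≈200, d≤20 |
| ann | one hidden layer of 16 units, L-BFGS | full-batch quasi-Newton is reliable at these sample sizes where SGD with early stopping is not |
| decision_tree | default depth | — |

Features are min–max scaled to [0, 1] inside each training fold before SVM
and MLP fitting (LIBSVM practice; simulated features already live in
(0, 1), so scaling mainly matters for rank-valued Z columns). Feature
schemes feed pair features **as converted Z columns**, never as raw
pair-member columns — the harness exists to demonstrate that this
distinction is what lets classifiers learn synergic structure. The
label-randomization control re-runs the identical CV with uniformly
permuted labels; with class-balanced data its accuracies collapse to ~50%.

## Problem sizes in the shipped experiments

The test suite and acceptance script run the simulation grid at n = 200
with 20 CV replicates per cell (fresh data and fresh fold shuffling per
replicate), 100 replicates for planted-pair recovery and for the
abs-pattern synergy rate, and n = 10⁴ for the independence null — sizes at
which every reported quantity is stable to well within the tolerances the
checks assert.

## Known limitations

- Raw |t| ranking only: no p-value calibration or multiple-testing control
  across the m(m−1)/2 pairs (screening, not inference).
- Plug-in MI bias as above; the interaction module is a reference, not an
  estimator of record.
- All-samples screening (the default, protocol-faithful mode) optimistically
  biases downstream CV accuracy; use `nested=True` when unbiased accuracy
  estimates matter more than replication of the original protocol.
- The published real-data experiments depend on four microarray cohorts not
  shipped here; the package exercises those code paths on synthetic data.
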