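# synpair

Fast screening of **synergic gene pairs** in binary-phenotype expression
data.

Individually discriminant genes — genes whose marginal expression separates
cancer from normal samples — are easy to find with a per-gene *t*-test.
Synergic pairs are harder: two genes can be jointly predictive while each
one alone carries no signal (positive interaction information
I(X₁;X₂;Y) > 0). Estimating I(X₁;X₂;Y) or MIC(X₁;X₂;Y) for every one of
the m(m−1)/2 pairs of a microarray is expensive and sensitive to
discretization. `synpair` implements the cheap alternative: collapse each
pair into a *single* feature and rank pairs with an ordinary two-sample
*t*-score.

Given expression values X_ij (sample *i*, gene *j*) replaced by their
within-gene ranks R_ij, a pair (p, q) is converted by one of five types:

| type | Z_i |
|------|-----------------------|
| sum  | R_ip + R_iq |
| diff | R_ip − R_iq |
| mul  | R_ip × R_iq |
| sign | 1 if R_ip ≥ R_iq else 0 |
| abs  | \|R_ip − R_iq\| |

The **abs** conversion is the one that captures the classic diagonal-band
synergy pattern (phenotype determined by how far apart two genes' ranks
are, Y ≈ |X₁ − X₂|), which the four doublet/TSP-style conversions and
single-gene ranking all miss. Converted features Z are screened
exhaustively and blockwise — memory stays O(block · n) however many pairs
exist — and the top pairs are fed, *as converted Z columns*, to standard
classifiers evaluated by stratified five-fold cross-validation with
Accuracy = (TP+TN)/(TP+FP+TN+FN) × 100%.

The package ships a planted-structure simulator
(y = Σ_j |X_{2j−1} − X_{2j}|, X ~ U(0,1), labels by median split), a
plug-in interaction-information reference measure, and the CV harness
comparing converted vs unconverted features and Ind/Syn/combined feature
schemes, including a label-randomization control.

## Worked example

```python
from synpair import (simulate_abs_pairs, scan_pairs, run_cv,
                     interaction_information)

# one planted abs pair (X1, X2) among 18 noise genes, n = 200 samples
ds = simulate_abs_pairs(k=1, n=200, seed=7, n_noise=18)
for e in scan_pairs(ds.to_expression_dataset(), conversion="abs",
                    top_n=3).entries:
    print(f"{e.rank}  {e.gene_p}-{e.gene_q}  t={e.t_score:.3f}")

s = interaction_information(ds.x[:, 0], ds.x[:, 1], ds.labels, n_bins=4)
print(f"interaction = {s.interaction:.3f} bits")

conv = run_cv(ds.z_true, ds.labels, "svm_rbf", seed=7).mean_accuracy
raw = run_cv(ds.x, ds.labels, "svm_rbf", seed=7).mean_accuracy
print(f"5-fold CV accuracy: converted {conv:.1f}%  unconverted {raw:.1f}%")
```

prints

```
1  X1-X2  t=-21.949
2  X2-N2  t=-3.259
3  N1-N14  t=3.149
interaction = 0.621 bits
5-fold CV accuracy: converted 98.5%  unconverted 95.0%
```

The planted pair tops the scan with |t| ≈ 22 while the best spurious pair
sits near |t| ≈ 3; its interaction information is strongly positive
(0.62 bits — synergy, since neither gene is individually informative); and
the classifier does better on the single converted feature Z = |X₁ − X₂|
than on the two raw columns.

The same workflow is available from the shell:

```sh
synpair simulate --k 1 --n 200 --n-noise 18 --seed 7 --out sim.tsv
synpair scan --input sim.tsv --conversion abs --top-n 10 --out pairs.tsv
synpair synergy --input sim.tsv --pair X1 X2 --bins 4
synpair evaluate --input sim.tsv --top-ind 10 --top-syn 5 --seed 1
synpair benchmark --k-max 10 --seeds 0..19 --out grid.tsv
```

For real datasets, `synpair scan --input matrix.tsv` expects a delimited
matrix with genes in rows, a header row of sample ids, and a `label` row
with exactly two distinct values (see `synpair.io.read_expression` for the
orientation and label-mapping options).

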