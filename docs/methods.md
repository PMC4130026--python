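# Methods

## Model and procedure

The package implements a filter–wrapper hybrid for multiclass
classification of labeled gene-expression matrices, built entirely on
chi-square statistics of m×2 class-conditional contingency tables.

Two table families are used. The *mean-split* table of a single gene
counts, per class, samples above versus below the gene's mean over all
samples of the dataset the table is built from; during selection that
dataset is always the training set, and single-gene tables are never
built across train and test. The *pairwise ordering* table of a gene
pair counts, per class, samples where the first gene exceeds the second
within the same sample. In both families an exact tie contributes 0.5
to each column of its class row, so counts may be fractional while each
table's grand total remains exactly the number of samples.

The chi-square statistic is evaluated in the products-of-marginals form
`N(Σ f²/(n_k T_q) − 1)`, which is algebraically the Pearson
`Σ(O−E)²/E` without continuity correction. It is used purely as an
association score: no p-values, degrees of freedom, or Yates correction
appear anywhere.

Ranking integrates main effects and interactions: gene j's score is
`S_j = χ²_j + Σ_{l≠j} w_jl · χ²_{j,l}` with `w_jl = χ²_j/(χ²_j+χ²_l)`.
The two ends' weights of every pair sum to one, so the total pairwise
mass is conserved across the ranking (a tested invariant).

The direct classifier needs no training: each candidate class is scored
by provisionally adding the test sample to that class and summing the
r(r−1)/2 pairwise statistics over the n+1 samples. Forward selection
starts from the ranked list's top two genes and accepts a candidate iff
the LOOCV accuracy of the direct classifier strictly increases, or ties
while the mean margin h̄ strictly increases. The procedure is purely
forward (no backward pass) and fully deterministic.

## Assumptions

- Class structure is expressed either through location shifts of single
  genes or through class-dependent reversals of within-sample gene
  orderings. Signals visible only in variance or in higher-order gene
  combinations are outside the model.
- Expression values are continuous; exact ties are expected to be rare
  and meaningful (see tie handling below).
- The classifier's robustness claim — invariance of predictions under
  strictly increasing per-sample transformations — holds exactly for
  the pairwise machinery and is asserted by tests; the mean-split
  statistic used in ranking is *not* invariant, so ranking (unlike
  classification) can be affected by per-sample distortions.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `cap_fraction` | 0.02 | fraction of the ranked list examined by forward selection; cap = max(2, round(cap_fraction·p)), counting the initial pair |
| `pair_prefilter` | None | if set to K, pairwise statistics are evaluated only among the top-K genes by single-gene chi-square (all other genes score S_j = χ²_j); bounds the O(p²) sweep on very large panels |
| `tie_tol` | 0.0 | absolute tolerance below which a comparison is declared a tie; the default treats only exact floating-point equality as a tie, since continuous expression values tie essentially only by design |

## Numerical choices

- **Zero margins.** A table cell whose row or column total is zero is
  necessarily zero and contributes nothing to the statistic (0/0 := 0),
  matching the limit of the Pearson form.
- **Clamping.** The statistic is mathematically non-negative; negative
  rounding residue (order 1e-15, from near-proportional fractional
  tables) is clamped to 0 so that independence yields exactly 0 and
  zero-effect genes get exactly zero ranking weight.
- **Zero-over-zero weights.** When both ends of a pair have zero
  single-gene statistic, the pair's weight is 0 for both: a pair of
  genes with no marginal effect carries no attributable direction.
- **Degenerate margins.** When a sample's true-class score is 0, its
  margin h is recorded as 0 with a warning (no evidence either way);
  this keeps the accept rule NaN-free on pure-noise data.
- **Tie-breaks**, all deterministic: ranking by descending S_j, then
  descending χ²_j, then gene identifier; class-score ties resolve to
  the fixed sorted class order; accept comparisons are strict with no
  tolerance (equal-accuracy, equal-h̄ candidates are rejected).
- **Exactness of incremental updates.** All counts are half-integers,
  exactly representable in binary, so the cached-table classifier
  (unit updates for the added sample) and the cached-table LOOCV
  (remove one contribution, re-add under each hypothesis) are bit-exact
  against from-scratch reconstruction — asserted, not approximated, in
  the acceptance tests.

## Design choices on open points

- The integrated score's pair sum runs over l ≠ j; a self-pair has no
  contingency table.
- The classifier's tables are pairwise ordering tables. A mean-split
  reading would be incoherent with the r(r−1)/2 pair count and would
  let the test sample move every split point; only the one added row
  may change.
- "Top 2%" is rounded (`round(0.02·p)`, minimum 2) and includes the
  initial two genes.
- The initial top-two genes are unconditionally kept; the procedure
  defines no backward pass.
- The ordered list Θ is computed once on the full training set, not
  re-computed per LOOCV fold; this is cheaper and matches the
  procedure's description, at the cost of a potential optimistic bias
  in the reported training LOOCV.
- Delimiters are auto-detected among tab and comma (overridable);
  missing values are rejected rather than imputed, since any imputation
  would silently change every statistic; labels are opaque strings and
  the sorted label order fixes all downstream tie-breaks.

## Synthetic data

The generator plants the two signal structures the method detects.
Single-shift genes place class k's mean at `effect·sd·k` plus Gaussian
noise. Planted pairs share a per-sample latent level `L ~ N(0,1)` and
split a signed class offset: `gene_a = L + s_c·d/2 + ε_a`,
`gene_b = L − s_c·d/2 + ε_b` with `ε ~ N(0,1)`, `s_c = +1` in the first
class and −1 otherwise, and `d = √2·Φ⁻¹(1−flip_prob)` so the
probability of the wrong within-sample ordering is exactly `flip_prob`;
at `flip_prob = 0` the ordering is enforced by reflecting the noise
difference (the infinite-offset limit). Remaining genes are i.i.d.
noise; a lognormal option exponentiates all values, preserving every
within-sample ordering while mimicking expression positivity.

Defaults define the package's reference recovery setting: two balanced
classes, 30+30 training and 30+30 test samples (stratified split), 200
noise genes, two shift genes at |effect| = 2 sd — one up- and one
down-regulated, the typical two-marker configuration — and one planted
pair at flip_prob = 0.05.

What the generator does *not* emulate: batch structure, heavy-tailed or
count noise, gene–gene correlation beyond the planted pairs, class
imbalance beyond what `n_per_class` encodes, and platform artefacts.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted signal under clean conditions, not expected
accuracy on real tumor panels.

## Problem sizes

The test suite and the acceptance script run at deliberately small
scale chosen to exercise every code path: oracle comparisons on random
instances up to n = 40, r = 6, m = 4; recovery and null studies over 20
generator seeds at p ≈ 200 (p = 2000 for the null single-gene
calibration, where only single-gene statistics are needed). The
implementation itself is vectorised and handles tens of thousands of
genes via `pair_prefilter`.

## Known limitations

- With a dominant planted pair the training LOOCV saturates at the
  initial step and the strict accept rule then rejects genuinely
  informative additions whose h̄ contribution is diluted by weaker
  pairs; recovery of *all* planted genes is therefore not guaranteed
  even at strong effect sizes. This is inherent to the strict
  forward rule, not a defect of the search.
- The mean margin h̄ compares at machine precision; candidates whose
  only effect is an exact score duplication (e.g. a duplicated gene)
  produce h̄ differences at rounding level and are rejected only
  because the comparison is strict.
- O(p²) pairwise ranking is quadratic in genes; use `pair_prefilter`
  beyond a few thousand genes.
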