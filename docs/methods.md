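# Methods

`igselect` implements a two-stage hybrid gene-selection pipeline for
two-class expression matrices, together with the evaluation protocol and a
synthetic-data generator used to validate it.

## Problem setting

The input is an m × n matrix of continuous expression values (m samples in
the tens, n genes in the thousands) with a binary phenotype per sample.
The goal is a very small gene subset (default 3) that classifies the
phenotype accurately. Because m ≪ n, univariate filters are used first to
discard the bulk of irrelevant genes cheaply, and a classifier-guided
wrapper then removes genes that are individually predictive but jointly
redundant.

## Pipeline

1. **Normalization.** Each gene is scaled to zero mean and unit variance.
   "Unit variance" uses the population (1/m) form; the choice only rescales
   by √(m/(m−1)) and is documented for reproducibility. Constant genes are
   mapped to zero and flagged rather than dropped, so column indices remain
   stable. Normalization statistics are computed on the full matrix by
   default; within-training-fold statistics are available via
   `normalize_within_fold` for leakage-free evaluation.

2. **Filter ranking.** Four per-gene scores are available:
   - *Information gain* (default): g(Y, X) = H(Y) − H(Y|X) in bits, with
     H(Y) = −Σ p(y) log₂ p(y) and H(Y|X) = Σₓ p(x) H(Y|X=x).
   - *Gain ratio*: g(Y, X) / H(X), zero by convention when the gene's bin
     distribution has zero entropy.
   - *Point-biserial correlation*: |r| between the continuous gene and the
     ±1 labels; constant genes score 0.
   - *ReliefF*: nearest-hit/nearest-miss feature weighting (k = 10
     neighbours, all instances by default, per-gene min–max scaled
     Manhattan differences; the two-class miss prior reduces to 1).

   Entropy scores require discrete variables, so each gene is first
   discretized with the Fayyad–Irani MDLP procedure: recursive binary
   splitting at class-boundary midpoints, accepting a split only when its
   information gain exceeds the MDL cost
   (log₂(N−1) + log₂(3^k − 2) − [k·H(S) − k₁·H(S₁) − k₂·H(S₂)])/N.
   A gene with no accepted cut forms a single bin and scores exactly 0.
   Unsupervised equal-frequency binning (10 bins) is available as a
   fallback. All entropies are base 2; on binary problems this puts IG in
   [0, 1], matching how such scores are conventionally reported.
   Ties in every ranking break by the on-disk gene order, making rankings
   exactly reproducible.

3. **Wrapper refinement (SVM-RFE).** The top 150 filter-ranked genes are
   reduced to 3 by recursive feature elimination: a linear-kernel
   soft-margin SVM is trained on the surviving genes and the gene with the
   smallest squared weight w_j² is removed, refitting each round. The
   linear kernel is used because only it yields per-gene weights; a
   single-pass variant (one fit, keep the k largest |w_j|) is provided for
   comparison.

4. **Evaluation.** The selected genes are scored by stratified 10-fold
   cross-validation of an RBF-kernel SVM (K(a,b) = exp(−γ‖a−b‖²), γ = 1/p,
   C = 1, the usual libsvm defaults). Folds are built per class by seeded
   shuffle and round-robin deal, so each fold's class proportions are
   within one sample of the global proportions. Accuracy is the pooled
   percentage of correctly classified samples, reported to 2 decimals.

SVM training is delegated to libsvm (through scikit-learn's `SVC`); the
package exposes the dual solution and checks 0 ≤ αᵢ ≤ C and Σαᵢyᵢ = 0 for
every model in its test suite, and verifies the trained dual objective
against an independent quadratic-programming solution on small problems.

## The slack penalty in the elimination stage

The elimination stage does **not** use C = 1. With z-scored genes and
m ≪ p the training data are linearly separable, so for any C ≥ 1 no dual
variable reaches its bound: the fit is effectively a hard-margin SVM, and
the hard-margin weight vector redistributes sharply as genes are removed.
Empirically this makes step-1 RFE unstable: on synthetic data with three
planted genes at a between-class shift of 2.0–2.5 pooled SD, recovery of
the planted triple drops to 25–75% of replicates at C = 1 (the identical
behavior is obtained from scikit-learn's independent RFE implementation,
so this is a property of the procedure, not of this code). Recovery is
≥ 95% across the whole range C ∈ [0.01, 0.1]. The package therefore
defaults the elimination stage to **C = 1/m**, which lies in that stable
region and has a natural reading: it keeps the total slack budget
comparable to the margin term as the sample count changes, so the box
constraints stay active in the m ≪ p regime. The final RBF classification
stage keeps C = 1. Both are configurable.

## Evaluation protocols and selection bias

By default the pipeline mirrors the conventional two-step protocol:
selection is performed once on the full dataset and the selected genes are
then cross-validated. This is optimistically biased — the test folds were
visible during selection. The bias is not small: on null data (no planted
signal, colon-like shape, 62 samples × 2000 genes, majority class 64.5%)
the default protocol reports ≈ 78–79% mean accuracy, about 14 points above
the majority rate, uniformly across all four filters. With
`select_within_fold=True` the entire selection pipeline is re-run inside
each training fold and the same null data score ≈ 54–56%, i.e. near
chance. Results obtained under the default protocol should be read as
comparisons *between* selection methods, not as unbiased accuracy
estimates; the within-fold mode is the honest estimate.

## Synthetic study data

The generator emulates the shape of classic two-class microarray
benchmarks: n ≈ 2,000–7,129 genes, m ≈ 47–102 samples, unbalanced classes
(presets: colon-like 2000 × 62 at 40/22, lung-like 7129 × 96 at 86/10,
leukemia-like 7129 × 72 at 25/47). Genes are independent Gaussians with
unit within-class SD; a small planted set (default 3) receives a
between-class mean shift expressed in pooled-SD units (default 2.5, a
strong but realistic microarray effect). Options add a block of redundant
genes correlated at ρ with an informative gene, and a log-normal transform
for heavy-tailed raw intensities. Everything is reproducible from one
seed.

What the generator does *not* emulate: gene–gene correlation structure
beyond the optional block, batch effects, probe-level noise, and the
many-gene polygenic signal of real tumors. Consequently, validation
results on synthetic data show that the pipeline recovers a known sparse
signal and does not hallucinate one — they do not certify accuracy levels
on real expression data.

One consequence of the sparse-signal design matters for the
accuracy-versus-n curve: with only 3 informative genes, an RBF kernel over
the top 200 ranked genes is dominated by the ~197 noise coordinates, and
accuracy necessarily decays as n grows (measured: from ~98% at n = 3 to
~66% at n = 200). Real tumor datasets keep such curves flat because they
carry differential signal in far more genes. The curve-shape validation
therefore plants 30 informative genes out of 2000 (a 1.5% differential
fraction, conservative for tumor/normal comparisons); the curve then
plateaus at its n = 30 level through n = 200.

## Study sizes used in validation

Planted-gene recovery and null-behavior studies use 20 replicates of the
colon-like shape; the honest-protocol null uses 5 replicates (it re-runs
the full selection ten times per replicate). Oracle cross-checks use
exhaustive enumeration for small discrete tables, 200 random genes for
discretization, and 50 random ≤ 8-sample problems for the QP comparison.
These sizes give stable means (SE of a 20-replicate accuracy mean ≈ 1
point) while keeping the whole validation run in a few minutes.

## Numerical choices and degenerate inputs

- Entropy terms use 0·log 0 := 0; information gain is clipped to 0 when
  rounding produces values above −1e−12 (larger negatives raise).
- MDLP candidate cuts are midpoints between adjacent distinct values whose
  label multisets differ; equal-gain candidate ties keep the leftmost cut.
- Ranking ties, RFE weight ties and survivor ordering all break by
  canonical (on-disk) gene order.
- Constant genes: z-score 0 and flagged; correlation 0; ReliefF weight 0.
- Classes smaller than the neighbour count (ReliefF) or fold count
  (cross-validation) reduce k with a warning rather than failing.
- Missing cells are rejected by default; per-gene mean imputation is
  opt-in (`impute_mean=True`), because silent imputation changes rankings.
- Class labels map lexicographically (smaller string → −1), and the
  mapping is logged and stored on the dataset.

## Known limitations

- The wrapper stage is O(n_filter) SVM fits per run with step 1; for
  n_filter ≫ 150 use a larger `step`.
- ReliefF computes the full m × m distance matrix; fine at microarray
  sample sizes, quadratic in m.
- Only binary phenotypes are supported, by design.
- ARFF support covers dense numeric attribute tables with a single nominal
  class attribute (the expression-table subset), not the full format.
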