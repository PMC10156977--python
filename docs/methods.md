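# Methods

## Co-occurrence counting

The counting rule fixes the GLCM offset to "immediately following base":
for a pattern set with pattern length m, position `i` (0-based,
`i ≤ L − m − 1`) contributes one count to cell (r, s) when the m-mer at `i`
equals row pattern r and the base at `i + m` equals column base s. The scan
is overlapping with step 1, which is the standard GLCM convention and the
only rule under which the single-base matrix I reduces to the adjacent-pair
table (`#(AC)` = A immediately followed by C) with grand total exactly
L − 1. Only this forward direction is counted; no symmetric (pattern
preceded by base) accumulation and no larger offsets are provided.

Sequences shorter than m + 1, and sequences in which no row pattern of a
set occurs, yield an all-zero matrix; its normalized form is all-zero and
all five texture features are defined as 0. This keeps every feature vector
total and exactly 40-dimensional regardless of input. The alternative
(NaN or an error) would propagate into the classifier for legitimate short
records.

The texture formulas sum over all cells of the q×4 matrix with 0-based
integer row and column indices in the (r − s) terms. For the 6×4 matrices
K and L the index difference simply runs over a wider range; a literal
square summation bound would be dimensionally inconsistent there. Entropy
uses the natural logarithm with 0·ln 0 ≡ 0. The within-matrix feature
order — energy, entropy, homogeneity, contrast, dissimilarity — is fixed
so that vectors are reproducible; nothing downstream depends on the order
beyond consistency.

## Classic estimators

**SE** is the two-symbol Shannon entropy of the purine/pyrimidine encoding,
in bits, so it lies in [0, 1] with maximum at balanced composition.

**MSE** is word-based entropy with base-2 logarithm. The word inventory has
two defensible readings and both are implemented:

- `window` (default): the word length is the longest run of identical
  bits ℓ*; the words are the overlapping ℓ*-windows of the sequence.
- `runs`: the words are the maximal runs themselves, keyed by
  (symbol, run length).

The chosen mode is recorded in CLI output; both modes give 0 exactly when
one word type occurs, and the window-mode value is bounded by ℓ* bits.

**HE** is the single-scale rescaled-range estimate solved at the full
length n: HE = log(Rₙ/Sₙ)/log(n/2), with Sₙ the population (divisor n)
standard deviation and Rₙ the range of the cumulative deviations from the
mean. No multi-window log-log regression is performed, and no Anis–Lloyd
small-sample correction is applied; on iid Bernoulli(1/2) noise the
estimator therefore sits above the asymptotic reference value 0.5 (about
0.55 at n = 65536 in the test suite's Monte-Carlo check). A constant
sequence has Sₙ = 0 and raises an error rather than returning a silent
number; `assemble_features` catches that error and imputes the column mean,
flagging the record in the log. Lengths below 3 are also errors: the
denominator log(n/2) vanishes at n = 2, so the single-scale formula is
undefined there.

**FD** is computed from the N×N indicator matrix (cell (i, j) = 1 iff
bases i and j are equal, N = min(length, cap)). σ(n) is defined here as the
exact mean 1-count over all (N − n + 1)² contiguous n×n submatrices,
evaluated with 2-D prefix sums in O(N²) per scale. This is the expectation
of sampling submatrices uniformly at random, so it replaces an unseeded
Monte-Carlo step with its deterministic limit; repeated calls are identical
to the bit. FD = −(1/N) Σₙ₌₂..N log σ(n)/log n, a ratio of logarithms and
hence base-free. The sign convention makes the value negative (σ(n) > 1 for
n ≥ 2 because the diagonal is all ones); the literal value is reported
because as a classifier feature the sign is immaterial. The `cap` knob
(default 1000) truncates long sequences before the O(N²) matrix is built;
it trades fidelity on long genes for bounded memory and is recorded in CLI
output.

## Classification protocol

The default protocol runs five repetitions of a stratified 50/50
train/test split and averages test-set metrics; a stratified five-fold CV
mode (`cv5`) is also provided. Within every split, the z-score scaler and
any PCA are fit on the training half only and applied to the held-out half;
zero-variance columns are guarded (mapped to exactly 0) so the
eigen-decomposition is well-posed. PCA retains the smallest number of
leading components whose cumulative explained-variance ratio reaches the
requested threshold, clipped to the rank of the standardized training
matrix. One master seed drives the splits and any classifier randomness and
is recorded in every report.

Classifier defaults — KNN with k = 5 and Euclidean distance, decision tree
with Gini impurity and unlimited depth, SVM with RBF kernel and C = 1 in
one-vs-rest mode — are this package's choices, made because the method
description leaves them open; all are standard scikit-learn estimators and
configurable.

Metrics are one-vs-rest per class on a single multiclass prediction,
weighted by class size nᵢ. The accuracy definition includes each class's
true negatives, so weighted accuracy is ≥ plain multiclass accuracy (a
property the tests check by brute force); weighted recall coincides with
plain accuracy. Precision for a class never predicted (TP + FP = 0) is
defined as 0, as is an F1 term with zero precision and recall. All metrics
are reported in percent.

## Synthetic benchmark

The generator samples each class from a Markov chain over {A, C, T, G}
(order 1 or 2), with lengths uniform on a per-class range and one
`id<TAB>label` sidecar TSV mirroring a per-class-file corpus. Markov chains
are the right generative family here because the co-occurrence features are
(m+1)-mer statistics with m ≤ 3: order-2 chains create signal those
features provably capture, while iid-uniform chains (the `null` preset) are
a near-null control.

The default benchmark has three balanced classes of 150 sequences, lengths
uniform on [300, 3000], built from order-2 transition matrices that mix a
uniform background (weight 0.45) with one of three structures (weight
0.55): extending the current base (homopolymer-rich), switching
purine/pyrimidine class every step, or continuing the ascending
A→C→T→G ladder. The mixing weight keeps every row well inside the
probability simplex while holding the pairwise row-averaged total-variation
distance between class transition matrices at or above 0.2. An imbalanced
variant (150/50/25) exercises the class-weighting path.

What passing the benchmark shows — and does not show: the features recover
*low-order transition structure*, which is the only signal the generator
emits. Real essential-gene sets differ additionally in length
distributions, GC content, codon structure and long-range correlations;
performance there is an empirical question the synthetic benchmark cannot
answer. The label-permutation control (weighted F1 at chance when labels
are shuffled) verifies that the pipeline has no leak between the feature
table and the evaluation split.

## Numerical choices and limitations

- Normalized matrices sum to 1 within 1e−12; degenerate (all-zero)
  matrices are the only exception and yield all-zero features.
- Ambiguous FASTA characters (N, IUPAC codes) are handled by policy:
  drop the record (default, logged), strip the characters, or error.
- Feature CSVs round-trip bit-exactly through pandas at full float
  precision; the column order (id, label, f1..f40[, SE, HE, MSE, FD]) is
  canonical.
- The problem sizes used by the test suite (200 random sequences for the
  counting oracle, indicator matrices up to N = 64 for the σ(n) oracle,
  200 × 65536 bits for the Hurst Monte-Carlo, the 450-sequence benchmark
  for recovery) were chosen to make each check sharp at desk scale.
- Known limitations: no FASTQ input, no multi-scale Hurst regression, no
  box-counting fractal dimension, no non-overlapping counting mode, no
  hyperparameter search, and no attempt to imitate real genome composition
  beyond low-order transitions.
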