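# genetexture

Fixed-length discriminant feature vectors for DNA sequences, built from
nucleotide co-occurrence matrices with texture statistics, plus classic
sequence-complexity estimators and a weighted-metric classification
protocol. The intended use case is classifying labeled sequence sets —
for example, essential-gene collections of different species — where each
class is one multi-FASTA file and sequences vary freely in length.

## The method

Every DNA sequence `S` over {A, C, G, T} is summarised by eight
co-occurrence matrices, the sequence analogue of a gray-level co-occurrence
matrix (GLCM) with a unit offset. A matrix is defined by a set of row
patterns (1-, 2- or 3-base strings) and the fixed column alphabet
(A, C, T, G); cell (r, s) counts the positions `i` where the pattern at `i`
equals row pattern `r` and the base at `i + m` (m = pattern length) equals
column base `s`, with overlapping occurrences all counted. The eight fixed
pattern sets are:

| Matrix | Row patterns |
|---|---|
| I | A, C, T, G |
| J | AA, CC, TT, GG |
| K | AC, AT, AG, CT, CG, TG |
| L | CA, TA, GA, TC, GC, GT |
| M | ACT, ACG, ATG, CTG |
| N | CAT, CAG, TAG, TCG |
| O | ATC, AGC, AGT, CGT |
| P | TCA, GCA, GTA, GTC |

Each matrix `G` is normalized to `G' = G / ΣG` and summarised by five
texture statistics over its cells (0-based indices r, s):

- energy `Σ G'(r,s)²`
- entropy `Σ −G'(r,s) ln G'(r,s)`
- homogeneity `Σ G'(r,s) / (1 + (r−s)²)`
- contrast `Σ G'(r,s) (r−s)²`
- dissimilarity `Σ G'(r,s) |r−s|`

Concatenating (energy, entropy, homogeneity, contrast, dissimilarity) over
I..P gives the 40-dimensional vector `f = (f1, …, f40)`.

Four classic single-number descriptors of the purine/pyrimidine encoding
(A,G → 1; C,T → 0) optionally extend the vector to 44 columns:

- **SE** — binary Shannon entropy `−Σ pᵢ log₂ pᵢ` ∈ [0, 1];
- **MSE** — word-based entropy `−Σ wⱼ log₂ wⱼ` over binary words (window or
  run inventory, see `docs/methods.md`);
- **HE** — single-scale rescaled-range Hurst exponent
  `log(Rₙ/Sₙ) / log(n/2)`;
- **FD** — indicator-matrix fractal dimension
  `−(1/N) Σₙ log σ(n) / log n`, where σ(n) is the mean 1-count over all
  n×n submatrices of the N×N base-identity dot-plot.

Classification uses KNN, decision-tree or RBF-SVM under five repeated
stratified 50/50 train/test splits (or stratified 5-fold CV), with optional
PCA reduction at a cumulative explained-variance threshold, and reports
class-size-weighted one-vs-rest accuracy, precision, recall and F1.

## Worked example

The bundled generator samples labeled classes from order-2 Markov chains
over {A, C, T, G}, so the whole pipeline runs without any external data:

```
$ genetexture synth --preset default --seed 1 --out-fasta synth.fa --out-labels synth.tsv
wrote synth.fa and synth.tsv

$ genetexture featurize --fasta synth.fa --labels synth.tsv --out features.csv
wrote features.csv: 450 sequences x 40 features (mse_mode=window, fd_cap=1000)

$ genetexture classify --features features.csv --model svm --seed 1 --report report.json
svm (repeated-split, seed=1): weighted accuracy 99.82%, precision 99.74%, recall 99.73%, F1 99.73%

$ genetexture classify --features features.csv --model svm --pca-variation 0.9 --seed 1 --report report_pca.json
svm (repeated-split, seed=1): weighted accuracy 99.94%, precision 99.91%, recall 99.91%, F1 99.91%
PCA variation 0.9 -> 6 components
```

The three synthetic classes differ only in their dinucleotide-conditioned
transition structure (homopolymer-rich, purine/pyrimidine-alternating, and
ascending-ladder chains); a weighted F1 near 100% shows the co-occurrence
features capture exactly that low-order structure. `report.json` holds the
full evaluation record: per-class confusion counts, the protocol, seed,
scaling and PCA settings. Real data works the same way — pass one
`--fasta` file per class (labels default to the file stem) or a single
FASTA with an `id<TAB>label` sidecar via `--labels`, and add `--classic`
for the 44-column variant.

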