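# Methods

`ribotex` classifies short RNA sequences (typically 20–25 nt miRNAs) by
species of origin.  It has two halves: a deterministic feature map that
turns a sequence over {A, C, G, U} into a fixed 43-value vector, and a
classification harness that trains and evaluates a roster of classical
ML and recurrent/convolutional DL models on tables of such vectors under
stratified K-fold protocols.  This note records the model, the defaults,
the numerical conventions, and the design choices that were genuinely
open.

## The composite feature map

### Co-occurrence texture block (f1–f40)

Eight fixed pattern sets over the RNA alphabet define eight co-occurrence
matrices (labelled I–P):

| set | patterns | shape |
|-----|----------|-------|
| X1 | A, C, U, G | 4×4 |
| X2 | AA, CC, UU, GG | 4×4 |
| X3 | AC, AU, AG, CU, CG, UG | 6×4 |
| X4 | CA, UA, GA, UC, GC, GU | 6×4 |
| X5 | ACU, ACG, AUG, CUG | 4×4 |
| X6 | CAU, CAG, UAG, UCG | 4×4 |
| X7 | AUC, AGC, AGU, CGU | 4×4 |
| X8 | UCA, GCA, GUA, GUC | 4×4 |

Entry (l, m) of a matrix counts how often pattern l occurs as a
contiguous, possibly overlapping substring that is followed — at a
configurable gap `offset`, default 1 meaning "immediately following" —
by base m (columns always ordered A, C, U, G).  Matching is exact and
ordered: X3 and X4 deliberately distinguish AC from CA.  Windows that
run past the sequence end contribute nothing, so short sequences give
legitimately all-zero matrices.

Each matrix is normalized to unit sum and summarized by the five
classical gray-level co-occurrence statistics, computed with 0-based
integer row/column indices l, m and natural log for the entropy
(0·ln 0 := 0):

- energy = Σ p(l,m)²
- entropy = −Σ p(l,m) ln p(l,m)
- homogeneity = Σ p(l,m) / (1 + (l−m)²)
- contrast = Σ p(l,m) (l−m)²
- dissimilarity = Σ p(l,m) |l−m|

The 40-value block lists matrices I…P in order, five statistics each, in
the fixed intra-matrix order (energy, entropy, homogeneity, contrast,
dissimilarity); the order is part of the contract so that feature
numbers f1…f40 are reproducible.  A zero-total matrix contributes five
zeros and a warning rather than an error, keeping the vector length
fixed for degenerate inputs.

The co-occurrence stage operates on the 4-letter sequence (the pattern
sets are written over four letters), not on the purine/pyrimidine
encoding; the binary encoding feeds only the entropy and Hurst features
below.  The gap between a pattern and its paired base is nowhere forced
by the construction; adjacent pairing (offset 1) is the default as the
natural sequence analogue of adjacent-pixel texture matrices, and the
offset is exposed as a parameter.

### Shannon entropy (SE)

The purine/pyrimidine encoding maps A/G→1 and C/U→0.  SE is the entropy
in bits of the empirical bit proportions, −Σᵢ pᵢ log₂ pᵢ with
0·log₂ 0 := 0; it is 0 for a constant bit string and 1 at p = 1/2.
Note the deliberate asymmetry of logarithm bases: SE uses log₂ (so the
range is [0, 1] bits) while the texture entropy uses ln.

### Hurst exponent (HE)

A single-scale rescaled-range statistic of the bit string D₁…Dₙ:
with μ the bit mean, Yₜ = Σᵢ≤ₜ (Dᵢ−μ) the cumulative deviations,
Φ = max Y − min Y the range and V the *population* standard deviation
(1/n inside the root),

    HE = log(Φ/V) / log(n/2).

The ratio of logs makes the base irrelevant.  The estimator is
single-scale by design (no windowed regression over multiple scales),
so it is biased relative to the asymptotic Hurst exponent of long
series: on i.i.d. Bernoulli(1/2) strings of n = 4096 its empirical mean
is ≈ 0.57 ± 0.03 rather than 0.5 (measured over 200 seeded draws; the
test suite asserts only that the mean lies strictly inside (0, 1)).  It is
used here as a bounded autocorrelation descriptor, not as a calibrated
estimate.  For constant bits V = 0 and HE is undefined; in
feature-vector context the configurable fill value (default 0.5, the
uncorrelated-series reference point) is substituted with a warning.
Minimum length is 3.

### Fractal dimension (FD)

The sequence's N×N indicator matrix has a 1 wherever symbols i and j
are equal (symmetric, unit diagonal).  For each window size k = 2…N a
one-density σ(k) is measured on k×k submatrices and

    FD = −(1/N) Σₖ log σ(k) / log k.

The published description of how σ(k) is sampled is ambiguous, so two
modes are provided: the default deterministic mode takes the leading
principal k×k submatrix (bit-reproducible, O(N²) via a 2-D cumulative
sum), and a seeded stochastic mode averages the density over r random
contiguous k×k minors, matching the "randomly selected" wording.  Under
this formula a constant sequence (saturated matrix, σ ≡ 1) has FD
exactly 0 — unusual for something called a dimension, but it is
implemented exactly as defined; FD depends only on the equality pattern
and is invariant under any relabeling of the alphabet.

### Assembly

The composite vector is f1…f40 followed by SE, HE, FD — 43 values, all
finite after the fill policies.  No truncation of the input sequence is
performed anywhere: every feature above is defined for arbitrary length,
so the map is length-invariant by construction.

## Dataset assembly and quality control

From a labeled feature table with k species the harness builds k·(k−1)/2
pairwise binary datasets (label 0/1 by alphabetical order within the
pair) and k one-vs-all datasets (target species = 1, rest = 0) —
one-vs-all problems are materialized as binary, so all downstream
metrics are binary.  Species label encoding is alphabetical (0…k−1).

Missing feature cells are filled by column-wise linear interpolation in
row order (boundary gaps copy the nearest value).  Class imbalance is
corrected by ADASYN, implemented in-package: each minority row receives
a synthesis budget proportional to the majority fraction among its
k = 5 nearest neighbours in the full dataset, and synthetic rows are
drawn uniformly on segments between the row and one of its k nearest
minority neighbours; the output ratio lands within 10% of balance, is
deterministic given the seed, and synthetic rows are flagged in the
per-row provenance.  Features are min–max scaled column-wise to [0, 1];
constant columns map to 0, and applied values outside the fitted bounds
extrapolate rather than clip.

In cross-validation the default route is leakage-free: scaler bounds
and ADASYN synthesis derive from the training fold only, so synthetic
provenance flags never appear in test folds.  Because published
pipelines of this kind are frequently ambiguous about the ordering of
balancing and splitting, a `corpus_wide_prep` flag reproduces the other
reading: scaling and balancing applied to the whole dataset before
splitting (synthetic rows then reach test folds).

## The model roster

Ten solo ML classifiers (LR, linear SVM, DT, RF, ET, XGBoost, KNN, LDA,
LGBM, GaussianNB) back five voting ensembles: EML1 = LR+SVM,
EML2 = DT+KNN, EML3 = DT+RF, EML4 = RF+DT+ET, EML5 = ET+XGBoost+LGBM.
Voting is soft — the ensemble probability is the arithmetic mean of
constituent probabilities — because AUCs are reported for the ensembles,
which requires continuous scores.  The linear SVM participates via its
decision score min–max normalized over the training scores (clipped at
prediction time), preserving its ranking.  The headline count of 38
models assumes nine solo-ML entries; all ten named classifiers are
implemented, so the full roster has 39 specifications.

The DL side runs on an in-package numpy network engine (reverse-mode
autodiff plus RNN/GRU/LSTM cells, bidirectional wrappers, 1-D
convolution, max pooling, dropout, dense layers, Adam), validated
against central finite differences in the test suite.  A feature vector
is presented to the network as a 43-step univariate sequence so
recurrent and convolutional stages scan the feature axis.

- 6 solo DL: GRU, BiGRU, RNN, BiRNN, LSTM, BiLSTM — one recurrent block,
  dropout, softmax head.
- 12 hybrid DL: two stacked blocks (LSTM-GRU, BiLSTM-BiGRU, …), the
  CNN-terminated variants replacing the second recurrent block's pooling
  with Conv1D → MaxPool → Flatten; HDL12 stacks LSTM-GRU-CNN.
- 6 ensemble DL: two hybrid branches, each truncated at its dropout
  layer, concatenated, then a dense stage (64 units, rectifier) and a
  softmax output.  EDL1 = BiLSTM-BiGRU ⊕ LSTM-GRU, EDL2 = BiLSTM-BiGRU ⊕
  BiRNN-RNN, EDL3 = BiGRU-GRU ⊕ LSTM-CNN, EDL4 = BiRNN-CNN ⊕ GRU-CNN,
  EDL5 = BiLSTM-LSTM ⊕ RNN-CNN, EDL6 = BiLSTM-CNN ⊕ BiGRU-CNN.  EDL3/4/5/6
  contain convolutional stages; EDL1/2 do not.

Training minimizes mean categorical cross-entropy with Adam.  Library
defaults: recurrent width 64, conv 32 filters / kernel 3 / pool 2,
dropout 0.2, dense 64, batch size 64, learning rate 1e-3, 50 epochs —
all overridable per spec or per training config.  ML training is
bit-reproducible given the seed; DL training is reproducible within the
determinism of the numpy engine (exact in practice, since no threading
nondeterminism is involved).

## Evaluation

Binary confusion counts (class 1 positive) give accuracy
η = (TP+TN)/total, recall R = TP/(TP+FN), precision P = TP/(TP+FP), and
F1 = 2PR/(P+R); zero denominators yield 0 with a warning.  AUC is the
trapezoidal area under the ROC curve (equivalently the normalized
Mann–Whitney U; the equivalence is asserted over seeded random
instances).  Cross-validation uses stratified shuffled K-fold with
K ∈ {2, 4, 5, 10} (train fraction (K−1)/K).

Aggregation averages per-fold records into (model, dataset) cells, then
produces per-model means over datasets, per-dataset means over models,
and the grand system mean; an incomplete grid is an error naming the
missing cells.  Family comparison rows report |mean(B) − mean(A)|
computed on means rounded to the report precision first — 2 decimals
for percentages, 4 for AUC (differences ×100) — matching the
round-then-difference convention of the printed comparison tables this
layout mirrors.

Reliability tests: one-way ANOVA across models' per-fold accuracies
(significance threshold p < 0.01), a per-model two-tailed Z of its mean
accuracy against the pooled mean (pooled-mean comparison; the
alternative paired reading of the published description is not
implemented), and adjusted R² of predicted positive-class probabilities
against the 0/1 labels.  Feature importance ships as seeded permutation
importance (mean held-out accuracy drop per shuffled column); a SHAP
explainer is deliberately not bundled.

## Synthetic corpora

Each species profile is a first-order Markov chain over (A, C, U, G):
the transition matrix interpolates between a shared mildly non-uniform
baseline and a species-specific matrix with Dirichlet(0.35) rows, with
a separation knob in [0, 1] (0: identical chains, no class signal; 1:
fully species-specific).  Lengths are uniform in 20–25 nt by default;
default class counts mirror a real four-species miRNA repository's
imbalance (≈ 2654 : 369 : 1978 : 764, scaled), so the oversampling path
is exercised.  First-order structure is chosen because the
co-occurrence features are adjacency statistics — the planted signal is
guaranteed to be expressible by the feature map.  The generator does
not emulate hairpin/secondary structure, positional composition bias,
or cross-species sequence homology, so passing recovery tests shows the
pipeline carries first-order compositional signal; it says nothing
about performance on real repository data.

## Desk-scale test profile

The correctness-oriented test runs use a reduced profile chosen once:
16 recurrent units, 8 conv filters, batch size 32, learning rate 0.01,
20 training epochs, corpora of 150 sequences per class at separation
0.7, K5 protocol, three seeds.  Under this profile the voting ensemble
EML4 recovers the planted signal at ≈ 0.88 mean accuracy across the six
pairwise datasets, and the convolutional two-branch ensemble (EDL6)
matches or beats a solo BiLSTM; at separation 0 every smoke-tested
model's mean AUC stays at chance level.  These numbers are recomputed by
the test suite on every run, not asserted as constants.

## Known limitations

- The single-scale Hurst estimator is biased; treat HE as a descriptor.
- FD's deterministic mode depends on the leading-minor convention; the
  stochastic mode's value depends on the minor-sampling seed.
- ADASYN's brute-force k-NN is O(n²) in dataset size — fine at the
  corpus sizes targeted here, not tuned for very large tables.
- The numpy DL engine is single-threaded and CPU-bound; it is built for
  correctness and reproducibility at desk scale, not for large corpora.
- Fitted DL models are not serialized; retrain from seeds (ML models
  pickle normally).
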