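# ribotex

Composite texture/complexity features for short RNA sequences and an
ensemble ML/DL harness for classifying them by species of origin.

Short non-coding RNAs such as miRNAs (~20–25 nt) carry species-specific
compositional structure, but they are too short for alignment-heavy
approaches and too nonlinear for plain k-mer counts.  `ribotex`
addresses this by mapping each sequence over {A, C, G, U} to a fixed
**43-value composite feature vector** and training a roster of
classical and deep classifiers on the resulting tables.  It is aimed at
researchers who want a reproducible, CPU-friendly pipeline from FASTA
to cross-validated species-classification reports.

## The feature map

For a sequence S of length n:

- **f1–f40 — co-occurrence texture block.**  Eight fixed pattern sets
  (the four bases; the four homodimers; six ordered heterodimers and
  their six reversals; four families of ordered trimers) each define a
  q×4 co-occurrence matrix: entry (l, m) counts occurrences of pattern
  l followed, at a configurable offset (default: immediately), by base
  m.  Each unit-normalized matrix XC′ is summarized by the five
  classical texture statistics, with 0-based indices l, m:

      energy        Σ XC′(l,m)²
      entropy       −Σ XC′(l,m) ln XC′(l,m)
      homogeneity   Σ XC′(l,m) / (1 + (l−m)²)
      contrast      Σ XC′(l,m) (l−m)²
      dissimilarity Σ XC′(l,m) |l−m|

- **SE — Shannon entropy** (bits) of the purine/pyrimidine encoding
  (A/G→1, C/U→0): SE = −Σ pᵢ log₂ pᵢ ∈ [0, 1].
- **HE — Hurst exponent**, the single-scale rescaled-range statistic
  HE = log(Φ/V) / log(n/2), where Φ is the range of the cumulative
  bit deviations and V their population standard deviation.
- **FD — fractal dimension** of the N×N indicator (self-equality)
  matrix: FD = −(1/N) Σₖ₌₂..ₙ log σ(k)/log k with σ(k) the one-density
  of k×k submatrices.

The harness builds all pairwise and one-vs-all binary datasets from a
labeled corpus, interpolates missing cells, balances classes with
ADASYN, min–max scales inside each training fold, and evaluates a
39-model roster (10 solo ML, 5 soft-voting ML ensembles, 6 solo, 12
hybrid and 6 two-branch ensemble recurrent/convolutional networks)
under stratified K-fold protocols with accuracy/recall/precision/F1/AUC
reporting, family comparison tables, reliability tests and permutation
feature importance.  See `docs/methods.md` for the full model and the
numerical conventions.

## Worked example

Featurize one sequence from the library:

```python
from ribotex import extract_composite_vector, encode_binary, COMPOSITE_NAMES
from ribotex.sequence_io import make_record

s = make_record("hsa-example", "Human", "UGAGGUAGUAGGUUGUAUAGUU")
v = extract_composite_vector(s)
print("".join(map(str, encode_binary(s).bits.tolist())))
for name in ("f1", "f2", "f3", "f4", "f5", "SE", "HE", "FD"):
    print(name, "=", round(v.values[COMPOSITE_NAMES.index(name)], 4))
```

prints

```
0111101101110010101100
f1 = 0.161
f2 = 1.9352
f3 = 0.4286
f4 = 3.4286
f5 = 1.5238
SE = 0.976
HE = 0.6782
FD = 0.4627
```

f1–f5 are the energy/entropy/homogeneity/contrast/dissimilarity of the
base-pair co-occurrence matrix (energy 0.16 and entropy 1.94: adjacent
base pairs are spread over many cells); SE ≈ 0.98 says purines and
pyrimidines are nearly balanced; HE ≈ 0.68 indicates positively
autocorrelated bit runs; FD ≈ 0.46 summarizes the repeat structure of
the self-equality matrix.

End-to-end from the shell — generate a seeded synthetic four-species
corpus, extract features, and cross-validate the strongest voting
ensemble (RF+DT+ET):

```sh
ribotex synth --species 4 --separation 0.7 --total 120 --seed 7 --out demo.fa
ribotex features demo.fa --out demo.tsv
ribotex evaluate demo.tsv --model EML4 --protocol 5 --seed 7
```

```
                    eta  alpha      R      P      F
dataset
Gorilla_vs_All   0.9917 0.9909 0.9000 1.0000 0.9333
Gorilla_vs_Human 0.9846 1.0000 1.0000 0.9833 0.9913
Gorilla_vs_Mouse 0.9800 0.9875 1.0000 0.9778 0.9882
Gorilla_vs_Rat   0.8700 0.9333 0.8667 0.9333 0.8933
Human_vs_All     0.8583 0.9490 0.8727 0.8456 0.8510
Human_vs_Mouse   0.8442 0.9371 0.8278 0.8189 0.8197
Human_vs_Rat     0.9162 0.9621 0.8000 0.8833 0.8114
Mouse_vs_All     0.8083 0.8939 0.7056 0.7325 0.7174
Mouse_vs_Rat     0.7561 0.8428 0.6833 0.5500 0.5990
Rat_vs_All       0.8917 0.9022 0.6333 0.6333 0.6076
mean accuracy 0.8901  mean AUC 0.9399
```

Each row is one of the ten datasets built from the corpus (six species
pairs, four one-vs-all); `eta` is K5 cross-validated accuracy and
`alpha` the AUC, averaged over folds.  The planted first-order
compositional signal is recovered well for the well-sampled pairs and
degrades for the rarest class (Gorilla) only where the comparison is
hard (vs. Rat).  `ribotex experiment --id 1..4` runs the canned family
comparisons (solo vs hybrid vs ensemble DL, CNN vs non-CNN ensembles,
solo vs ensemble ML, ensemble ML vs ensemble DL) and prints the
per-dataset family table.

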