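"""Sequence co-occurrence matrices and their texture statistics.

Eight fixed pattern sets (1-, 2- and 3-mers over A, C, U, G) each define a
q x 4 co-occurrence matrix: entry (l, m) counts how often pattern l occurs
in the sequence immediately followed -- at a configurable offset -- by base
m.  Each normalized matrix is summarized by five texture statistics
(energy, entropy, homogeneity, contrast, dissimilarity), the classical
gray-level co-occurrence statistics transplanted from image texture
analysis onto the 1-D symbol stream.  The eight matrices x five statistics
yield the 40-value block f1..f40 of the composite feature vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sequence_io import ALPHABET, NucleotideSequence

COLUMN_SYMBOLS = ("A", "C", "U", "G")

_PATTERN_TABLE = [
    ("X1", "I", ("A", "C", "U", "G")),
    ("X2", "J", ("AA", "CC", "UU", "GG")),
    ("X3", "K", ("AC", "AU", "AG", "CU", "CG", "UG")),
    ("X4", "L", ("CA", "UA", "GA", "UC", "GC", "GU")),
    ("X5", "M", ("ACU", "ACG", "AUG", "CUG")),
    ("X6", "N", ("CAU", "CAG", "UAG", "UCG")),
    ("X7", "O", ("AUC", "AGC", "AGU", "CGU")),
    ("X8", "P", ("UCA", "GCA", "GUA", "GUC")),
]

#: intra-matrix statistic order; part of the f1..f40 layout contract
TEXTURE_ORDER = ("energy", "entropy", "homogeneity", "contrast", "dissimilarity")

FEATURE_NAMES: tuple[str, ...] = tuple(f"f{i}" for i in range(1, 41))


@dataclass(frozen=True)
class PatternSet:
    name: str
    matrix_label: str
    patterns: tuple[str, ...]
    column_symbols: tuple[str, ...] = COLUMN_SYMBOLS

    @property
    def q(self) -> int:
        return len(self.patterns)

    @property
    def k(self) -> int:
        """Pattern length (uniform within a set)."""
        return len(self.patterns[0])


@dataclass
class CooccurrenceMatrix:
    pattern_set: PatternSet
    counts: np.ndarray
    offset: int
    normalized: np.ndarray | None = None
    zero_total: bool = False

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TextureFeatures:
    energy: float
    entropy: float
    homogeneity: float
    contrast: float
    dissimilarity: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.energy, self.entropy, self.homogeneity,
                self.contrast, self.dissimilarity)


def pattern_sets() -> list[PatternSet]:
    """The eight fixed pattern sets, in matrix order I..P."""
    return [PatternSet(name, label, patterns) for name, label, patterns in _PATTERN_TABLE]


def count_cooccurrence(
    seq: NucleotideSequence, ps: PatternSet, offset: int = 1
) -> CooccurrenceMatrix:
    """Count (pattern, following base) co-occurrences in a sequence.

    ``counts[l, m]`` is the number of start positions i such that the
    contiguous k-mer at i equals ``ps.patterns[l]`` and the base ``offset``
    positions past the pattern's end equals ``column_symbols[m]``.
    Occurrences may overlap; windows running past the end contribute
    nothing, so short sequences legitimately give all-zero counts.
    """
    if offset < 1:
        raise ValueError("offset must be >= 1")
    k = ps.k
    s = seq.symbols
    n = len(s)
    row = {p: i for i, p in enumerate(ps.patterns)}
    col = {c: j for j, c in enumerate(ps.column_symbols)}
    counts = np.zeros((ps.q, 4), dtype=np.int64)
    # anchor i is 0-based here; paired base sits at i + k + offset - 1
    for i in range(n - k - offset + 1):
        l = row.get(s[i:i + k])
        if l is not None:
            counts[l, col[s[i + k + offset - 1]]] += 1
    return CooccurrenceMatrix(pattern_set=ps, counts=counts, offset=offset)


def normalize(cm: CooccurrenceMatrix) -> CooccurrenceMatrix:
    """Divide counts by their total so entries sum to 1 (all-zero kept as-is)."""
    total = cm.counts.sum()
    if total == 0:
        cm.normalized = np.zeros_like(cm.counts, dtype=float)
        cm.zero_total = True
    else:
        cm.normalized = cm.counts / total
        cm.zero_total = False
    return cm


def texture_features(cm: CooccurrenceMatrix) -> TextureFeatures:
    """Energy, entropy (natural log), homogeneity, contrast, dissimilarity.

    Indices l (row) and m (column) are 0-based; 0*ln(0) is taken as 0.  A
    zero-total matrix yields all five statistics equal to 0.
    """
    if cm.normalized is None:
        raise ValueError("matrix must be normalized first")
    p = cm.normalized
    if cm.zero_total:
        return TextureFeatures(0.0, 0.0, 0.0, 0.0, 0.0)
    l_idx, m_idx = np.indices(p.shape)
    diff = l_idx - m_idx
    nz = p > 0
    energy = float(np.sum(p * p))
    entropy = float(-np.sum(p[nz] * np.log(p[nz])))
    homogeneity = float(np.sum(p / (1.0 + diff**2)))
    contrast = float(np.sum(p * diff**2))
    dissimilarity = float(np.sum(p * np.abs(diff)))
    return TextureFeatures(energy, entropy, homogeneity, contrast, dissimilarity)


def extract_cooccurrence_features(
    seq: NucleotideSequence, offset: int = 1, warn_zero_total: bool = True
) -> np.ndarray:
    """The ordered f1..f40 vector: matrices I..P, five statistics each."""
    values: list[float] = []
    for ps in pattern_sets():
        cm = normalize(count_cooccurrence(seq, ps, offset=offset))
        if cm.zero_total and warn_zero_total:
            warnings.warn(
                f"sequence {seq.id!r}: zero-total co-occurrence matrix "
                f"{ps.matrix_label}; its texture features are 0"
            )
        values.extend(texture_features(cm).as_tuple())
    return np.asarray(values, dtype=float)
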