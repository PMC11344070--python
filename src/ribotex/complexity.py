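"""Complexity descriptors of a sequence: Shannon entropy, Hurst exponent,
indicator-matrix fractal dimension, and the assembled 43-value composite
feature vector.

Shannon entropy and the Hurst exponent are computed on the
purine/pyrimidine bit string; the fractal dimension is computed on the
4-symbol sequence through its N x N self-equality (indicator) matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cooccurrence import FEATURE_NAMES, extract_cooccurrence_features
from .sequence_io import BinarySequence, NucleotideSequence, encode_binary

#: column layout of the composite vector
COMPOSITE_NAMES: tuple[str, ...] = FEATURE_NAMES + ("SE", "HE", "FD")

#: fill value used when the Hurst exponent is undefined (constant bits);
#: 0.5 is the uncorrelated-series reference point
HURST_FILL = 0.5


@dataclass
class CompositeFeatureVector:
    values: np.ndarray  # length 43, order COMPOSITE_NAMES
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(COMPOSITE_NAMES),):
            raise ValueError(f"composite vector must have {len(COMPOSITE_NAMES)} values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("composite vector contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


def shannon_entropy(b: BinarySequence) -> float:
    """Entropy (bits) of the empirical 0/1 proportions; 0*log2(0) := 0.

    0 for a constant bit string, 1 when zeros and ones are equally frequent.
    """
    bits = np.asarray(b.bits)
    if bits.size == 0:
        raise ValueError("empty sequence")
    p1 = bits.mean()
    se = 0.0
    for p in (p1, 1.0 - p1):
        if p > 0:
            se -= p * math.log2(p)
    return se


def hurst_intermediates(b: BinarySequence) -> dict[str, np.ndarray | float]:
    """Mean, cumulative deviations, range and population std of the bits."""
    d = np.asarray(b.bits, dtype=float)
    mu = d.mean()
    y = np.cumsum(d - mu)
    phi = float(y.max() - y.min())
    v = float(np.sqrt(np.mean((d - mu) ** 2)))  # population form
    return {"mu": float(mu), "Y": y, "Phi": phi, "V": v}


def hurst_exponent(b: BinarySequence, fill: float | None = None) -> float:
    """Single-scale rescaled-range exponent: log(Phi/V) / log(n/2).

    Phi is the range of the cumulative deviations of the bits from their
    mean and V their population standard deviation.  For constant bits the
    ratio is undefined (V = 0): with ``fill`` given that value is returned
    with a warning, otherwise a ValueError is raised.
    """
    n = len(b.bits)
    if n < 3:
        raise ValueError("Hurst exponent requires length >= 3")
    inter = hurst_intermediates(b)
    if inter["V"] == 0.0:
        if fill is None:
            raise ValueError("Hurst exponent undefined for a constant bit sequence")
        warnings.warn(f"constant bit sequence {b.source_id!r}: HE set to fill {fill}")
        return fill
    return math.log(inter["Phi"] / inter["V"]) / math.log(n / 2.0)


def indicator_matrix(seq: NucleotideSequence) -> np.ndarray:
    """N x N self-equality grid: 1 where symbols i and j match."""
    s = np.frombuffer(seq.symbols.encode(), dtype="S1")
    return (s[:, None] == s[None, :]).astype(np.int8)


def fractal_dimension(
    seq: NucleotideSequence,
    mode: str = "leading",
    n_minors: int = 10,
    seed: int | None = None,
) -> float:
    """Indicator-matrix fractal dimension.

    For each window size k = 2..N a one-density sigma(k) is measured on
    k x k submatrices of the indicator matrix and the dimension is
    ``-(1/N) * sum(log(sigma(k)) / log(k))``.  The default ``leading`` mode
    uses the leading principal submatrix (bit-reproducible); ``random``
    mode averages the density over ``n_minors`` seeded random contiguous
    minors.  A saturated (constant-sequence) matrix gives exactly 0.
    """
    n = len(seq)
    if n < 2:
        raise ValueError("fractal dimension requires length >= 2")
    grid = indicator_matrix(seq)
    if mode == "random":
        rng = np.random.default_rng(seed)
    elif mode != "leading":
        raise ValueError(f"unknown mode {mode!r}")
    acc = 0.0
    # cumulative 2-D sum makes each leading-minor density O(1)
    csum = grid.cumsum(axis=0).cumsum(axis=1)
    for k in range(2, n + 1):
        if mode == "leading":
            sigma = csum[k - 1, k - 1] / (k * k)
        else:
            dens = []
            for _ in range(n_minors):
                i = rng.integers(0, n - k + 1)
                j = rng.integers(0, n - k + 1)
                dens.append(grid[i:i + k, j:j + k].mean())
            sigma = float(np.mean(dens))
        # sigma >= k/k^2 > 0 always: the diagonal of any principal minor is 1;
        # random contiguous minors still contain at least one matching pair
        # only when they straddle the diagonal -- guard anyway
        if sigma <= 0:
            continue
        acc += math.log(sigma) / math.log(k)
    return -acc / n


def extract_composite_vector(
    seq: NucleotideSequence,
    offset: int = 1,
    hurst_fill: float = HURST_FILL,
    fd_mode: str = "leading",
    seed: int | None = None,
) -> CompositeFeatureVector:
    """Assemble f1..f40 followed by SE, HE, FD (43 values, all finite)."""
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        f40 = extract_cooccurrence_features(seq, offset=offset)
        b = encode_binary(seq)
        se = shannon_entropy(b)
        he = hurst_exponent(b, fill=hurst_fill)
        fd = fractal_dimension(seq, mode=fd_mode, seed=seed)
    for w in caught:
        flags.append(str(w.message))
    values = np.concatenate([f40, [se, he, fd]])
    return CompositeFeatureVector(values=values, flags=tuple(flags))


def featurize_corpus(records, offset: int = 1, **kwargs):
    """Composite vectors for a list of records -> (ids, labels, matrix)."""
    ids = [r.id for r in records]
    labels = [r.species_label for r in records]
    mat = np.vstack([extract_composite_vector(r, offset=offset, **kwargs).values
                     for r in records])
    return ids, labels, mat
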