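"""Assembly of binary classification datasets from a labeled feature table.

From a multi-species corpus the harness builds the pairwise datasets (one
per unordered species pair) and the one-vs-all datasets (target species
against everything else, materialized as a binary problem).  Quality
control mirrors a standard tabular pipeline: linear interpolation of
missing feature cells, ADASYN oversampling of the minority class, and
min-max scaling with bounds fitted on training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class SpeciesDataset:
    name: str
    features: np.ndarray          # (n_samples, n_features)
    labels: np.ndarray            # values in {0, 1}
    task: str                     # "pairwise" | "one_vs_all"
    class_names: tuple[str, str]  # (negative, positive)
    provenance: np.ndarray        # per-row source ids; synthetic rows flagged
    balanced: bool = False

    def __post_init__(self) -> None:
        n = len(self.features)
        if not (len(self.labels) == len(self.provenance) == n):
            raise ValueError("features, labels and provenance must align")

    @property
    def n_samples(self) -> int:
        return len(self.labels)


def label_encode(species_names: Sequence[str]) -> dict[str, int]:
    """Stable alphabetical encoding of species names to 0..k-1."""
    return {name: i for i, name in enumerate(sorted(set(species_names)))}


def _corpus_arrays(corpus: pd.DataFrame):
    feats = corpus.drop(columns=["id", "label"]).to_numpy(dtype=float)
    labels = corpus["label"].to_numpy()
    ids = corpus["id"].to_numpy()
    return feats, labels, ids


def build_pairwise(corpus: pd.DataFrame, a: str, b: str) -> SpeciesDataset:
    """Rows of species a and b only; label 0 for a, 1 for b."""
    if a == b:
        raise ValueError("pairwise dataset needs two distinct species")
    feats, labels, ids = _corpus_arrays(corpus)
    for sp in (a, b):
        if not np.any(labels == sp):
            raise ValueError(f"species {sp!r} absent from corpus")
    mask = (labels == a) | (labels == b)
    return SpeciesDataset(
        name=f"{a}_vs_{b}",
        features=feats[mask],
        labels=(labels[mask] == b).astype(int),
        task="pairwise",
        class_names=(a, b),
        provenance=ids[mask].astype(object),
    )


def build_one_vs_all(corpus: pd.DataFrame, target: str) -> SpeciesDataset:
    """All corpus rows; label 1 for the target species, 0 for the rest."""
    feats, labels, ids = _corpus_arrays(corpus)
    if not np.any(labels == target):
        raise ValueError(f"species {target!r} absent from corpus")
    if np.all(labels == target):
        raise ValueError("one-vs-all needs at least one other species")
    return SpeciesDataset(
        name=f"{target}_vs_All",
        features=feats.copy(),
        labels=(labels == target).astype(int),
        task="one_vs_all",
        class_names=("All", target),
        provenance=ids.astype(object),
    )


def build_all_datasets(corpus: pd.DataFrame) -> list[SpeciesDataset]:
    """The standard grid: C(k,2) pairwise + k one-vs-all datasets."""
    species = sorted(corpus["label"].unique())
    out = [build_pairwise(corpus, a, b) for a, b in combinations(species, 2)]
    out += [build_one_vs_all(corpus, sp) for sp in species]
    return out


def interpolate_missing(features: np.ndarray) -> np.ndarray:
    """Column-wise linear interpolation of NaN cells in row order.

    Interior gaps take the straight line between the nearest non-missing
    neighbors; boundary gaps copy the nearest non-missing value.  A column
    with fewer than one non-missing value is an error.
    """
    df = pd.DataFrame(np.asarray(features, dtype=float))
    if df.isna().all().any():
        bad = list(df.columns[df.isna().all()])
        raise ValueError(f"columns {bad} are entirely missing")
    out = df.interpolate(method="linear", limit_direction="both", axis=0)
    return out.to_numpy()


def balance_adasyn(
    ds: SpeciesDataset, seed: int, k: int = 5, tol: float = 0.1
) -> SpeciesDataset:
    """Adaptive synthetic oversampling of the minority class.

    Each minority row x_i gets a synthesis budget proportional to the
    fraction of majority rows among its k nearest neighbors (rows that are
    harder to learn get more synthetic mass); synthetic rows are drawn
    uniformly on segments between x_i and one of its k nearest *minority*
    neighbors.  Already-balanced input (ratio within ``tol``) is returned
    unchanged.  Deterministic given ``seed``.
    """
    classes, counts = np.unique(ds.labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("ADASYN balancing expects exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min / n_maj >= 1.0 - tol:
        return ds
    if n_min <= k:
        raise ValueError(
            f"minority class has {n_min} rows; needs more than k={k} "
            f"neighbors -- use a smaller k"
        )
    rng = np.random.default_rng(seed)
    X, y = ds.features, ds.labels
    X_min = X[y == minority]
    min_prov = ds.provenance[y == minority]

    def knn_idx(query, pool, kk):
        # brute-force Euclidean k-NN excluding self-matches by distance rank
        d2 = ((query[:, None, :] - pool[None, :, :]) ** 2).sum(axis=2)
        return np.argsort(d2, axis=1, kind="stable")[:, 1:kk + 1]

    # hardness ratio r_i: majority fraction among k nearest corpus neighbors
    nbr_all = knn_idx(X_min, X, k)
    r = (y[nbr_all] != minority).mean(axis=1)
    if r.sum() == 0:
        r = np.ones_like(r)  # fully interior minority: spread budget evenly
    r_hat = r / r.sum()
    g_total = n_maj - n_min
    g = np.floor(r_hat * g_total).astype(int)
    # distribute the rounding remainder to the hardest rows
    short = g_total - g.sum()
    if short > 0:
        g[np.argsort(-r_hat, kind="stable")[:short]] += 1

    nbr_min = knn_idx(X_min, X_min, k)
    new_rows, new_prov = [], []
    for i, gi in enumerate(g):
        for _ in range(gi):
            z = nbr_min[i, rng.integers(0, nbr_min.shape[1])]
            lam = rng.random()
            new_rows.append(X_min[i] + lam * (X_min[z] - X_min[i]))
            new_prov.append(f"synthetic:{min_prov[i]}")
    if new_rows:
        X_out = np.vstack([X, np.asarray(new_rows)])
        y_out = np.concatenate([y, np.full(len(new_rows), minority, dtype=y.dtype)])
        prov_out = np.concatenate([ds.provenance, np.asarray(new_prov, dtype=object)])
    else:
        X_out, y_out, prov_out = X, y, ds.provenance
    return replace(ds, features=X_out, labels=y_out, provenance=prov_out,
                   balanced=True)


@dataclass
class MinMaxScaler:
    """Column-wise (x - min) / (max - min) with bounds from the fit matrix.

    Constant columns map to 0; applied values outside the fitted bounds
    extrapolate beyond [0, 1] rather than being clipped.
    """

    mins: np.ndarray | None = None
    ranges: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("cannot fit scaler on an empty matrix")
        self.mins = X.min(axis=0)
        rng = X.max(axis=0) - self.mins
        rng[rng == 0] = 1.0  # constant column -> all zeros after shift
        self.ranges = rng
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mins is None:
            raise ValueError("scaler is not fitted")
        return (np.asarray(X, dtype=float) - self.mins) / self.ranges


def minmax_scale(fit_on: np.ndarray, apply_to: np.ndarray):
    """Convenience wrapper: returns (scaled apply_to, fitted scaler)."""
    scaler = MinMaxScaler().fit(fit_on)
    return scaler.transform(apply_to), scaler
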