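"""Seeded synthetic multi-species sequence corpora.

Each species is a first-order Markov chain over (A, C, U, G) whose
transition matrix interpolates between a shared baseline (separation 0:
all species identical, no class signal) and a species-specific random
stochastic matrix (separation 1: maximally distinct for the
construction).  First-order structure is a test instrument, not a
biological claim: the co-occurrence features are adjacency statistics,
so the planted signal is expressible by the feature map.  Default class
imbalance mirrors a typical four-species miRNA repository snapshot
(ratios ~ 2654 : 369 : 1978 : 764) so oversampling paths are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_io import NucleotideSequence

SYMBOLS = ("A", "C", "U", "G")

#: per-species counts proportional to a real four-species miRNA corpus
DEFAULT_COUNT_RATIOS = {"Human": 2654, "Gorilla": 369, "Mouse": 1978, "Rat": 764}

#: mildly non-uniform shared baseline chain
_BASELINE = np.array([
    [0.30, 0.25, 0.25, 0.20],
    [0.25, 0.30, 0.20, 0.25],
    [0.20, 0.25, 0.30, 0.25],
    [0.25, 0.20, 0.25, 0.30],
])


@dataclass(frozen=True)
class SpeciesProfile:
    name: str
    transition: np.ndarray          # 4x4 row-stochastic
    initial: np.ndarray             # length-4 probability vector
    length_range: tuple[int, int] = (20, 25)

    def __post_init__(self) -> None:
        t = np.asarray(self.transition)
        if t.shape != (4, 4) or np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition must be 4x4 row-stochastic")
        lo, hi = self.length_range
        if not (3 <= lo <= hi <= 200):
            raise ValueError("length range must lie within [3, 200]")


def make_profiles(
    num_species: int,
    separation: float,
    seed: int,
    names: list[str] | None = None,
    length_range: tuple[int, int] = (20, 25),
) -> list[SpeciesProfile]:
    """Species profiles interpolating baseline <-> species-specific chains.

    At separation 0 every species shares the baseline matrix; at 1 each
    uses its own Dirichlet-drawn stochastic matrix.  Deterministic given
    the seed.
    """
    if num_species < 2:
        raise ValueError("need at least two species")
    if not 0.0 <= separation <= 1.0:
        raise ValueError("separation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if names is None:
        defaults = list(DEFAULT_COUNT_RATIOS)
        names = [defaults[i] if i < len(defaults) else f"Species{i}"
                 for i in range(num_species)]
    profiles = []
    for name in names[:num_species]:
        # sharply peaked Dirichlet rows make distinct species chains
        specific = rng.dirichlet(np.full(4, 0.35), size=4)
        transition = (1.0 - separation) * _BASELINE + separation * specific
        initial = transition.mean(axis=0)
        profiles.append(SpeciesProfile(
            name=name,
            transition=transition,
            initial=initial / initial.sum(),
            length_range=length_range,
        ))
    return profiles


def sample_corpus(
    profiles: list[SpeciesProfile],
    counts: dict[str, int] | list[int],
    seed: int,
) -> list[NucleotideSequence]:
    """Draw labeled Markov-chain sequences; deterministic given the seed."""
    if not isinstance(counts, dict):
        counts = {p.name: c for p, c in zip(profiles, counts)}
    rng = np.random.default_rng(seed)
    records = []
    for prof in profiles:
        n = counts[prof.name]
        if n < 1:
            raise ValueError(f"count for {prof.name!r} must be >= 1")
        lo, hi = prof.length_range
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            idx = np.empty(length, dtype=int)
            idx[0] = rng.choice(4, p=prof.initial)
            for t in range(1, length):
                idx[t] = rng.choice(4, p=prof.transition[idx[t - 1]])
            records.append(NucleotideSequence(
                id=f"{prof.name.lower()}_{i}",
                species_label=prof.name,
                symbols="".join(SYMBOLS[j] for j in idx),
            ))
    return records


def default_counts(total: int = 218) -> dict[str, int]:
    """Scale the default imbalance ratios down to roughly ``total`` records."""
    grand = sum(DEFAULT_COUNT_RATIOS.values())
    return {name: max(1, round(total * c / grand))
            for name, c in DEFAULT_COUNT_RATIOS.items()}
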