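"""Reading, validating and encoding short RNA/DNA sequence records.

Sequences are normalized to the RNA alphabet {A, C, G, U} (uppercase,
T mapped to U).  The purine/pyrimidine binary encoding maps A/G to 1 and
C/U to 0; all downstream complexity features (Shannon entropy, Hurst
exponent) operate on that bit string.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

ALPHABET = ("A", "C", "G", "U")
#: purine/pyrimidine map: A/G -> 1, C/U -> 0
PURINE_BITS = {"A": 1, "G": 1, "C": 0, "U": 0}


class SequenceValidationError(ValueError):
    """Raised when a record contains symbols outside {A, C, G, U}."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A labeled sequence record over the RNA alphabet."""

    id: str
    species_label: str
    symbols: str

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        for pos, sym in enumerate(self.symbols, start=1):
            if sym not in PURINE_BITS:
                raise SequenceValidationError(
                    f"record {self.id!r}: invalid symbol {sym!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class BinarySequence:
    """Purine/pyrimidine bit string of a source record."""

    bits: np.ndarray
    source_id: str

    def __len__(self) -> int:
        return len(self.bits)


def normalize_symbols(raw: str) -> str:
    """Uppercase and map DNA thymine to uracil; no other rewriting."""
    return raw.strip().upper().replace("T", "U")


def make_record(rec_id: str, label: str, raw_symbols: str) -> NucleotideSequence:
    return NucleotideSequence(id=rec_id, species_label=label,
                              symbols=normalize_symbols(raw_symbols))


def read_fasta(
    path: str | Path,
    label_map: dict[str, str] | None = None,
    drop_invalid: bool = False,
) -> list[NucleotideSequence]:
    """Read a multi-record FASTA file into validated records.

    The species label is taken from ``label_map`` (record id -> label) when
    given, otherwise from the first whitespace-separated word of the header
    after the record id.  Records with ambiguity codes (N, R, Y, ...) raise
    :class:`SequenceValidationError` unless ``drop_invalid`` is set, in which
    case they are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[NucleotideSequence] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        if label_map is not None:
            try:
                label = label_map[entry.id]
            except KeyError:
                raise KeyError(f"no label for FASTA record {entry.id!r}")
        else:
            parts = entry.description.split()
            label = parts[1] if len(parts) > 1 else "unlabeled"
        try:
            records.append(make_record(entry.id, label, str(entry.seq)))
        except SequenceValidationError:
            if drop_invalid:
                warnings.warn(f"dropping record {entry.id!r} with ambiguous symbols")
                continue
            raise
    if not records:
        raise ValueError(f"no sequence records found in {path}")
    return records


def read_plain(path: str | Path, labels: Sequence[str]) -> list[NucleotideSequence]:
    """Read one-sequence-per-line text with an explicit parallel label list."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) != len(labels):
        raise ValueError(f"{len(lines)} sequences but {len(labels)} labels")
    return [make_record(f"seq{i}", lab, ln) for i, (ln, lab) in enumerate(zip(lines, labels))]


def read_label_table(path: str | Path) -> dict[str, str]:
    """Two-column (id, label) TSV -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "label"], dtype=str)
    return dict(zip(df["id"], df["label"]))


def encode_binary(seq: NucleotideSequence) -> BinarySequence:
    """Purine/pyrimidine encoding: A/G -> 1, C/U -> 0, position-wise."""
    bits = np.fromiter((PURINE_BITS[s] for s in seq.symbols), dtype=np.int8,
                       count=len(seq))
    return BinarySequence(bits=bits, source_id=seq.id)


def write_feature_table(
    records: Iterable[tuple[str, str, "np.ndarray"]],
    feature_names: Sequence[str],
    path: str | Path,
) -> None:
    """Write (id, label, feature-vector) rows as a TSV feature table.

    Header is ``id, label`` followed by the feature names; round-trips
    losslessly through :func:`read_feature_table` (full float repr).
    """
    rows = []
    for rec_id, label, values in records:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(feature_names),):
            raise ValueError(
                f"record {rec_id!r}: expected {len(feature_names)} features, "
                f"got {values.shape}"
            )
        rows.append([rec_id, label, *values])
    df = pd.DataFrame(rows, columns=["id", "label", *feature_names])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "label": str})
    if list(df.columns[:2]) != ["id", "label"]:
        raise ValueError("feature table must start with 'id' and 'label' columns")
    return df
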