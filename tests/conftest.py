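import numpy as np
import pandas as pd
import pytest

from ribotex.experiments import corpus_frame
from ribotex.sequence_io import make_record
from ribotex.synthetic import make_profiles, sample_corpus


@pytest.fixture
def rec():
    """Factory for quick unlabeled records."""
    def _rec(symbols, rec_id="x", label="Human"):
        return make_record(rec_id, label, symbols)
    return _rec


@pytest.fixture(scope="session")
def small_corpus_records():
    """Four species, 30 records each, clearly separated chains."""
    profiles = make_profiles(4, separation=0.8, seed=11)
    return sample_corpus(profiles, {p.name: 30 for p in profiles}, seed=11)


@pytest.fixture(scope="session")
def small_corpus(small_corpus_records) -> pd.DataFrame:
    """Composite-feature table of the small synthetic corpus."""
    return corpus_frame(small_corpus_records)


@pytest.fixture(scope="session")
def two_class_features(small_corpus):
    """(X, y) from the first two species of the small corpus."""
    from ribotex.datasets import build_pairwise
    species = sorted(small_corpus["label"].unique())
    ds = build_pairwise(small_corpus, species[0], species[1])
    return ds
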