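import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ribotex.cooccurrence import (
    COLUMN_SYMBOLS,
    CooccurrenceMatrix,
    FEATURE_NAMES,
    count_cooccurrence,
    extract_cooccurrence_features,
    normalize,
    pattern_sets,
    texture_features,
)
from ribotex.sequence_io import make_record


def naive_counts(s: str, patterns, offset: int) -> np.ndarray:
    """Independent brute-force enumeration over (position, pattern) pairs."""
    counts = np.zeros((len(patterns), 4), dtype=int)
    for l, pat in enumerate(patterns):
        k = len(pat)
        for i in range(len(s)):
            j = i + k + offset - 1
            if j < len(s) and s[i:i + k] == pat:
                counts[l, COLUMN_SYMBOLS.index(s[j])] += 1
    return counts


class TestPatternSets:
    def test_exact_printed_sets(self):
        sets = pattern_sets()
        assert [ps.name for ps in sets] == [f"X{i}" for i in range(1, 9)]
        assert [ps.matrix_label for ps in sets] == list("IJKLMNOP")
        assert sets[0].patterns == ("A", "C", "U", "G")
        assert sets[1].patterns == ("AA", "CC", "UU", "GG")
        assert sets[2].patterns == ("AC", "AU", "AG", "CU", "CG", "UG")
        assert sets[3].patterns == ("CA", "UA", "GA", "UC", "GC", "GU")
        assert sets[4].patterns == ("ACU", "ACG", "AUG", "CUG")
        assert sets[5].patterns == ("CAU", "CAG", "UAG", "UCG")
        assert sets[6].patterns == ("AUC", "AGC", "AGU", "CGU")
        assert sets[7].patterns == ("UCA", "GCA", "GUA", "GUC")

    def test_shapes_and_totals(self):
        sets = pattern_sets()
        assert [ps.q for ps in sets] == [4, 4, 6, 6, 4, 4, 4, 4]
        assert all(ps.column_symbols == ("A", "C", "U", "G") for ps in sets)
        assert sum(ps.q for ps in sets) == 36
        assert sum(ps.q * 4 for ps in sets) == 144


class TestCounting:
    def test_adjacent_pairs(self, rec):
        cm = count_cooccurrence(rec("ACGU"), pattern_sets()[0], offset=1)
        expected = np.zeros((4, 4), int)
        expected[0, 1] = 1  # A followed by C
        expected[1, 3] = 1  # C followed by G
        expected[3, 2] = 1  # G followed by U
        np.testing.assert_array_equal(cm.counts, expected)

    def test_homogeneous_run(self, rec):
        cm = count_cooccurrence(rec("AAAA"), pattern_sets()[0], offset=1)
        assert cm.counts[0, 0] == 3 and cm.counts.sum() == 3

    def test_too_short_sequence_all_zero(self, rec):
        for ps in pattern_sets():
            assert count_cooccurrence(rec("A"), ps, offset=1).counts.sum() == 0

    @given(s=st.text(alphabet="ACGU", min_size=3, max_size=60),
           offset=st.integers(1, 3))
    @settings(derandomize=True, max_examples=150)
    def test_matches_naive_enumeration(self, s, offset):
        seq = make_record("x", "h", s)
        for ps in pattern_sets():
            fast = count_cooccurrence(seq, ps, offset=offset).counts
            np.testing.assert_array_equal(fast, naive_counts(s, ps.patterns, offset))
            # anchor bound: at most n - k - offset + 1 occurrences
            assert fast.sum() <= max(0, len(s) - ps.k - offset + 1)


class TestNormalize:
    def test_unit_sum(self, rec):
        cm = normalize(count_cooccurrence(rec("ACGU"), pattern_sets()[0]))
        assert math.isclose(cm.normalized.sum(), 1.0, abs_tol=1e-12)
        assert np.all(cm.normalized[cm.counts > 0] == pytest.approx(1 / 3))

    def test_zero_total_flag(self, rec):
        cm = normalize(count_cooccurrence(rec("A"), pattern_sets()[0]))
        assert cm.zero_total and np.all(cm.normalized == 0)


class TestTextureFeatures:
    @staticmethod
    def _matrix(grid):
        cm = CooccurrenceMatrix(pattern_set=pattern_sets()[0],
                                counts=np.asarray(grid), offset=1)
        return normalize(cm)

    def test_delta_distribution(self):
        grid = np.zeros((4, 4), int)
        grid[0, 0] = 7
        tf = texture_features(self._matrix(grid))
        assert tf.as_tuple() == (1.0, 0.0, 1.0, 0.0, 0.0)

    def test_uniform_grid_closed_forms(self):
        tf = texture_features(self._matrix(np.ones((4, 4), int)))
        assert tf.energy == pytest.approx(1 / 16)
        assert tf.entropy == pytest.approx(math.log(16))
        assert tf.contrast == pytest.approx(2.5)
        assert tf.dissimilarity == pytest.approx(1.25)
        assert tf.homogeneity == pytest.approx(0.5)

    def test_zero_total_gives_zero_features(self, rec):
        cm = normalize(count_cooccurrence(rec("A"), pattern_sets()[0]))
        assert texture_features(cm).as_tuple() == (0.0,) * 5

    @given(s=st.text(alphabet="ACGU", min_size=5, max_size=60))
    @settings(derandomize=True, max_examples=100)
    def test_statistic_bounds(self, s):
        seq = make_record("x", "h", s)
        for ps in pattern_sets():
            cm = normalize(count_cooccurrence(seq, ps))
            tf = texture_features(cm)
            assert 0.0 <= tf.energy <= 1.0
            assert 0.0 <= tf.homogeneity <= 1.0
            assert 0.0 <= tf.entropy <= math.log(4 * ps.q) + 1e-12
            assert tf.contrast >= 0.0 and tf.dissimilarity >= 0.0


class TestFeatureVector:
    def test_length_and_names(self, rec):
        v = extract_cooccurrence_features(rec("ACGUACGUACGUACGUACGUAC"))
        assert v.shape == (40,)
        assert FEATURE_NAMES == tuple(f"f{i}" for i in range(1, 41))

    def test_homogeneous_sequence_blocks(self, rec):
        with pytest.warns(UserWarning, match="zero-total"):
            v = extract_cooccurrence_features(rec("A" * 22))
        # matrix I: all mass at (A, A) -> delta statistics
        np.testing.assert_allclose(v[:5], [1.0, 0.0, 1.0, 0.0, 0.0])
        # matrix J (AA followed by A): same delta shape
        np.testing.assert_allclose(v[5:10], [1.0, 0.0, 1.0, 0.0, 0.0])
        # sets with no all-A pattern see nothing
        np.testing.assert_allclose(v[10:], 0.0)

    @given(s=st.text(alphabet="ACGU", min_size=1, max_size=60))
    @settings(derandomize=True, max_examples=60)
    def test_fixed_length_regardless_of_input(self, s):
        assert extract_cooccurrence_features(
            make_record("x", "h", s), warn_zero_total=False).shape == (40,)
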