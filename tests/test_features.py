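"""One-hot encoding, mutual information, per-marker selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ystr_ancestry.features import (
    EncodingError,
    binary_mi_per_column,
    build_vocabulary,
    label_entropy,
    mutual_information,
    one_hot_encode,
    select_one_per_marker,
)
from ystr_ancestry.data import MISSING
from ystr_ancestry.panel import MarkerPanel
from ystr_ancestry.simulate import SimulationConfig, generate_table, separable_models

from conftest import make_table


def brute_force_mi(x, y):
    """Independent oracle: direct double sum over the contingency table."""
    n = len(x)
    mi = 0.0
    for xv in set(x):
        px = sum(1 for v in x if v == xv) / n
        for yv in set(y):
            pxy = sum(1 for a, b in zip(x, y) if a == xv and b == yv) / n
            py = sum(1 for v in y if v == yv) / n
            if pxy > 0:
                mi += pxy * math.log(pxy / (px * py))
    return mi


class TestVocabulary:
    def test_one_profile_one_entry_per_locus(self, single_copy_panel):
        t = make_table(single_copy_panel, [("s1", "A", ["10", "11", "12"])])
        vocab = build_vocabulary(t)
        assert len(vocab) == 3

    def test_union_of_observed_alleles(self, single_copy_panel):
        t = make_table(single_copy_panel, [
            ("s1", "A", ["14", "9", "10"]),
            ("s2", "A", ["15", "9", "10"]),
        ])
        vocab = build_vocabulary(t)
        assert [e for e in vocab.entries if e[0] == "L1"] == [("L1", "14"), ("L1", "15")]
        assert len(vocab) == 4

    def test_order_invariant_to_profile_order(self, single_copy_panel):
        rows = [("s1", "A", ["14", "9", "10"]), ("s2", "A", ["12", "8", "11"])]
        v1 = build_vocabulary(make_table(single_copy_panel, rows))
        v2 = build_vocabulary(make_table(single_copy_panel, rows[::-1]))
        assert v1.entries == v2.entries

    def test_numeric_order_with_microvariants(self, single_copy_panel):
        t = make_table(single_copy_panel, [
            ("s1", "A", ["13.2", "9", "10"]),
            ("s2", "A", ["13", "9", "10"]),
            ("s3", "A", ["14", "9", "10"]),
        ])
        l1 = [a for lc, a in build_vocabulary(t).entries if lc == "L1"]
        assert l1 == ["13", "13.2", "14"]

    def test_missing_rejected(self, single_copy_panel):
        t = make_table(single_copy_panel, [("s1", "A", ["10", MISSING, "12"])])
        with pytest.raises(EncodingError):
            build_vocabulary(t)

    def test_feature_name_convention(self, small_panel):
        t = make_table(small_panel, [("s1", "A", ["14", "11", "13.2", "22", "10"])])
        names = build_vocabulary(t).feature_names
        assert "DYS19_14" in names and "DYS385b_13.2" in names and "DYS439_10" in names


class TestOneHot:
    def test_row_sums_equal_locus_copy_count(self, small_panel):
        t = make_table(small_panel, [
            ("s1", "A", ["14", "11", "14", "22", "10"]),
            ("s2", "B", ["13", "12", "12", "23", "11"]),
        ])
        vocab = build_vocabulary(t)
        fm = one_hot_encode(t, vocab)
        assert np.all(fm.values.sum(axis=1) == small_panel.n_locus_copies)

    def test_identical_profiles_identical_rows(self, single_copy_panel):
        t = make_table(single_copy_panel, [
            ("s1", "A", ["10", "11", "12"]),
            ("s2", "A", ["10", "11", "12"]),
        ])
        fm = one_hot_encode(t, build_vocabulary(t))
        assert np.array_equal(fm.values[0], fm.values[1])

    def test_hand_checked_matrix(self):
        panel = MarkerPanel(loci=("X", "Y"))
        t = make_table(panel, [("s1", "A", ["14", "9"]), ("s2", "B", ["15", "9"])])
        fm = one_hot_encode(t, build_vocabulary(t))
        assert fm.feature_names == ["X_14", "X_15", "Y_9"]
        assert fm.values.tolist() == [[1, 0, 1], [0, 1, 1]]

    def test_unseen_allele_strict_vs_permissive(self, single_copy_panel):
        train = make_table(single_copy_panel, [("s1", "A", ["10", "11", "12"])])
        vocab = build_vocabulary(train)
        test = make_table(single_copy_panel, [("t1", None, ["99", "11", "12"])])
        with pytest.raises(EncodingError, match="99"):
            one_hot_encode(test, vocab)
        fm = one_hot_encode(test, vocab, on_unseen="zero")
        assert fm.values.sum() == 2  # the unseen locus contributes no 1


class TestMutualInformation:
    def test_constant_feature_zero(self):
        assert mutual_information(np.zeros(50, int), np.arange(50) % 3) == 0.0

    def test_perfect_dependence_equals_entropy(self):
        y = np.array([0, 1] * 20)
        assert mutual_information(y, y) == pytest.approx(label_entropy(y), abs=1e-12)

    def test_contingency_oracle(self):
        # [[30,10],[10,30]]: direct plug-in sum
        x = np.array([0] * 40 + [1] * 40)
        y = np.array([0] * 30 + [1] * 10 + [0] * 10 + [1] * 30)
        assert mutual_information(x, y) == pytest.approx(brute_force_mi(x, y), abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(2, 40), st.integers(2, 4), st.integers(0, 10_000))
    def test_matches_brute_force_on_random_instances(self, n, k, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n)
        y = rng.integers(0, k, n)
        assert mutual_information(x, y) == pytest.approx(
            brute_force_mi(list(x), list(y)), abs=1e-12
        )

    def test_bounded_by_label_entropy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 2, 60)
            y = rng.integers(0, 3, 60)
            assert 0.0 <= mutual_information(x, y) <= label_entropy(y) + 1e-12

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, (80, 12))
        y = rng.integers(0, 2, 80)
        vec = binary_mi_per_column(X, y)
        for j in range(12):
            assert vec[j] == pytest.approx(mutual_information(X[:, j], y), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros(3), np.zeros(4))


class TestSelectOnePerMarker:
    def _encoded(self, panel, n_per_pop=60, seed=0):
        ms = separable_models(panel, 2, alleles_per_locus=3, seed=seed)
        t = generate_table(SimulationConfig(
            panel, ms, {m.name: n_per_pop for m in ms}, seed=seed))
        vocab = build_vocabulary(t)
        fm = one_hot_encode(t, vocab)
        y = np.array([0 if p == "POP1" else 1 for p in t.populations])
        return fm, vocab, y

    def test_output_width_equals_locus_copy_count(self, small_panel):
        fm, vocab, y = self._encoded(small_panel)
        sub, _ = select_one_per_marker(fm, y, vocab)
        assert sub.n_features == small_panel.n_locus_copies

    def test_twenty_locus_copy_panel_yields_twenty(self):
        panel = MarkerPanel(loci=tuple(f"L{i}" for i in range(20)))
        fm, vocab, y = self._encoded(panel)
        sub, _ = select_one_per_marker(fm, y, vocab)
        assert sub.n_features == 20

    def test_single_allele_locus_kept(self, single_copy_panel):
        t = make_table(single_copy_panel, [
            ("s1", "A", ["10", "11", "12"]),
            ("s2", "B", ["10", "12", "12"]),
        ])
        vocab = build_vocabulary(t)
        fm = one_hot_encode(t, vocab)
        sub, sub_vocab = select_one_per_marker(fm, np.array([0, 1]), vocab)
        assert ("L1", "10") in sub_vocab.entries and ("L3", "12") in sub_vocab.entries

    def test_private_allele_selected(self, single_copy_panel):
        # L1 allele "30" appears only in class 1 -> maximal MI at L1
        rows = [(f"a{i}", "A", ["10", "11", "12"]) for i in range(20)]
        rows += [(f"b{i}", "B", ["30", "11", "12"]) for i in range(20)]
        t = make_table(single_copy_panel, rows)
        vocab = build_vocabulary(t)
        fm = one_hot_encode(t, vocab)
        y = np.array([0] * 20 + [1] * 20)
        _, sub_vocab = select_one_per_marker(fm, y, vocab)
        l1 = [a for lc, a in sub_vocab.entries if lc == "L1"]
        assert l1 in (["10"], ["30"])  # both have identical MI (complementary)
        # tie broken toward the lowest numeric allele
        assert l1 == ["10"]

    def test_idempotent(self, small_panel):
        fm, vocab, y = self._encoded(small_panel)
        sub, sub_vocab = select_one_per_marker(fm, y, vocab)
        again, again_vocab = select_one_per_marker(sub, y, sub_vocab)
        assert again_vocab.entries == sub_vocab.entries
        assert np.array_equal(again.values, sub.values)

    def test_subset_of_input_columns(self, small_panel):
        fm, vocab, y = self._encoded(small_panel)
        sub, _ = select_one_per_marker(fm, y, vocab)
        assert set(sub.feature_names) <= set(fm.feature_names)
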