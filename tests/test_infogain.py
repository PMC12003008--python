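import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alarmtrie import (
    CallSequence,
    Corpus,
    build_trie,
    class_weights,
    conditional_distribution,
    entropy_of_distribution,
    info_profile,
    kl_gain,
    node_accuracy,
    positional_accuracy,
    positional_entropy,
    prefix_probability,
    read_profile,
    write_profile,
)
from alarmtrie.infogain import InfoGainError
from alarmtrie.trie import TrieNode

from oracles import brute_profile

LOG3_2 = math.log(2) / math.log(3)


@st.composite
def small_corpora(draw):
    n = draw(st.integers(2, 10))
    labels = draw(
        st.lists(st.sampled_from(["E", "L", "T"]), min_size=n, max_size=n).filter(
            lambda ls: len(set(ls)) >= 2
        )
    )
    token_lists = draw(
        st.lists(
            st.lists(st.sampled_from(["A", "B"]), min_size=1, max_size=4).map(tuple),
            min_size=n,
            max_size=n,
        )
    )
    seqs = tuple(CallSequence(toks, y) for toks, y in zip(token_lists, labels))
    return Corpus(seqs, ("A", "B"), tuple(sorted(set(labels))))


class TestClassWeights:
    def test_study_counts_give_printed_weights(self):
        seqs = [CallSequence(("A",), "E")] * 39 + [CallSequence(("A",), "T")] * 79 + [CallSequence(("A",), "L")] * 166
        corpus = Corpus(tuple(seqs))
        w = class_weights(corpus)
        assert w["E"] == Fraction(1, 117)
        assert w["T"] == Fraction(1, 237)
        assert w["L"] == Fraction(1, 498)

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"E": 5, "L": 5, "T": 5}, {"E": Fraction(1, 15), "L": Fraction(1, 15), "T": Fraction(1, 15)}),
            ({"E": 2, "L": 1, "T": 1}, {"E": Fraction(1, 6), "L": Fraction(1, 3), "T": Fraction(1, 3)}),
        ],
    )
    def test_formula(self, counts, expected):
        seqs = tuple(CallSequence(("A",), y) for y, n in counts.items() for _ in range(n))
        w = class_weights(Corpus(seqs))
        assert {y: w[y] for y in counts} == expected

    def test_normalization_is_exact(self):
        seqs = tuple(CallSequence(("A",), y) for y, n in [("E", 7), ("L", 13), ("T", 29)] for _ in range(n))
        w = class_weights(Corpus(seqs))
        assert sum(v * n for v, n in zip(w.values, w.counts)) == 1

    def test_empty_class_rejected(self):
        corpus = Corpus((CallSequence(("A",), "E"),), class_alphabet=("E", "L", "T"))
        with pytest.raises(InfoGainError, match="zero sequences"):
            class_weights(corpus)


class TestNodeLevel:
    def test_prefix_probabilities_tiny(self, tiny_corpus):
        trie = build_trie(tiny_corpus)
        w = class_weights(tiny_corpus)
        assert prefix_probability(trie, trie.find(("A",)), w) == pytest.approx(1 / 3, abs=1e-15)
        assert prefix_probability(trie, trie.find(("B",)), w) == pytest.approx(2 / 3, abs=1e-15)
        for t in range(trie.depth + 1):
            total = sum(prefix_probability(trie, n, w) for n in trie.nodes_at_depth(t))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_conditional_distributions_tiny(self, tiny_corpus):
        trie = build_trie(tiny_corpus)
        w = class_weights(tiny_corpus)
        np.testing.assert_allclose(conditional_distribution(trie, trie.root, w), [1 / 3] * 3, atol=1e-15)
        np.testing.assert_allclose(conditional_distribution(trie, trie.find(("B",)), w), [0, 0.5, 0.5], atol=1e-15)
        pure = conditional_distribution(trie, trie.find(("B", "A", "A")), w)
        np.testing.assert_array_equal(pure, [0, 0, 1])

    def test_zero_mass_node_rejected(self, tiny_corpus):
        trie = build_trie(tiny_corpus)
        w = class_weights(tiny_corpus)
        with pytest.raises(InfoGainError, match="zero-mass"):
            conditional_distribution(trie, TrieNode(prefix=("B", "B")), w)

    def test_mismatched_weights_rejected(self, tiny_corpus):
        trie = build_trie(tiny_corpus)
        other = Corpus(tuple(CallSequence(("A",), y) for y in "ELT"))
        with pytest.raises(InfoGainError, match="class counts"):
            prefix_probability(trie, trie.root, class_weights(other))


class TestEntropyAndAccuracy:
    @pytest.mark.parametrize(
        "dist,k,expected",
        [
            ([1 / 3, 1 / 3, 1 / 3], 3, 1.0),
            ([1, 0, 0], 3, 0.0),
            ([0.5, 0.5, 0.0], 3, LOG3_2),
            ([0.5, 0.5], 2, 1.0),
        ],
    )
    def test_entropy_closed_forms(self, dist, k, expected):
        assert entropy_of_distribution(dist, k) == pytest.approx(expected, abs=1e-15)

    def test_entropy_rejects_non_distribution(self):
        with pytest.raises(InfoGainError):
            entropy_of_distribution([0.7, 0.7], 2)

    @pytest.mark.parametrize(
        "dist,expected",
        [([1 / 3, 1 / 3, 1 / 3], 1 / 3), ([0.06, 0.72, 0.22], 0.72), ([0, 1, 0], 1.0)],
    )
    def test_node_accuracy_is_max_probability(self, dist, expected):
        assert node_accuracy(dist) == pytest.approx(expected, abs=1e-15)


class TestPositionalIndices:
    def test_tiny_corpus_worked_example(self, tiny_corpus):
        trie = build_trie(tiny_corpus, max_depth=3)
        w = class_weights(tiny_corpus)
        assert positional_entropy(trie, 0, w) == pytest.approx(1.0, abs=1e-12)
        assert positional_entropy(trie, 1, w) == pytest.approx(2 / 3 * LOG3_2, abs=1e-12)
        assert positional_entropy(trie, 3, w) == pytest.approx(0.0, abs=1e-12)
        assert positional_accuracy(trie, 0, w) == pytest.approx(1 / 3, abs=1e-15)
        assert positional_accuracy(trie, 1, w) == pytest.approx(2 / 3, abs=1e-15)
        assert kl_gain(positional_entropy(trie, 0, w), positional_entropy(trie, 1, w)) == pytest.approx(
            1 - 2 / 3 * LOG3_2, abs=1e-12
        )

    def test_position_out_of_range(self, tiny_corpus):
        trie = build_trie(tiny_corpus, max_depth=2)
        with pytest.raises(Exception):
            positional_entropy(trie, 3, class_weights(tiny_corpus))

    def test_uninformative_split_has_zero_gain(self):
        # both first symbols carry identical class composition
        seqs = tuple(
            CallSequence((sym, "A"), y)
            for sym in ("A", "B")
            for y in ("E", "L")
        )
        profile = info_profile(Corpus(seqs, class_alphabet=("E", "L")), max_depth=1)
        assert profile.D[1] == 0.0

    def test_perfectly_separating_first_symbol_reaches_accuracy_one(self):
        seqs = (CallSequence(("A",), "E"),) * 3 + (CallSequence(("B",), "L"),) * 5
        profile = info_profile(Corpus(seqs, class_alphabet=("E", "L")), max_depth=1)
        assert profile.J[1] == 1.0
        assert profile.H[1] == 0.0

    def test_full_profile_of_tiny_corpus(self, tiny_corpus):
        profile = info_profile(tiny_corpus, max_depth=3)
        np.testing.assert_allclose(profile.H, [1, 2 / 3 * LOG3_2, 2 / 3 * LOG3_2, 0], atol=1e-12)
        np.testing.assert_allclose(profile.D, [0, 1 - 2 / 3 * LOG3_2, 0, 2 / 3 * LOG3_2], atol=1e-12)
        np.testing.assert_allclose(profile.J, [1 / 3, 2 / 3, 2 / 3, 1], atol=1e-12)


class TestOracleEquivalence:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(small_corpora())
    def test_trie_indices_match_brute_force_enumeration(self, corpus):
        t_max = corpus.max_length() + 1
        profile = info_profile(corpus, max_depth=t_max)
        H, D, J = brute_profile([s.tokens for s in corpus.sequences], list(corpus.labels()), t_max)
        np.testing.assert_allclose(profile.H, H, atol=1e-12)
        np.testing.assert_allclose(profile.D, D, atol=1e-12)
        np.testing.assert_allclose(profile.J, J, atol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(small_corpora())
    def test_refinement_monotonicity_and_telescoping(self, corpus):
        profile = info_profile(corpus)
        assert np.all(np.diff(profile.H) <= 1e-12)
        assert np.all(np.diff(profile.J) >= -1e-12)
        assert np.all(profile.D >= 0)
        for t in range(len(profile.H)):
            assert profile.D[1 : t + 1].sum() == pytest.approx(profile.H[0] - profile.H[t], abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(small_corpora())
    def test_balanced_classes_make_weighting_immaterial(self, corpus):
        # equalize class sizes by repetition, then compare weighted conditional
        # distributions with raw count fractions
        counts = corpus.class_counts()
        target = math.lcm(*counts.values())
        seqs = []
        for y in corpus.class_alphabet:
            mine = [s for s in corpus.sequences if s.label == y]
            seqs.extend(mine * (target // counts[y]))
        balanced = corpus.with_sequences(seqs)
        trie = build_trie(balanced)
        w = class_weights(balanced)
        for node in trie.nodes_at_depth(1):
            total = node.total_count()
            raw = np.array([node.class_counts.get(y, 0) / total for y in balanced.class_alphabet])
            np.testing.assert_allclose(conditional_distribution(trie, node, w), raw, atol=1e-12)


def test_profile_tsv_round_trip(tmp_path, tiny_corpus):
    profile = info_profile(tiny_corpus)
    back = read_profile(write_profile(profile, tmp_path / "p.tsv"))
    np.testing.assert_allclose(back.H, profile.H, atol=1e-12)
    np.testing.assert_allclose(back.D, profile.D, atol=1e-12)
    np.testing.assert_allclose(back.J, profile.J, atol=1e-12)
    assert np.all(np.isnan(back.D_lo))
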