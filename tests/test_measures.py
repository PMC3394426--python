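"""Unit and property tests for the string similarity measures."""

import math
import random

import edlib
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abbrclust.measures import (
    CorpusStats,
    MongeElkanParams,
    WeightVector,
    build_corpus_stats,
    edit_distance,
    jaro,
    jaro_winkler,
    monge_elkan,
    ngram_dice,
    normalized_edit_distance,
    soft_tfidf,
    weighted_edit_distance,
)
from tests import oracles
from tests.conftest import all_strings, random_string

short_text = st.text(alphabet="abcdx -", max_size=10)
words = st.text(alphabet="abcx", min_size=1, max_size=6)


class TestEditDistance:
    def test_matches_recursive_enumeration_exhaustively(self):
        strings = all_strings("abc", 4)
        for s1 in strings:
            for s2 in strings:
                assert edit_distance(s1, s2) == oracles.lev_recursive(s1, s2)

    def test_kitten_sitting_equals_bruteforce(self):
        assert edit_distance("kitten", "sitting") == oracles.lev_recursive(
            "kitten", "sitting"
        )

    def test_agrees_with_edlib_on_random_pairs(self, pyrng):
        for _ in range(1000):
            s1 = random_string(pyrng, "abcdefgh xyz", 15)
            s2 = random_string(pyrng, "abcdefgh xyz", 15)
            if not s1 or not s2:  # edlib rejects empty queries
                continue
            assert edit_distance(s1, s2) == edlib.align(s1, s2)["editDistance"]

    @settings(derandomize=True, max_examples=150)
    @given(short_text, short_text, short_text)
    def test_metric_axioms(self, a, b, c):
        assert edit_distance(a, b) == edit_distance(b, a)
        assert (edit_distance(a, b) == 0) == (a == b)
        assert edit_distance(a, c) <= edit_distance(a, b) + edit_distance(b, c)


class TestNormalizedEditDistance:
    def test_single_insertion_worked_example(self):
        s1 = "diethylene glycol monoethyl ether"
        s2 = "diethylene glycol monomethyl ether"
        assert edit_distance(s1, s2) == 1
        assert normalized_edit_distance(s1, s2) == 1 / max(len(s1), len(s2))

    @pytest.mark.parametrize(
        "s1,s2,expected",
        [("abc", "abc", 0.0), ("abc", "", 1.0), ("", "", 0.0), ("ab", "ba", 1.0)],
    )
    def test_boundary_cases(self, s1, s2, expected):
        assert normalized_edit_distance(s1, s2) == expected

    @settings(derandomize=True, max_examples=150)
    @given(short_text, short_text)
    def test_bounded_unit_interval(self, a, b):
        assert 0.0 <= normalized_edit_distance(a, b) <= 1.0


class TestWeightedEditDistance:
    def test_unit_weights_reduce_to_unweighted_bitwise(self, pyrng):
        w = WeightVector()
        for _ in range(300):
            s1 = random_string(pyrng, "abcdefg -", 12)
            s2 = random_string(pyrng, "abcdefg -", 12)
            assert weighted_edit_distance(s1, s2, w) == normalized_edit_distance(s1, s2)

    def test_free_deletion(self):
        assert weighted_edit_distance("ax", "a", WeightVector({"x": 0.0})) == 0.0

    def test_matches_script_enumeration(self, pyrng):
        w_e = WeightVector({"e": 0.4})
        expected = oracles.weighted_script_min_cost("chemical", "chmical", {"e": 0.4})
        assert expected == 0.4
        assert weighted_edit_distance("chemical", "chmical", w_e) == expected / 8
        for _ in range(400):
            s1 = random_string(pyrng, "abce", 6)
            s2 = random_string(pyrng, "abce", 6)
            wmap = {c: round(pyrng.random(), 2) for c in "abce"}
            got = weighted_edit_distance(s1, s2, WeightVector(wmap))
            want = oracles.weighted_script_min_cost(s1, s2, wmap)
            want = want / max(len(s1), len(s2)) if max(len(s1), len(s2)) else 0.0
            assert got == pytest.approx(want, abs=1e-12)

    def test_monotone_in_each_weight(self, pyrng):
        for _ in range(60):
            s1 = random_string(pyrng, "abcd", 8)
            s2 = random_string(pyrng, "abcd", 8)
            char = pyrng.choice("abcd")
            values = [1.0, 0.8, 0.5, 0.2, 0.0]
            dists = [
                weighted_edit_distance(s1, s2, WeightVector({char: v})) for v in values
            ]
            # lowering one letter's cost can only lower the distance
            assert all(d2 <= d1 + 1e-15 for d1, d2 in zip(dists, dists[1:]))


class TestMongeElkan:
    def test_self_similarity_is_one(self):
        for s in ("a", "dime", "diethylene glycol"):
            assert monge_elkan(s, s) == 1.0

    def test_empty_string_rejected(self):
        with pytest.raises(ValueError):
            monge_elkan("", "abc")

    def test_class_substitution_example(self):
        # d~t share a class: 3 + 5 + 5 + 5 over denominator 5*4
        assert monge_elkan("dime", "time") == pytest.approx(
            oracles.monge_elkan_enumeration("dime", "time")
        )
        assert monge_elkan("dime", "time") == pytest.approx(0.9)

    def test_single_gap_example(self):
        # local alignment may keep only the 'a' match (5) rather than
        # bridging the gap (5 - 6 + 5 = 4)
        assert monge_elkan("ab", "acb") == pytest.approx(
            oracles.monge_elkan_enumeration("ab", "acb")
        )
        assert monge_elkan("ab", "acb") == pytest.approx(0.5)

    def test_matches_alignment_enumeration_exhaustively(self):
        strings = [s for s in all_strings("abc", 3) if s]
        for s1 in strings:
            for s2 in strings:
                assert monge_elkan(s1, s2) == pytest.approx(
                    oracles.monge_elkan_enumeration(s1, s2), abs=1e-12
                )

    def test_matches_enumeration_on_random_pairs(self, pyrng):
        params = MongeElkanParams(match_score=5, class_score=2, mismatch_score=-5)
        for _ in range(300):
            s1 = random_string(pyrng, "adept", 5, min_len=1)
            s2 = random_string(pyrng, "adept", 5, min_len=1)
            assert monge_elkan(s1, s2, params) == pytest.approx(
                oracles.monge_elkan_enumeration(s1, s2, params), abs=1e-12
            )

    @settings(derandomize=True, max_examples=150)
    @given(
        st.text(alphabet="abde", min_size=1, max_size=6),
        st.text(alphabet="abde", min_size=1, max_size=6),
    )
    def test_symmetric_and_bounded(self, a, b):
        s = monge_elkan(a, b)
        assert 0.0 <= s <= 1.0
        assert s == monge_elkan(b, a)


class TestJaroFamily:
    def test_worked_example_with_transposition(self):
        # 6 matches, one transposed pair (t/h), prefix 'mar'
        j = jaro("martha", "marhta")
        assert j == pytest.approx(17 / 18)
        assert jaro_winkler("martha", "marhta") == pytest.approx(j + 0.3 * (1 - j))

    @pytest.mark.parametrize("s1,s2", [("abc", "xyz"), ("", "abc"), ("", "")])
    def test_no_matches_scores_zero(self, s1, s2):
        assert jaro(s1, s2) == 0.0
        assert jaro_winkler(s1, s2) == 0.0

    def test_matches_definitional_oracle(self, pyrng):
        strings = all_strings("abc", 4)
        for s1 in strings[::3]:
            for s2 in strings[::3]:
                assert jaro(s1, s2) == pytest.approx(
                    oracles.jaro_definitional(s1, s2), abs=1e-12
                )
        for _ in range(1000):
            s1 = random_string(pyrng, "abcdef", 10)
            s2 = random_string(pyrng, "abcdef", 10)
            assert jaro_winkler(s1, s2) == pytest.approx(
                oracles.jaro_winkler_definitional(s1, s2), abs=1e-12
            )

    @settings(derandomize=True, max_examples=200)
    @given(short_text, short_text)
    def test_winkler_boost_properties(self, a, b):
        j, jw = jaro(a, b), jaro_winkler(a, b)
        assert 0.0 <= j <= 1.0 and 0.0 <= jw <= 1.0
        assert jw >= j
        if not (a and b and a[0] == b[0]):
            assert jw == j  # no common prefix: no boost
        assert jaro(a, b) == jaro(b, a)
        assert jaro_winkler(a, b) == jaro_winkler(b, a)


class TestCorpusStats:
    def test_counts_strings_not_occurrences(self):
        stats = build_corpus_stats(["a b", "b c"])
        assert stats.corpus_size == 2
        assert stats.doc_freq == {"a": 1, "b": 2, "c": 1}
        assert build_corpus_stats(["x x x"]).doc_freq == {"x": 1}

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            build_corpus_stats([])

    def test_matches_independent_recount(self, pyrng):
        corpus = [
            " ".join(random_string(pyrng, "ab", 3, min_len=1) for _ in range(3))
            for _ in range(10)
        ]
        stats = build_corpus_stats(corpus)
        for token in stats.doc_freq:
            naive = sum(token in s.split() for s in corpus)
            assert stats.doc_freq[token] == naive
            assert 1 <= stats.doc_freq[token] <= stats.corpus_size


class TestSoftTfidf:
    def test_self_similarity_is_one_for_rare_tokens(self):
        corpus = ["alpha beta", "gamma delta", "epsilon zeta"]
        stats = build_corpus_stats(corpus)
        assert soft_tfidf("alpha beta", "alpha beta", stats) == pytest.approx(1.0)

    def test_no_token_pair_reaches_cutoff(self):
        stats = build_corpus_stats(["alpha beta", "gamma delta"])
        assert soft_tfidf("alpha beta", "gamma delta", stats, a=0.9) == 0.0

    def test_worked_example_matches_definitional_oracle(self):
        corpus = ["acid amine", "acid ether", "amine ether"]
        stats = build_corpus_stats(corpus)
        got = soft_tfidf("acid amine", "acid ether", stats, a=0.5)
        assert got == pytest.approx(
            oracles.soft_tfidf_definitional("acid amine", "acid ether", corpus, a=0.5)
        )
        assert got > 0.0

    def test_matches_oracle_on_random_corpora(self, pyrng):
        for _ in range(200):
            corpus = list(
                {
                    " ".join(
                        random_string(pyrng, "abx", 4, min_len=1) for _ in range(2)
                    )
                    for _ in range(5)
                }
            )
            s1, s2 = pyrng.choice(corpus), pyrng.choice(corpus)
            stats = build_corpus_stats(corpus)
            a = pyrng.choice([0.5, 0.8, 0.9])
            assert soft_tfidf(s1, s2, stats, a) == pytest.approx(
                oracles.soft_tfidf_definitional(s1, s2, corpus, a), abs=1e-12
            )

    def test_ubiquitous_tokens_carry_no_weight(self):
        stats = build_corpus_stats(["common a", "common b"])
        # 'common' occurs in every string: log IDF = 0, so it cannot match
        assert soft_tfidf("common", "common", stats) == 0.0

    def test_empty_tokenization_rejected(self):
        stats = build_corpus_stats(["a b"])
        with pytest.raises(ValueError):
            soft_tfidf("", "a", stats)


class TestNgramDice:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [
            ("night", "nacht", 0.2),  # only "ht" shared; 2*1/(5+5)
            ("ab", "cd", 0.0),
            ("abcd", "abcd", 0.75),  # 3 bigrams each over length denominator 8
            ("a", "abc", 0.0),  # shorter than the n-gram order
        ],
    )
    def test_length_denominator_examples(self, s1, s2, expected):
        assert ngram_dice(s1, s2) == pytest.approx(expected)

    def test_repeated_bigrams_capped_by_multiplicity(self):
        # "aaa" has bigram aa twice, "aa" only once: c = 1
        assert ngram_dice("aaa", "aa") == pytest.approx(2 * 1 / 5)

    def test_ngram_denominator_restores_self_identity(self):
        assert ngram_dice("abcd", "abcd", denominator="ngram") == 1.0

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            ngram_dice("ab", "cd", n=0)

    def test_matches_greedy_occurrence_oracle(self, pyrng):
        strings = all_strings("abc", 4)
        for s1 in strings[::2]:
            for s2 in strings[::2]:
                assert ngram_dice(s1, s2) == pytest.approx(
                    oracles.dice_greedy(s1, s2), abs=1e-12
                )
        for _ in range(1000):
            s1 = random_string(pyrng, "abcd", 9)
            s2 = random_string(pyrng, "abcd", 9)
            n = pyrng.choice([1, 2, 3])
            assert ngram_dice(s1, s2, n) == pytest.approx(
                oracles.dice_greedy(s1, s2, n), abs=1e-12
            )

    @settings(derandomize=True, max_examples=200)
    @given(short_text, short_text)
    def test_symmetric_and_bounded(self, a, b):
        s = ngram_dice(a, b)
        assert 0.0 <= s <= 1.0
        assert s == ngram_dice(b, a)


class TestWeightVector:
    def test_validation(self):
        with pytest.raises(ValueError):
            WeightVector({"e": -0.1})
        with pytest.raises(ValueError):
            WeightVector([1.0] * 25)
        with pytest.raises(ValueError):
            WeightVector({"E": 0.5})

    def test_tsv_round_trip(self, tmp_path):
        w = WeightVector({"e": 0.4, "h": 0.1, "z": 0.0})
        path = tmp_path / "w.tsv"
        w.to_tsv(path)
        assert WeightVector.from_tsv(path) == w
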