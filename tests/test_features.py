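"""Tokenization, information gain, subset-ranked top words, lexicon overlap."""

import math
from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

from depsignal.corpus import GOLD
from depsignal.features import (
    SKIPPED,
    information_gain,
    lexicon_overlap,
    tokenize,
    top_words,
)


class TestTokenize:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("I can't concentrate", ["i", "can't", "concentrate"]),
            ("Tiredddd!!! 😴", ["tiredddd", "😴"]),
            ("...", []),
            ("#depressed day", ["#depressed", "day"]),
            ("see http://example.com now", ["see", "<url>", "now"]),
            ("hey @friend :(", ["hey", "<user>"]),
            ("'quoted'", ["quoted"]),
        ],
    )
    def test_examples(self, text, expected):
        assert tokenize(text) == expected

    @given(st.text(max_size=40))
    def test_tokens_are_normalized(self, text):
        for tok in tokenize(text):
            assert tok == tok.lower()
            assert tok
            assert not any(c.isspace() for c in tok)


def ig_oracle(observations):
    """Brute-force mutual information (bits) over (present, positive) pairs."""

    def entropy(labels):
        n = len(labels)
        return -sum(
            (c / n) * math.log2(c / n) for c in Counter(labels).values() if c
        )

    n = len(observations)
    ys = [y for _, y in observations]
    result = entropy(ys)
    for v in (0, 1):
        sub = [y for w, y in observations if w == v]
        if sub:
            result -= len(sub) / n * entropy(sub)
    return result


class TestInformationGain:
    def _corpus(self, build_corpus, rows):
        """rows: list of (has_word, is_positive)."""
        records = []
        for i, (w, y) in enumerate(rows):
            text = "xmarker filler" if w else "filler other"
            cat = "fatigue" if y else "no_evidence"
            records.append((f"t{i}", text, {GOLD: [cat]}))
        return build_corpus(records)

    def test_word_in_every_tweet_is_zero_bits(self, build_corpus):
        corpus = self._corpus(build_corpus, [(1, 1), (1, 0), (1, 1), (1, 0)])
        assert information_gain("xmarker", "fatigue", corpus) == pytest.approx(0.0)

    def test_perfect_predictor_of_balanced_category_is_one_bit(self, build_corpus):
        corpus = self._corpus(build_corpus, [(1, 1), (1, 1), (0, 0), (0, 0)])
        assert information_gain("xmarker", "fatigue", corpus) == pytest.approx(1.0)

    def test_six_tweet_fixture_matches_oracle(self, build_corpus):
        rows = [(1, 1), (1, 1), (0, 1), (1, 0), (0, 0), (0, 0)]
        corpus = self._corpus(build_corpus, rows)
        assert information_gain("xmarker", "fatigue", corpus) == pytest.approx(
            ig_oracle(rows), abs=1e-12
        )

    def test_unknown_category_rejected(self, build_corpus):
        corpus = self._corpus(build_corpus, [(1, 1), (0, 0)])
        with pytest.raises(KeyError):
            information_gain("xmarker", "sadness", corpus)

    @given(
        st.lists(
            st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=2, max_size=30
        )
    )
    def test_matches_oracle_and_bounds(self, build_corpus, rows):
        corpus = self._corpus(build_corpus, rows)
        ig = information_gain("xmarker", "fatigue", corpus)
        assert ig == pytest.approx(ig_oracle(rows), abs=1e-12)
        h_c = ig_oracle([(y, y) for _, y in rows])
        h_w = ig_oracle([(w, w) for w, _ in rows])
        assert -1e-12 <= ig <= min(h_c, h_w) + 1e-12


def planted_corpus(build_corpus, n=400, seed=9):
    """Positives carry 'xsleepword' plus noise; negatives only noise."""
    import numpy as np

    rng = np.random.default_rng(seed)
    noise = ["night", "day", "coffee", "game", "work", "rain"]
    records = []
    for i in range(n):
        positive = rng.random() < 0.15
        words = list(rng.choice(noise, size=6))
        if positive:
            words.append("xsleepword")
        rng.shuffle(words)
        cat = "disturbed_sleep" if positive else "no_evidence"
        records.append((f"t{i}", " ".join(words), {GOLD: [cat]}))
    return build_corpus(records)


class TestTopWords:
    def test_planted_word_ranks_first(self, build_corpus):
        corpus = planted_corpus(build_corpus)
        scores = top_words(corpus, "disturbed_sleep", k=5, seed=1)
        assert scores[0].word == "xsleepword"
        assert scores[0].avg_rank == 1.0

    def test_k_larger_than_vocabulary(self, build_corpus):
        corpus = planted_corpus(build_corpus, n=60)
        scores = top_words(corpus, "disturbed_sleep", k=10_000, seed=1)
        vocab = set()
        for t in corpus.tweets:
            vocab.update(tokenize(t.text))
        assert len(scores) == len(vocab)

    def test_too_few_mentions_skipped(self, build_corpus):
        corpus = build_corpus(
            [
                ("t1", "xw a", {GOLD: ["weather"]}),
                ("t2", "b c", {GOLD: ["no_evidence"]}),
                ("t3", "d e", {GOLD: ["no_evidence"]}),
            ]
        )
        assert top_words(corpus, "weather", min_mentions=3) is SKIPPED

    def test_deterministic_and_order_invariant(self, build_corpus):
        corpus = planted_corpus(build_corpus)
        reversed_corpus = build_corpus(
            [
                (t.tweet_id, t.text, {GOLD: sorted(corpus.gold_labels(t.tweet_id))})
                for t in reversed(corpus.tweets)
            ]
        )
        a = top_words(corpus, "disturbed_sleep", k=8, seed=3)
        b = top_words(corpus, "disturbed_sleep", k=8, seed=3)
        c = top_words(reversed_corpus, "disturbed_sleep", k=8, seed=3)
        assert a == b == c  # same seed, any tweet order

    def test_seed_changes_subsets_not_planted_winner(self, build_corpus):
        corpus = planted_corpus(build_corpus)
        for seed in (1, 2, 3):
            assert top_words(corpus, "disturbed_sleep", k=1, seed=seed)[0].word == "xsleepword"


class TestLexiconOverlap:
    def test_wildcard_covers_inflection(self, lexicon):
        covered, n = lexicon_overlap(["depressed", "examweek"], lexicon)
        assert covered == ["depressed"]
        assert n == 1

    def test_empty_input(self, lexicon):
        assert lexicon_overlap([], lexicon) == ([], 0)

    def test_accepts_word_scores(self, build_corpus, lexicon):
        corpus = planted_corpus(build_corpus)
        scores = top_words(corpus, "disturbed_sleep", k=5, seed=1)
        covered, n = lexicon_overlap(scores, lexicon)
        assert "xsleepword" not in covered
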