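"""Tokenization and information-gain ranking of words per category.

Information gain here is the mutual information (in bits) between binary
word presence and a one-vs-rest category indicator::

    IG(w, c) = H(C) - P(w) H(C | w) - P(!w) H(C | !w)

with the convention 0*log(0) = 0.  Words are ranked per category by IG
within each of 5 seeded random subsets of the corpus, and the final order
is by ascending *average rank* across subsets (lower = more
characteristic), with lexicographic tie-breaks.  Subset membership is
keyed by a hash of (seed, tweet_id), never by position, so permuting the
corpus does not change results.

Stopwords are deliberately not removed: on short personal texts, function
words (personal pronouns especially) are themselves informative.
"""

from __future__ import annotations

import hashlib
import re
import string
from dataclasses import dataclass

import numpy as np

from .corpus import AnnotatedCorpus
from .lexicon import Lexicon

__all__ = [
    "SKIPPED",
    "TokenizedTweet",
    "WordScore",
    "tokenize",
    "information_gain",
    "top_words",
    "lexicon_overlap",
]

_URL_RE = re.compile(r"^(https?://|www\.)", re.IGNORECASE)
_STRIP_CHARS = string.punctuation
_STRIP_LEAD = _STRIP_CHARS.replace("#", "")  # '#' survives at the front of hashtags


class _Skipped:
    """Sentinel: category had too few positive tweets to rank words."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "SKIPPED"


SKIPPED = _Skipped()


@dataclass(frozen=True)
class TokenizedTweet:
    tweet_id: str
    tokens: tuple[str, ...]


def tokenize(text: str) -> list[str]:
    """Normalize a short text into lowercase tokens.

    Whitespace-split; URLs become ``<url>`` and @-mentions ``<user>``;
    leading/trailing punctuation is stripped except a leading ``#``
    (hashtags survive intact); internal punctuation (apostrophes) is kept.
    Degenerate input may yield an empty list.
    """
    tokens: list[str] = []
    for raw in text.lower().split():
        if _URL_RE.match(raw):
            tokens.append("<url>")
            continue
        if raw.startswith("@") and len(raw) > 1:
            tokens.append("<user>")
            continue
        tok = raw.lstrip(_STRIP_LEAD).rstrip(_STRIP_CHARS)
        if tok and tok != "#":
            tokens.append(tok)
    return tokens


def _entropy(counts: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) of rows of nonnegative counts; 0 log 0 = 0."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, counts / np.where(total > 0, total, 1.0), 0.0)
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -(p * logp).sum(axis=-1)


def _ig_from_counts(n11, n10, n01, n00):
    """Vectorized IG (bits) from the four cells of word x category tables.

    n11: word present & positive, n10: present & negative,
    n01: absent & positive,  n00: absent & negative.
    """
    n11, n10, n01, n00 = (np.asarray(a, dtype=float) for a in (n11, n10, n01, n00))
    n = n11 + n10 + n01 + n00
    h_c = _entropy(np.stack([n11 + n01, n10 + n00], axis=-1))
    n_w = n11 + n10
    n_nw = n01 + n00
    h_c_w = _entropy(np.stack([n11, n10], axis=-1))
    h_c_nw = _entropy(np.stack([n01, n00], axis=-1))
    ig = h_c - (n_w / n) * h_c_w - (n_nw / n) * h_c_nw
    return np.maximum(ig, 0.0)  # clip the odd -1e-16 from float round-off


def _presence(tweets, vocab: list[str] | None = None):
    """Binary presence matrix (tweets x vocab) and the vocabulary used."""
    token_sets = [set(tokenize(t.text)) for t in tweets]
    if vocab is None:
        vocab = sorted(set().union(*token_sets)) if token_sets else []
    col = {w: j for j, w in enumerate(vocab)}
    x = np.zeros((len(tweets), len(vocab)), dtype=np.int8)
    for i, toks in enumerate(token_sets):
        for w in toks:
            j = col.get(w)
            if j is not None:
                x[i, j] = 1
    return x, vocab


def _positive_vector(corpus: AnnotatedCorpus, category: str, tweets) -> np.ndarray:
    no_ev = corpus.scheme.no_evidence
    if category not in corpus.scheme or category == no_ev:
        raise KeyError(f"category must be one of the 21 evidence labels, got {category!r}")
    return np.array(
        [1 if category in corpus.gold_labels(t.tweet_id) else 0 for t in tweets], dtype=np.int8
    )


def information_gain(word: str, category: str, corpus: AnnotatedCorpus) -> float:
    """IG (bits) of one word for one one-vs-rest category, over gold labels."""
    if len(corpus.tweets) < 2:
        raise ValueError("need at least 2 tweets")
    if not corpus.has_gold():
        raise ValueError("corpus has no GOLD annotations")
    y = _positive_vector(corpus, category, corpus.tweets)
    present = np.array(
        [1 if word in set(tokenize(t.text)) else 0 for t in corpus.tweets], dtype=np.int8
    )
    n11 = int(np.sum(present & y))
    n10 = int(np.sum(present & (1 - y)))
    n01 = int(np.sum((1 - present) & y))
    n00 = int(np.sum((1 - present) & (1 - y)))
    return float(_ig_from_counts(n11, n10, n01, n00))


@dataclass(frozen=True)
class WordScore:
    word: str
    category: str
    ig_bits: float
    rank_per_subset: tuple[int, ...]
    avg_rank: float


def _subset_assignment(tweet_ids: list[str], n_subsets: int, seed: int) -> dict[str, int]:
    """Equal-sized random partition, stable under corpus reordering.

    Tweets are ordered by a salted SHA-256 of (seed, tweet_id) and chunked;
    subset sizes differ by at most one.
    """
    def key(tid: str) -> str:
        return hashlib.sha256(f"{seed}:{tid}".encode()).hexdigest()

    ordered = sorted(tweet_ids, key=key)
    size = len(ordered)
    assignment: dict[str, int] = {}
    for rank, tid in enumerate(ordered):
        assignment[tid] = rank * n_subsets // size if size else 0
    return assignment


def top_words(
    corpus: AnnotatedCorpus,
    category: str,
    k: int = 10,
    n_subsets: int = 5,
    seed: int = 0,
    min_mentions: int = 3,
):
    """Top-k words for a category by average IG rank over random subsets.

    Returns a list of :class:`WordScore` sorted by ascending average rank
    (ties broken lexicographically), or the :data:`SKIPPED` sentinel when
    the category has fewer than ``min_mentions`` positive gold tweets.
    Words absent from a subset's vocabulary take rank = subset vocabulary
    size + 1 in that subset.
    """
    if not corpus.has_gold():
        raise ValueError("corpus has no GOLD annotations")
    tweets = corpus.tweets
    y_all = _positive_vector(corpus, category, tweets)
    if int(y_all.sum()) < min_mentions:
        return SKIPPED

    assignment = _subset_assignment([t.tweet_id for t in tweets], n_subsets, seed)
    x_all, vocab = _presence(tweets)
    word_index = {w: j for j, w in enumerate(vocab)}
    ranks = np.zeros((n_subsets, len(vocab)))
    subset_of = np.array([assignment[t.tweet_id] for t in tweets])
    for s in range(n_subsets):
        mask = subset_of == s
        xs, ys = x_all[mask], y_all[mask]
        present_words = xs.any(axis=0)
        sub_vocab_size = int(present_words.sum())
        n11 = (xs * ys[:, None]).sum(axis=0)
        n10 = (xs * (1 - ys)[:, None]).sum(axis=0)
        n01 = ys.sum() - n11
        n00 = (1 - ys).sum() - n10
        ig = _ig_from_counts(n11, n10, n01, n00)
        order = sorted(
            (j for j in range(len(vocab)) if present_words[j]),
            key=lambda j: (-ig[j], vocab[j]),
        )
        ranks[s, :] = sub_vocab_size + 1
        for pos, j in enumerate(order, start=1):
            ranks[s, j] = pos
    avg = ranks.mean(axis=0)

    # corpus-level IG, reported alongside the ranking
    n11 = (x_all * y_all[:, None]).sum(axis=0)
    n10 = (x_all * (1 - y_all)[:, None]).sum(axis=0)
    ig_full = _ig_from_counts(n11, n10, y_all.sum() - n11, (1 - y_all).sum() - n10)

    ordered = sorted(vocab, key=lambda w: (avg[word_index[w]], w))
    out = [
        WordScore(
            word=w,
            category=category,
            ig_bits=float(ig_full[word_index[w]]),
            rank_per_subset=tuple(int(r) for r in ranks[:, word_index[w]]),
            avg_rank=float(avg[word_index[w]]),
        )
        for w in ordered[:k]
    ]
    return out


def lexicon_overlap(words, lexicon: Lexicon):
    """Which ranked words are already covered by a lexicon pattern.

    ``words`` may be strings or :class:`WordScore` records.  A word is
    covered iff some unique lexicon pattern matches it under whole-token
    semantics.  Returns ``(covered_words, count)``.
    """
    unique = lexicon.unique_patterns()
    covered = []
    for w in words:
        token = w.word if isinstance(w, WordScore) else w
        if any(p.matches(token) for p in unique):
            covered.append(token)
    return covered, len(covered)
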