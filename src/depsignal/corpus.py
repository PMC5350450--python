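"""Data model and JSON-lines readers/writers for annotated tweet corpora.

A corpus is a list of tweets plus a flat list of (tweet, annotator,
category) annotations against a fixed :class:`~depsignal.scheme.CategoryScheme`.
Gold (adjudicated) labels use the reserved annotator id ``GOLD``.

Serialization is one JSON object per line::

    {"id": "t1", "text": "...", "source": "synthetic",
     "labels": {"A1": ["depressed_mood"], "GOLD": ["no_evidence"]}}

Lines starting with ``#`` are treated as comments.  An annotator listed
with an empty label list receives a ``no_evidence`` annotation when
``infer_no_evidence`` is on (the default), since the no-evidence label is
by definition what an annotator asserts by asserting nothing else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .scheme import DEFAULT_SCHEME, CategoryScheme

GOLD = "GOLD"

__all__ = ["GOLD", "Tweet", "CategoryAnnotation", "AnnotatedCorpus", "read_corpus", "write_corpus"]


@dataclass(frozen=True)
class Tweet:
    tweet_id: str
    text: str
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"tweet {self.tweet_id!r}: text must be non-empty")


@dataclass(frozen=True, order=True)
class CategoryAnnotation:
    tweet_id: str
    annotator_id: str
    category: str


class AnnotatedCorpus:
    """Validated tweets + annotations.

    Invariants enforced at construction:

    * tweet ids are unique; every annotation references an existing tweet
      and a scheme category;
    * duplicate (tweet, annotator, category) triples are rejected;
    * per annotator and tweet, ``no_evidence`` is mutually exclusive with
      every other label.
    """

    def __init__(
        self,
        tweets: Iterable[Tweet],
        annotations: Iterable[CategoryAnnotation],
        scheme: CategoryScheme = DEFAULT_SCHEME,
    ):
        self.tweets: list[Tweet] = list(tweets)
        self.annotations: list[CategoryAnnotation] = list(annotations)
        self.scheme = scheme

        ids = [t.tweet_id for t in self.tweets]
        self._tweets_by_id: dict[str, Tweet] = {t.tweet_id: t for t in self.tweets}
        if len(self._tweets_by_id) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValueError(f"duplicate tweet ids: {sorted(dupes)[:5]}")

        seen: set[CategoryAnnotation] = set()
        labels: dict[tuple[str, str], set[str]] = {}
        for a in self.annotations:
            if a.tweet_id not in self._tweets_by_id:
                raise ValueError(f"annotation references unknown tweet {a.tweet_id!r}")
            if a.category not in scheme:
                raise ValueError(f"unknown category {a.category!r} on tweet {a.tweet_id!r}")
            if a in seen:
                raise ValueError(
                    f"duplicate annotation ({a.tweet_id!r}, {a.annotator_id!r}, {a.category!r})"
                )
            seen.add(a)
            labels.setdefault((a.tweet_id, a.annotator_id), set()).add(a.category)
        for (tid, aid), cats in labels.items():
            if scheme.no_evidence in cats and len(cats) > 1:
                raise ValueError(
                    f"annotator {aid!r} mixes no_evidence with other labels on tweet {tid!r}"
                )
        self._labels = labels

    # -- queries -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.tweets)

    def tweet(self, tweet_id: str) -> Tweet:
        return self._tweets_by_id[tweet_id]

    def annotators(self) -> list[str]:
        """Annotator ids in first-appearance order."""
        out: list[str] = []
        for a in self.annotations:
            if a.annotator_id not in out:
                out.append(a.annotator_id)
        return out

    def labels(self, tweet_id: str, annotator_id: str) -> frozenset[str]:
        """Label set one annotator asserted on one tweet (empty if unseen)."""
        return frozenset(self._labels.get((tweet_id, annotator_id), frozenset()))

    def annotated_tweet_ids(self, annotator_id: str) -> set[str]:
        return {tid for (tid, aid) in self._labels if aid == annotator_id}

    def assertions(self, annotator_id: str) -> set[tuple[str, str]]:
        """All (tweet_id, category) assertions by one annotator."""
        return {
            (a.tweet_id, a.category) for a in self.annotations if a.annotator_id == annotator_id
        }

    def has_gold(self) -> bool:
        return any(a.annotator_id == GOLD for a in self.annotations)

    def gold_labels(self, tweet_id: str) -> frozenset[str]:
        return self.labels(tweet_id, GOLD)

    def with_annotations(self, extra: Iterable[CategoryAnnotation]) -> "AnnotatedCorpus":
        """A new corpus with additional annotations (tweets shared)."""
        return AnnotatedCorpus(self.tweets, list(self.annotations) + list(extra), self.scheme)

    # -- equality (used by round-trip contracts) ---------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedCorpus):
            return NotImplemented
        return (
            self.tweets == other.tweets
            and sorted(self.annotations) == sorted(other.annotations)
            and self.scheme == other.scheme
        )

    # -- tabular export ----------------------------------------------------

    def annotation_frame(self):
        """Flat (tweet_id, annotator, category) triples as a DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            [(a.tweet_id, a.annotator_id, a.category) for a in self.annotations],
            columns=["tweet_id", "annotator", "category"],
        )


def read_corpus(
    path: str | Path,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    *,
    infer_no_evidence: bool = True,
) -> AnnotatedCorpus:
    """Read a JSON-lines corpus file.

    Errors name the offending line: unknown category labels, duplicate
    tweet ids (caught by corpus validation) and malformed JSON all raise
    ``ValueError``.
    """
    path = Path(path)
    tweets: list[Tweet] = []
    annotations: list[CategoryAnnotation] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path.name}:{lineno}: invalid JSON: {exc}") from exc
            try:
                tweet = Tweet(
                    tweet_id=str(rec["id"]),
                    text=rec["text"],
                    source=rec.get("source", "synthetic"),
                )
            except KeyError as exc:
                raise ValueError(f"{path.name}:{lineno}: missing field {exc}") from exc
            tweets.append(tweet)
            for annotator, cats in rec.get("labels", {}).items():
                if not cats and infer_no_evidence:
                    cats = [scheme.no_evidence]
                for cat in cats:
                    if cat not in scheme:
                        raise ValueError(
                            f"{path.name}:{lineno}: unknown category {cat!r} "
                            f"(annotator {annotator!r})"
                        )
                    annotations.append(
                        CategoryAnnotation(tweet.tweet_id, annotator, cat)
                    )
    return AnnotatedCorpus(tweets, annotations, scheme)


def write_corpus(corpus: AnnotatedCorpus, path: str | Path) -> Path:
    """Write a corpus as JSON-lines; inverse of :func:`read_corpus`."""
    path = Path(path)
    by_tweet: dict[str, dict[str, list[str]]] = {t.tweet_id: {} for t in corpus.tweets}
    for a in corpus.annotations:
        by_tweet[a.tweet_id].setdefault(a.annotator_id, []).append(a.category)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# depsignal annotated corpus (JSON lines)\n")
        for t in corpus.tweets:
            labels = {aid: sorted(cats) for aid, cats in sorted(by_tweet[t.tweet_id].items())}
            rec = {"id": t.tweet_id, "text": t.text, "source": t.source, "labels": labels}
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    return path
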