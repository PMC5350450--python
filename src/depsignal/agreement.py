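"""Pairwise inter-annotator agreement (F score) and adjudication.

Agreement between two annotators is measured without assuming either is
the truth: over the tweets both annotated, a *match* is a (tweet, category)
assertion made by both; a *type-1 mismatch* is an assertion made only by
the first annotator, a *type-2 mismatch* one made only by the second.  The
F score is then::

    F = 2 * matches / (2 * matches + mismatches) * 100%

which equals the harmonic-mean F1 of treating either annotator as
reference for the other (and is therefore symmetric).  No chance
correction is applied.  The "overall" score is micro-averaged: counts are
pooled across all categories (including no-evidence) before the single
formula application, so overall counts equal the sum of per-category
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .corpus import GOLD, AnnotatedCorpus, CategoryAnnotation

logger = logging.getLogger(__name__)

#: Pool all categories, including no-evidence (the Table-3-style "overall").
ALL = "ALL"
#: Pool the 21 evidence categories only.
EVIDENCE = "EVIDENCE"


class _NotObserved:
    """Sentinel for a category with no assertions by either annotator."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NOT_OBSERVED"

    def __str__(self) -> str:
        return "—"  # em dash, the printed "not observed" marker


NOT_OBSERVED = _NotObserved()


@dataclass(frozen=True)
class AgreementCounts:
    """Match/mismatch counts for one annotator pair (category or pooled)."""

    matches: int
    type1_mismatches: int
    type2_mismatches: int

    def __post_init__(self) -> None:
        if min(self.matches, self.type1_mismatches, self.type2_mismatches) < 0:
            raise ValueError("agreement counts must be non-negative")

    @property
    def mismatches(self) -> int:
        return self.type1_mismatches + self.type2_mismatches

    def swapped(self) -> "AgreementCounts":
        """Counts from the other annotator's perspective (type1/type2 swap)."""
        return AgreementCounts(self.matches, self.type2_mismatches, self.type1_mismatches)

    def __add__(self, other: "AgreementCounts") -> "AgreementCounts":
        return AgreementCounts(
            self.matches + other.matches,
            self.type1_mismatches + other.type1_mismatches,
            self.type2_mismatches + other.type2_mismatches,
        )


def pair_counts(
    corpus: AnnotatedCorpus,
    annotator_a: str,
    annotator_b: str,
    category: str = ALL,
) -> AgreementCounts:
    """Match/mismatch counts between two annotators on co-annotated tweets.

    ``category`` may be a single scheme label, :data:`ALL` (pool every
    category including no-evidence) or :data:`EVIDENCE` (pool the 21
    evidence categories).  Tweets not annotated by both are excluded; if no
    tweet was annotated by both, an "empty comparison set" error is raised.
    """
    shared = corpus.annotated_tweet_ids(annotator_a) & corpus.annotated_tweet_ids(annotator_b)
    if not shared:
        raise ValueError(
            f"empty comparison set: no tweets co-annotated by {annotator_a!r} and {annotator_b!r}"
        )
    if category not in (ALL, EVIDENCE) and category not in corpus.scheme:
        raise KeyError(f"unknown category: {category!r}")

    def keep(cat: str) -> bool:
        if category == ALL:
            return True
        if category == EVIDENCE:
            return cat != corpus.scheme.no_evidence
        return cat == category

    a_set = {(t, c) for (t, c) in corpus.assertions(annotator_a) if t in shared and keep(c)}
    b_set = {(t, c) for (t, c) in corpus.assertions(annotator_b) if t in shared and keep(c)}
    return AgreementCounts(
        matches=len(a_set & b_set),
        type1_mismatches=len(a_set - b_set),
        type2_mismatches=len(b_set - a_set),
    )


def f_score(counts: AgreementCounts):
    """Agreement F score in percent, or NOT_OBSERVED if no assertions.

    ``F = 100 * 2m / (2m + mismatches)``.  All-zero counts mean neither
    annotator asserted the category; that renders as an em dash in reports.
    """
    denom = 2 * counts.matches + counts.mismatches
    if denom == 0:
        return NOT_OBSERVED
    return 100.0 * 2 * counts.matches / denom


def agreement_report(
    corpus: AnnotatedCorpus,
    pairs: list[tuple[str, str]] | None = None,
):
    """Per-category and overall F scores for each annotator pair.

    Returns a DataFrame with one row per category (scheme order, no-evidence
    first, then symptoms and stressors) plus an ``overall`` row, one column
    per pair; NOT_OBSERVED cells hold NaN (rendered "—" on export).
    """
    import numpy as np
    import pandas as pd

    if pairs is None:
        anns = [a for a in corpus.annotators() if a != GOLD]
        pairs = [(anns[i], anns[j]) for i in range(len(anns)) for j in range(i + 1, len(anns))]
    scheme = corpus.scheme
    rows = ["overall", scheme.no_evidence, *scheme.evidence_categories]
    out = {}
    for a, b in pairs:
        col = []
        for cat in rows:
            counts = pair_counts(corpus, a, b, ALL if cat == "overall" else cat)
            score = f_score(counts)
            col.append(np.nan if score is NOT_OBSERVED else score)
        out[f"{a}/{b}"] = col
    return pd.DataFrame(out, index=rows)


def adjudicate(
    corpus: AnnotatedCorpus,
    pair: tuple[str, str],
    adjudicator: str,
) -> list[CategoryAnnotation]:
    """Resolve disagreements between a pair by a third annotator.

    Tweets where the pair's label sets agree pass through unchanged; where
    they disagree, the adjudicator's labels win (a three-way disagreement is
    still resolved to the adjudicator and logged as an unresolved-majority
    event).  A disagreement with no adjudicator labels is an error listing
    the tweet ids.  Output annotations carry annotator id ``GOLD``.
    """
    a, b = pair
    shared = corpus.annotated_tweet_ids(a) & corpus.annotated_tweet_ids(b)
    missing: list[str] = []
    gold: list[CategoryAnnotation] = []
    for tid in sorted(shared):
        la, lb = corpus.labels(tid, a), corpus.labels(tid, b)
        if la == lb:
            chosen = la
        else:
            lc = corpus.labels(tid, adjudicator)
            if not lc:
                missing.append(tid)
                continue
            if lc != la and lc != lb:
                logger.info("unresolved majority on tweet %s: adjudicator label wins", tid)
            chosen = lc
        gold.extend(CategoryAnnotation(tid, GOLD, c) for c in sorted(chosen))
    if missing:
        raise ValueError(f"disagreements without adjudicator labels on tweets: {missing}")
    return gold


@dataclass(frozen=True)
class PhasePlan:
    """Corpus-size arithmetic for the three-phase annotation workflow.

    Phase 1: all three annotators label a common batch.  Phase 2: each of
    the three annotator pairs labels its own batch, the third adjudicating.
    Phase 3: each annotator labels an independent batch; an overlap subset
    drawn from already-annotated tweets adds reliability but no new tweets.
    """

    n_phase1: int
    n_phase2_per_pair: int
    n_phase3_per_annotator: int
    n_overlap: int = 0

    def __post_init__(self) -> None:
        for name in ("n_phase1", "n_phase2_per_pair", "n_phase3_per_annotator", "n_overlap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_unique_tweets(self) -> int:
        return self.n_phase1 + 3 * self.n_phase2_per_pair + 3 * self.n_phase3_per_annotator


def phase_plan(
    n_phase1: int,
    n_phase2_per_pair: int,
    n_phase3_per_annotator: int,
    n_overlap: int = 0,
) -> PhasePlan:
    """Build a :class:`PhasePlan`; ``.total_unique_tweets`` is the corpus size."""
    return PhasePlan(n_phase1, n_phase2_per_pair, n_phase3_per_annotator, n_overlap)
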