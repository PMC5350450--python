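"""Synthetic annotated-tweet corpora with planted, recoverable ground truth.

Real keyword-sampled tweet corpora cannot be redistributed, so every
pipeline stage is exercised against generated corpora whose relevant
parameters are planted and therefore recoverable:

* a skewed 22-way gold label distribution (~72% of annotations are
  no-evidence; symptom:stressor annotation mass ~65:35),
* pairwise category correlations: each listed (a, b, phi) target is drawn
  from the exact 2x2 joint distribution with the requested marginals and
  phi (equivalently, via a shared latent Bernoulli component); categories
  not listed in any pair are drawn independently, so a category may appear
  in at most one target pair,
* per-keyword retrieval precision: each planted lexicon keyword is
  injected into tweets so that the share of its tweets carrying evidence
  labels equals a planted relevance,
* per-category discriminative vocabulary: labeled tweets embed planted
  marker words absent elsewhere, recoverable by information-gain ranking,
* token counts drawn from a rounded normal (mean 14.56, SD 7.40 by
  default) truncated at 1,
* optional noisy annotators with known deletion/spurious-label rates, so
  expected pairwise agreement is available in closed form.

Everything is driven by one seeded generator stream: a fixed seed yields a
byte-identical corpus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus import GOLD, AnnotatedCorpus, CategoryAnnotation, Tweet
from .lexicon import Lexicon, load_lexicon
from .scheme import DEFAULT_SCHEME, CategoryScheme

__all__ = [
    "DEFAULT_PREVALENCE",
    "DEFAULT_PHI_TARGETS",
    "DEFAULT_KEYWORD_RELEVANCE",
    "AnnotatorModel",
    "GeneratorConfig",
    "GroundTruth",
    "generate_corpus",
    "corrupt_annotations",
    "expected_pairwise_f",
    "keyword_surface",
]

#: Per-category probability that a tweet carries the label.  The skew
#: mirrors the published corpus shape: total evidence mass ~0.30 per tweet
#: (so ~72% of gold annotations are no-evidence once the implied
#: no-evidence annotations are counted), symptom:stressor mass 65:35, and
#: depressed mood / fatigue / disturbed sleep the most prevalent symptoms.
#: Categories involved in the default correlation targets are kept
#: moderately prevalent so their planted phi is estimable at n = 10,000.
DEFAULT_PREVALENCE: dict[str, float] = {
    # symptoms (sum 0.195)
    "depressed_mood": 0.062,
    "anhedonia": 0.0008,
    "weight_change": 0.003,
    "disturbed_sleep": 0.042,
    "psychomotor_agitation": 0.0012,
    "fatigue": 0.052,
    "worthlessness": 0.026,
    "diminished_concentration": 0.005,
    "suicidal_ideation": 0.003,
    # stressors (sum 0.105)
    "life_course": 0.003,
    "primary_support": 0.027,
    "social_environment": 0.030,
    "educational_problems": 0.018,
    "occupational_problems": 0.005,
    "housing_problems": 0.004,
    "economic_problems": 0.008,
    "health_care_access": 0.0003,
    "legal_system": 0.0015,
    "other_psychosocial": 0.0012,
    "weather": 0.004,
    "media": 0.003,
}

#: Planted pairwise phi targets (disjoint pairs).  The pairs echo the
#: strongest published co-occurrences (fatigue with disturbed sleep,
#: depressed mood with worthlessness) plus one small stressor effect,
#: covering three Cohen magnitude bins.
DEFAULT_PHI_TARGETS: tuple[tuple[str, str, float], ...] = (
    ("fatigue", "disturbed_sleep", 0.50),
    ("depressed_mood", "worthlessness", 0.40),
    ("social_environment", "primary_support", 0.12),
)

#: Planted per-keyword relevance: probability that a tweet containing the
#: keyword carries an evidence label.  Values span the five precision bins.
DEFAULT_KEYWORD_RELEVANCE: dict[str, float] = {
    "tired": 0.10,
    "sobbing": 0.25,
    "depress*": 0.35,
    "fired": 0.55,
    "suicid*": 0.70,
    "insomnia": 0.85,
}

#: Shared background vocabulary (checked against the lexicon: none of
#: these tokens matches any keyword pattern).  Sampled with Zipf weights.
BACKGROUND_VOCAB: tuple[str, ...] = (
    "i", "the", "to", "a", "and", "you", "my", "is", "it", "in", "of", "for",
    "on", "me", "that", "this", "so", "with", "was", "at", "but", "have",
    "just", "be", "not", "are", "we", "all", "like", "up", "get", "about",
    "out", "can", "your", "when", "what", "got", "now", "day", "today",
    "time", "good", "going", "love", "really", "know", "see", "one", "back",
    "had", "from", "new", "will", "home", "night", "morning", "again",
    "people", "work", "school", "still", "then", "them", "some", "well",
    "much", "think", "right", "want", "need", "make", "way", "been", "who",
    "her", "his", "she", "he", "they", "our", "there", "here", "come",
    "over", "into", "after", "before", "never", "always", "week", "year",
    "game", "watch", "music", "song", "coffee", "food", "dinner", "lunch",
    "friend", "friends", "family", "house", "weekend", "tomorrow", "soon",
    "maybe", "thing", "things", "better", "best", "last", "first", "next",
    "off", "down", "why", "how", "where", "did", "does", "say", "said",
    "birthday", "happy", "thanks", "please", "great", "nice", "cool",
)


@dataclass(frozen=True)
class AnnotatorModel:
    """Noise model for one simulated annotator.

    ``deletion_rate``: probability each gold evidence assertion is dropped
    (a tweet left with no assertion becomes no-evidence for the annotator).
    ``spurious_rate``: probability the annotator adds one random evidence
    category a tweet does not carry.
    """

    deletion_rate: float = 0.15
    spurious_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("deletion_rate", "spurious_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _phi_bounds(pa: float, pb: float) -> tuple[float, float]:
    """Admissible phi interval (Frechet bounds) for two Bernoulli marginals."""
    qa, qb = 1.0 - pa, 1.0 - pb
    lo = max(-np.sqrt(pa * pb / (qa * qb)), -np.sqrt(qa * qb / (pa * pb)))
    hi = min(np.sqrt(pa * qb / (pb * qa)), np.sqrt(pb * qa / (pa * qb)))
    return float(lo), float(hi)


def keyword_surface(rendered: str, lexicon: Lexicon) -> str:
    """A token that matches exactly one unique lexicon pattern.

    For a literal pattern the stem itself qualifies; for a wildcard, the
    first of a few candidate inflections matching only that pattern is
    used.  Raises if every candidate is ambiguous (matches a second
    pattern), since an ambiguous token would contaminate planted
    per-keyword precision.
    """
    pattern = lexicon.pattern_by_rendered(rendered)
    candidates = [pattern.stem, pattern.stem + "e", pattern.stem + "s",
                  pattern.stem + "ed", pattern.stem + "ing", pattern.stem + "y"]
    for cand in candidates:
        matched = lexicon.matching_patterns(cand)
        if matched == [pattern]:
            return cand
    raise ValueError(f"no unambiguous surface token for pattern {rendered!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus."""

    n_tweets: int = 10_000
    prevalence: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    multilabel_rate: float = 0.0
    phi_targets: tuple[tuple[str, str, float], ...] = DEFAULT_PHI_TARGETS
    keyword_relevance: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_KEYWORD_RELEVANCE)
    )
    keyword_hit_rate: float = 0.02
    planted_words_per_category: int = 10
    words_per_tweet: int = 3
    background_vocab: tuple[str, ...] = BACKGROUND_VOCAB
    length_mean: float = 14.56
    length_sd: float = 7.40
    annotators: Mapping[str, AnnotatorModel] = field(
        default_factory=lambda: {
            "A1": AnnotatorModel(),
            "A2": AnnotatorModel(),
            "A3": AnnotatorModel(),
        }
    )
    seed: int = 0
    scheme: CategoryScheme = DEFAULT_SCHEME

    def __post_init__(self) -> None:
        if self.n_tweets < 1:
            raise ValueError("n_tweets must be >= 1")
        evidence = set(self.scheme.evidence_categories)
        if set(self.prevalence) != evidence:
            missing = evidence - set(self.prevalence)
            extra = set(self.prevalence) - evidence
            raise ValueError(f"prevalence must cover the 21 evidence categories "
                             f"(missing {sorted(missing)}, unknown {sorted(extra)})")
        for c, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence[{c!r}] must be in [0, 1], got {p}")
        if sum(self.prevalence.values()) > 1.0:
            raise ValueError("total prevalence mass must not exceed 1")
        if not 0.0 <= self.multilabel_rate <= 1.0:
            raise ValueError("multilabel_rate must be in [0, 1]")
        if not 0.0 < self.keyword_hit_rate <= 1.0:
            raise ValueError("keyword_hit_rate must be in (0, 1]")
        seen: set[str] = set()
        for a, b, target in self.phi_targets:
            for c in (a, b):
                if c not in evidence:
                    raise ValueError(f"phi target references unknown category {c!r}")
                if c in seen:
                    raise ValueError(
                        f"category {c!r} appears in more than one phi target; the "
                        "shared-latent construction requires disjoint pairs"
                    )
                seen.add(c)
            pa, pb = self.prevalence[a], self.prevalence[b]
            if pa in (0.0, 1.0) or pb in (0.0, 1.0):
                if target != 0.0:
                    raise ValueError(f"phi target for degenerate marginal ({a!r}, {b!r})")
                continue
            lo, hi = _phi_bounds(pa, pb)
            if not lo <= target <= hi:
                raise ValueError(
                    f"phi target {target} for ({a!r}, {b!r}) outside the Frechet-"
                    f"admissible interval [{lo:.3f}, {hi:.3f}] for marginals "
                    f"({pa}, {pb})"
                )
        for kw, r in self.keyword_relevance.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"keyword_relevance[{kw!r}] must be in [0, 1]")
        for name, model in self.annotators.items():
            if not isinstance(model, AnnotatorModel):
                raise ValueError(f"annotators[{name!r}] must be an AnnotatorModel")

    def planted_words(self) -> dict[str, tuple[str, ...]]:
        """Per-category planted discriminative tokens (absent elsewhere)."""
        return {
            c: tuple(f"x{c}{i}" for i in range(1, self.planted_words_per_category + 1))
            for c in self.scheme.evidence_categories
        }


@dataclass
class GroundTruth:
    """What was planted, for recovery checks downstream."""

    gold: dict  # tweet_id -> frozenset of evidence categories (may be empty)
    phi_targets: tuple
    keyword_relevance: dict  # rendered pattern -> planted relevance
    keyword_surfaces: dict  # rendered pattern -> injected token
    planted_words: dict  # category -> tuple of tokens
    evidence_rate: float  # realized share of tweets with >= 1 evidence label
    config: GeneratorConfig

    def to_json(self) -> str:
        payload = {
            "gold": {tid: sorted(cats) for tid, cats in self.gold.items()},
            "phi_targets": [list(t) for t in self.phi_targets],
            "keyword_relevance": self.keyword_relevance,
            "keyword_surfaces": self.keyword_surfaces,
            "planted_words": {c: list(w) for c, w in self.planted_words.items()},
            "evidence_rate": self.evidence_rate,
            "seed": self.config.seed,
            "n_tweets": self.config.n_tweets,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json(), encoding="utf-8")
        return path


def _sample_pair(rng: np.random.Generator, n: int, pa: float, pb: float, target: float):
    """Draw n correlated Bernoulli pairs from the exact 2x2 joint."""
    p11 = pa * pb + target * np.sqrt(pa * (1 - pa) * pb * (1 - pb))
    p10 = pa - p11
    p01 = pb - p11
    u = rng.random(n)
    x = u < p11 + p10
    y = (u < p11) | ((u >= p11 + p10) & (u < p11 + p10 + p01))
    return x, y


def generate_corpus(
    config: GeneratorConfig, lexicon: Lexicon | None = None
) -> tuple[AnnotatedCorpus, GroundTruth]:
    """Generate a gold-labeled corpus and its ground truth.

    Deterministic given ``config.seed``.  The emitted corpus contains GOLD
    annotations only; use :func:`corrupt_annotations` to add simulated
    annotators.
    """
    if lexicon is None:
        lexicon = load_lexicon()
    scheme = config.scheme
    cats = scheme.evidence_categories
    col = {c: j for j, c in enumerate(cats)}
    n = config.n_tweets
    rng = np.random.default_rng(config.seed)

    planted = config.planted_words()
    _validate_vocab_against_lexicon(config, planted, lexicon)

    # -- gold label indicators --------------------------------------------
    labels = np.zeros((n, len(cats)), dtype=bool)
    paired = set()
    for a, b, target in config.phi_targets:
        xa, xb = _sample_pair(rng, n, config.prevalence[a], config.prevalence[b], target)
        labels[:, col[a]] = xa
        labels[:, col[b]] = xb
        paired.update((a, b))
    free = [c for c in cats if c not in paired]
    for c in free:
        labels[:, col[c]] = rng.random(n) < config.prevalence[c]

    if config.multilabel_rate > 0.0 and free:
        # a labeled tweet may gain one extra (independent) category
        weights = np.array([config.prevalence[c] for c in free], dtype=float)
        if weights.sum() > 0:
            weights = weights / weights.sum()
            labeled = np.flatnonzero(labels.any(axis=1))
            gains = labeled[rng.random(labeled.size) < config.multilabel_rate]
            extra = rng.choice(len(free), size=gains.size, p=weights)
            for i, j in zip(gains, extra):
                labels[i, col[free[j]]] = True

    evidence = labels.any(axis=1)
    p_evidence = float(evidence.mean())

    # -- keyword containment, conditioned on realized evidence status -----
    surfaces = {kw: keyword_surface(kw, lexicon) for kw in config.keyword_relevance}
    h = config.keyword_hit_rate
    contains: dict[str, np.ndarray] = {}
    for kw, r in config.keyword_relevance.items():
        q1 = h * r / p_evidence if p_evidence > 0 else 0.0
        q0 = h * (1 - r) / (1 - p_evidence) if p_evidence < 1 else 0.0
        if q1 > 1.0 or q0 > 1.0:
            raise ValueError(
                f"keyword {kw!r}: hit rate {h} with relevance {r} is not achievable "
                f"at evidence rate {p_evidence:.3f}"
            )
        u = rng.random(n)
        contains[kw] = np.where(evidence, u < q1, u < q0)

    # -- token assembly ----------------------------------------------------
    lengths = np.maximum(1, np.rint(rng.normal(config.length_mean, config.length_sd, n))).astype(int)
    bg_weights = 1.0 / np.arange(1, len(config.background_vocab) + 1)
    bg_weights /= bg_weights.sum()
    kw_list = list(config.keyword_relevance)
    tweets: list[Tweet] = []
    gold_sets: dict[str, frozenset] = {}
    annotations: list[CategoryAnnotation] = []
    width = len(str(n))
    for i in range(n):
        tid = f"t{i:0{width}d}"
        required: list[str] = []
        tweet_cats = [cats[j] for j in np.flatnonzero(labels[i])]
        for c in tweet_cats:
            pool = planted[c]
            take = min(config.words_per_tweet, len(pool))
            idx = rng.choice(len(pool), size=take, replace=False)
            required.extend(pool[j] for j in idx)
        for kw in kw_list:
            if contains[kw][i]:
                required.append(surfaces[kw])
        n_bg = max(lengths[i] - len(required), 1 if not required else 0)
        bg_idx = rng.choice(len(config.background_vocab), size=n_bg, p=bg_weights)
        tokens = required + [config.background_vocab[j] for j in bg_idx]
        order = rng.permutation(len(tokens))
        text = " ".join(tokens[j] for j in order)
        tweets.append(Tweet(tweet_id=tid, text=text, source="synthetic"))
        gold_sets[tid] = frozenset(tweet_cats)
        if tweet_cats:
            annotations.extend(CategoryAnnotation(tid, GOLD, c) for c in sorted(tweet_cats))
        else:
            annotations.append(CategoryAnnotation(tid, GOLD, scheme.no_evidence))

    corpus = AnnotatedCorpus(tweets, annotations, scheme)
    truth = GroundTruth(
        gold=gold_sets,
        phi_targets=config.phi_targets,
        keyword_relevance=dict(config.keyword_relevance),
        keyword_surfaces=surfaces,
        planted_words=planted,
        evidence_rate=p_evidence,
        config=config,
    )
    return corpus, truth


def _validate_vocab_against_lexicon(config, planted, lexicon: Lexicon) -> None:
    """Planted and background tokens must not match any keyword pattern."""
    patterns = lexicon.unique_patterns()
    for word in config.background_vocab:
        if any(p.matches(word) for p in patterns):
            raise ValueError(f"background word {word!r} matches a lexicon pattern")
    for c, words in planted.items():
        for word in words:
            if any(p.matches(word) for p in patterns):
                raise ValueError(f"planted word {word!r} ({c}) matches a lexicon pattern")


def corrupt_annotations(
    corpus: AnnotatedCorpus,
    annotators: Mapping[str, AnnotatorModel] | None = None,
    seed: int = 0,
) -> list[CategoryAnnotation]:
    """Derive noisy per-annotator labels from a gold-labeled corpus.

    Each annotator independently drops each gold evidence assertion with
    their deletion rate (an empty result becomes no-evidence) and adds one
    spurious evidence category with their spurious rate.  With deletion
    rate ``d`` and no spurious labels, the expected pairwise agreement over
    evidence assertions on single-label tweets is ``F = 100 (1 - d)``; see
    :func:`expected_pairwise_f`.
    """
    if not corpus.has_gold():
        raise ValueError("corpus has no GOLD annotations")
    if annotators is None:
        annotators = {"A1": AnnotatorModel(), "A2": AnnotatorModel(), "A3": AnnotatorModel()}
    scheme = corpus.scheme
    evidence_cats = scheme.evidence_categories
    rng = np.random.default_rng(seed)
    out: list[CategoryAnnotation] = []
    for aid, model in annotators.items():
        for t in corpus.tweets:
            gold = corpus.gold_labels(t.tweet_id) - {scheme.no_evidence}
            kept = {c for c in sorted(gold) if rng.random() >= model.deletion_rate}
            if rng.random() < model.spurious_rate:
                candidates = [c for c in evidence_cats if c not in kept]
                if candidates:
                    kept.add(candidates[rng.integers(len(candidates))])
            if not kept:
                kept = {scheme.no_evidence}
            out.extend(CategoryAnnotation(t.tweet_id, aid, c) for c in sorted(kept))
    return out


def expected_pairwise_f(deletion_rate: float) -> float:
    """Closed-form expected pairwise F (percent) under pure deletion noise.

    On single-label gold tweets, two independent annotators with deletion
    rate ``d`` both keep an assertion with probability (1-d)^2 (a match)
    and exactly one keeps it with probability 2 d (1-d) (a mismatch), so

        F = 2 (1-d)^2 / (2 (1-d)^2 + 2 d (1-d)) * 100 = 100 (1 - d).
    """
    d = deletion_rate
    if not 0.0 <= d <= 1.0:
        raise ValueError("deletion_rate must be in [0, 1]")
    if d == 1.0:
        return 0.0
    return 100.0 * 2 * (1 - d) ** 2 / (2 * (1 - d) ** 2 + 2 * d * (1 - d))
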