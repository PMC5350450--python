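"""Per-keyword retrieval precision against gold labels, with 5-bin summary.

The precision of a keyword is the share of its matched tweets whose gold
label set contains at least one depression-related category (any symptom
or stressor, i.e. anything other than no-evidence)::

    precision = 100 * relevant_hits / tweet_hits

``tweet_hits`` counts distinct tweets per keyword.  The hit *distribution*
additionally counts a tweet once per distinct matching keyword
("nonmutually exclusive tweet hits"), so its denominator is the number of
times any keyword was matched in a tweet.

Precisions are classified into five equal bins; the printed integer ranges
(0-19%, 20-39%, ...) are realized as half-open real intervals at
20/40/60/80 with the top bin closed, so fractional precisions are
classifiable and integer percentages land in the printed bins.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus import AnnotatedCorpus
from .features import tokenize
from .lexicon import KeywordPattern, Lexicon

__all__ = [
    "PRECISION_BINS",
    "KeywordPrecision",
    "PrecisionResult",
    "keyword_precision",
    "bin_precision",
    "hit_distribution",
]


@dataclass(frozen=True)
class PrecisionBin:
    label: str
    lower: float  # inclusive
    upper: float  # exclusive, except the last bin which is closed at 100


#: The five bins partition [0, 100] with no gaps or overlaps.
PRECISION_BINS: tuple[PrecisionBin, ...] = (
    PrecisionBin("zero-to-poor", 0.0, 20.0),
    PrecisionBin("poor-to-low", 20.0, 40.0),
    PrecisionBin("low-to-moderate", 40.0, 60.0),
    PrecisionBin("moderate-to-high", 60.0, 80.0),
    PrecisionBin("high-to-excellent", 80.0, 100.0),
)


def bin_precision(p: float) -> str:
    """Bin label for a precision percentage in [0, 100]."""
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"precision must be in [0, 100], got {p}")
    for b in PRECISION_BINS[:-1]:
        if b.lower <= p < b.upper:
            return b.label
    return PRECISION_BINS[-1].label  # [80, 100] closed at the top


@dataclass(frozen=True)
class KeywordPrecision:
    pattern: KeywordPattern
    tweet_hits: int
    relevant_hits: int

    def __post_init__(self) -> None:
        if not 0 <= self.relevant_hits <= self.tweet_hits:
            raise ValueError("need 0 <= relevant_hits <= tweet_hits")

    @property
    def precision(self) -> float:
        return 100.0 * self.relevant_hits / self.tweet_hits

    @property
    def bin(self) -> str:
        return bin_precision(self.precision)


@dataclass(frozen=True)
class PrecisionResult:
    """Per-keyword precisions plus the keywords that matched nothing."""

    found: tuple[KeywordPrecision, ...]
    not_found: tuple[KeywordPattern, ...]

    @property
    def total_tweet_hits(self) -> int:
        """Nonmutually exclusive tweet hits (sum over keywords)."""
        return sum(kp.tweet_hits for kp in self.found)

    def by_pattern(self, rendered: str) -> KeywordPrecision:
        for kp in self.found:
            if kp.pattern.render() == rendered:
                return kp
        raise KeyError(f"no hits recorded for pattern {rendered!r}")

    def frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                (kp.pattern.render(), kp.tweet_hits, kp.relevant_hits, kp.precision, kp.bin)
                for kp in self.found
            ],
            columns=["pattern", "tweet_hits", "relevant_hits", "precision_pct", "bin"],
        )


def keyword_precision(corpus: AnnotatedCorpus, lexicon: Lexicon) -> PrecisionResult:
    """Precision of every unique lexicon keyword against gold labels.

    A tweet is *relevant* for a keyword iff its gold label set contains at
    least one non-no-evidence category.  Keywords matching zero tweets are
    reported separately in ``not_found``.  Requires gold annotations.
    """
    if not corpus.has_gold():
        raise ValueError("corpus has no GOLD annotations; adjudicate or generate gold first")
    unique = lexicon.unique_patterns()
    hits: dict[KeywordPattern, set[str]] = {p: set() for p in unique}
    for t in corpus.tweets:
        for token in set(tokenize(t.text)):
            for p in unique:
                if p.matches(token):
                    hits[p].add(t.tweet_id)
    no_ev = corpus.scheme.no_evidence
    found: list[KeywordPrecision] = []
    not_found: list[KeywordPattern] = []
    for p in unique:
        tweet_ids = hits[p]
        if not tweet_ids:
            not_found.append(p)
            continue
        relevant = sum(
            1 for tid in tweet_ids if any(c != no_ev for c in corpus.gold_labels(tid))
        )
        found.append(KeywordPrecision(pattern=p, tweet_hits=len(tweet_ids), relevant_hits=relevant))
    return PrecisionResult(found=tuple(found), not_found=tuple(not_found))


def hit_distribution(precisions: list[KeywordPrecision] | PrecisionResult):
    """Per-bin tweet-hit counts and proportions.

    Returns a DataFrame indexed by bin label with columns ``tweet_hits``
    and ``proportion``; proportions sum to 1 over the bins and counts sum
    to the total nonmutually exclusive tweet hits.
    """
    import pandas as pd

    if isinstance(precisions, PrecisionResult):
        precisions = list(precisions.found)
    if not precisions:
        raise ValueError("empty precision list")
    counts = {b.label: 0 for b in PRECISION_BINS}
    for kp in precisions:
        counts[kp.bin] += kp.tweet_hits
    total = sum(counts.values())
    df = pd.DataFrame(
        {"tweet_hits": list(counts.values())}, index=pd.Index(counts.keys(), name="bin")
    )
    df["proportion"] = df["tweet_hits"] / total
    return df


def plot_hit_distribution(distribution, path) -> None:
    """Bar chart of tweet hits by precision bin (saved to ``path``)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(distribution.index, distribution["tweet_hits"], color="0.2")
    ax.set_xlabel("keyword precision bin")
    ax.set_ylabel("tweet hits")
    ax.set_title("Distribution of tweet hits by keyword precision")
    plt.setp(ax.get_xticklabels(), rotation=20, ha="right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
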