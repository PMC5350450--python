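"""Category frequency, multi-label distribution, and phi co-occurrence.

Frequencies are computed over gold *annotation instances* (a tweet with
two categories contributes two annotations) while the multi-label
distribution is over tweets.  Co-occurrence between the 21 evidence
categories uses the phi coefficient -- the Pearson product-moment
correlation of two binary indicators, algebraically::

    phi = (n11*n00 - n10*n01) / sqrt(n1. * n0. * n.1 * n.0)

Magnitudes are classified with Cohen effect-size bins.  The printed
criteria leave (0.09, 0.1) uncovered; the realized partition closes that
gap at 0.1 with half-open intervals: [0, 0.1) less-than-small, [0.1, 0.3)
small-to-medium, [0.3, 0.5) medium-to-large, [0.5, 1] greater-than-large.
Binning uses |r|; signs are reported in the matrix.  Two-sided P values
(from the t transform) are computed for reference but never used for
binning, because they conflate effect size with sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agreement import NOT_OBSERVED
from .corpus import AnnotatedCorpus

__all__ = [
    "COHEN_BINS",
    "FrequencyReport",
    "PhiMatrix",
    "frequency_report",
    "indicator_matrix",
    "phi",
    "phi_pvalue",
    "cohen_bin",
    "phi_matrix",
    "heatmap",
]


@dataclass(frozen=True)
class FrequencyReport:
    total_annotations: int
    per_category: dict  # category -> (count, percentage of annotations)
    no_evidence_count: int
    evidence_count: int
    symptom_count: int
    stressor_count: int
    multilabel: dict  # 1 / 2 / 3 -> tweet counts (3 means ">= 3")
    n_tweets: int

    @property
    def no_evidence_pct(self) -> float:
        return 100.0 * self.no_evidence_count / self.total_annotations

    @property
    def evidence_pct(self) -> float:
        return 100.0 * self.evidence_count / self.total_annotations

    @property
    def symptom_pct(self) -> float:
        return 100.0 * self.symptom_count / self.total_annotations

    @property
    def stressor_pct(self) -> float:
        return 100.0 * self.stressor_count / self.total_annotations

    def to_dict(self) -> dict:
        return {
            "n_tweets": self.n_tweets,
            "total_annotations": self.total_annotations,
            "no_evidence": {"count": self.no_evidence_count, "pct": self.no_evidence_pct},
            "evidence": {"count": self.evidence_count, "pct": self.evidence_pct},
            "symptoms": {"count": self.symptom_count, "pct": self.symptom_pct},
            "stressors": {"count": self.stressor_count, "pct": self.stressor_pct},
            "per_category": {
                c: {"count": n, "pct": p} for c, (n, p) in self.per_category.items()
            },
            "multilabel_tweets": {str(k): v for k, v in self.multilabel.items()},
        }


def frequency_report(corpus: AnnotatedCorpus) -> FrequencyReport:
    """Gold category frequencies, evidence/group splits and multi-label counts."""
    from .scheme import Group

    if len(corpus.tweets) == 0:
        raise ValueError("empty corpus")
    if not corpus.has_gold():
        raise ValueError("corpus has no GOLD annotations")
    scheme = corpus.scheme
    counts = {c: 0 for c in scheme.categories}
    multilabel = {1: 0, 2: 0, 3: 0}
    for t in corpus.tweets:
        labels = corpus.gold_labels(t.tweet_id)
        for c in labels:
            counts[c] += 1
        if labels:
            multilabel[min(len(labels), 3)] += 1
    total = sum(counts.values())
    sym = sum(counts[c] for c in scheme.categories if scheme.group(c) is Group.SYMPTOM)
    stress = sum(counts[c] for c in scheme.categories if scheme.group(c) is Group.STRESSOR)
    no_ev = counts[scheme.no_evidence]
    return FrequencyReport(
        total_annotations=total,
        per_category={c: (n, 100.0 * n / total) for c, n in counts.items()},
        no_evidence_count=no_ev,
        evidence_count=total - no_ev,
        symptom_count=sym,
        stressor_count=stress,
        multilabel=multilabel,
        n_tweets=len(corpus.tweets),
    )


def indicator_matrix(corpus: AnnotatedCorpus):
    """Tweets x 21 binary DataFrame of gold evidence-category indicators.

    A no-evidence-only tweet is an all-zero row; row sums reproduce the
    evidence-label counts of the multi-label distribution.
    """
    import pandas as pd

    if not corpus.has_gold():
        raise ValueError("corpus has no GOLD annotations")
    cats = corpus.scheme.evidence_categories
    data = np.zeros((len(corpus.tweets), len(cats)), dtype=np.int8)
    col = {c: j for j, c in enumerate(cats)}
    for i, t in enumerate(corpus.tweets):
        for c in corpus.gold_labels(t.tweet_id):
            if c in col:
                data[i, col[c]] = 1
    return pd.DataFrame(data, index=[t.tweet_id for t in corpus.tweets], columns=list(cats))


def _table(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = int(np.sum((x == 0) & (y == 0)))
    return n11, n10, n01, n00


def phi(x, y):
    """Phi coefficient of two equal-length binary vectors.

    Returns :data:`~depsignal.agreement.NOT_OBSERVED` when either margin
    has zero variance (a constant vector has no correlation).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    n11, n10, n01, n00 = _table(x, y)
    r1, r0 = n11 + n10, n01 + n00  # x margins
    c1, c0 = n11 + n01, n10 + n00  # y margins
    if r1 == 0 or r0 == 0 or c1 == 0 or c0 == 0:
        return NOT_OBSERVED
    return (n11 * n00 - n10 * n01) / np.sqrt(float(r1) * r0 * c1 * c0)


def phi_pvalue(r: float, n: int) -> float:
    """Two-sided P value for a correlation via the t transform."""
    from scipy import stats

    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


@dataclass(frozen=True)
class CohenBin:
    label: str
    lower: float  # inclusive, on |r|
    upper: float  # exclusive, except the last bin closed at 1


COHEN_BINS: tuple[CohenBin, ...] = (
    CohenBin("less-than-small", 0.0, 0.1),
    CohenBin("small-to-medium", 0.1, 0.3),
    CohenBin("medium-to-large", 0.3, 0.5),
    CohenBin("greater-than-large", 0.5, 1.0),
)


def cohen_bin(r: float) -> str:
    """Cohen effect-size bin for a correlation coefficient (binned on |r|)."""
    m = abs(r)
    if m > 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    for b in COHEN_BINS[:-1]:
        if b.lower <= m < b.upper:
            return b.label
    return COHEN_BINS[-1].label


@dataclass
class PhiMatrix:
    """Symmetric phi matrix over the 21 evidence categories.

    ``r`` holds NaN where a pair is not observed (a category never
    annotated); ``observed`` is the boolean mask of defined cells;
    ``effect_bin`` holds Cohen bin labels (empty string where undefined);
    ``p`` holds two-sided P values for reference.
    """

    labels: tuple
    r: "object"  # DataFrame
    observed: "object"  # DataFrame[bool]
    effect_bin: "object"  # DataFrame[str]
    p: "object"  # DataFrame

    def pairs(self, min_abs: float = 0.0):
        """Long-form DataFrame of the off-diagonal upper triangle."""
        import pandas as pd

        rows = []
        for i, a in enumerate(self.labels):
            for b in self.labels[i + 1 :]:
                if not bool(self.observed.loc[a, b]):
                    continue
                val = float(self.r.loc[a, b])
                if abs(val) >= min_abs:
                    rows.append((a, b, val, self.effect_bin.loc[a, b], float(self.p.loc[a, b])))
        return pd.DataFrame(rows, columns=["category_a", "category_b", "phi", "effect_bin", "p"])

    def bin_counts(self) -> dict:
        """Number of observed off-diagonal pairs per Cohen bin."""
        out = {b.label: 0 for b in COHEN_BINS}
        for i, a in enumerate(self.labels):
            for b in self.labels[i + 1 :]:
                if bool(self.observed.loc[a, b]):
                    out[str(self.effect_bin.loc[a, b])] += 1
        return out


def phi_matrix(corpus: AnnotatedCorpus) -> PhiMatrix:
    """Pairwise phi over the 21 evidence categories of a gold-labeled corpus."""
    import pandas as pd

    ind = indicator_matrix(corpus)
    labels = tuple(ind.columns)
    k = len(labels)
    n = len(ind)
    r = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    obs = np.zeros((k, k), dtype=bool)
    bins = np.full((k, k), "", dtype=object)
    cols = [ind[c].to_numpy() for c in labels]
    for i in range(k):
        for j in range(i, k):
            val = phi(cols[i], cols[j])
            if val is NOT_OBSERVED:
                continue
            r[i, j] = r[j, i] = val
            obs[i, j] = obs[j, i] = True
            bins[i, j] = bins[j, i] = cohen_bin(val)
            pval[i, j] = pval[j, i] = phi_pvalue(val, n)
    idx = pd.Index(labels)
    return PhiMatrix(
        labels=labels,
        r=pd.DataFrame(r, index=idx, columns=idx),
        observed=pd.DataFrame(obs, index=idx, columns=idx),
        effect_bin=pd.DataFrame(bins, index=idx, columns=idx),
        p=pd.DataFrame(pval, index=idx, columns=idx),
    )


def heatmap(matrix: PhiMatrix, path) -> None:
    """Render the co-occurrence matrix colored by Cohen effect bin.

    Axes are indexed 1..21 in scheme order (darker = larger effect);
    not-observed cells share the background color.  Deterministic given
    the matrix.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    k = len(matrix.labels)
    level = np.zeros((k, k))
    for i, a in enumerate(matrix.labels):
        for j, b in enumerate(matrix.labels):
            if bool(matrix.observed.loc[a, b]):
                label = str(matrix.effect_bin.loc[a, b])
                level[i, j] = 1 + [c.label for c in COHEN_BINS].index(label)
    cmap = ListedColormap(["#f7f7f7", "#d9d9d9", "#969696", "#525252", "#000000"])
    fig, ax = plt.subplots(figsize=(8, 7))
    ax.imshow(level, cmap=cmap, vmin=0, vmax=4)
    ticks = np.arange(k)
    ax.set_xticks(ticks, labels=[str(i + 1) for i in ticks], fontsize=7)
    ax.set_yticks(ticks, labels=[f"{lab}={i + 1}" for i, lab in enumerate(matrix.labels)], fontsize=7)
    ax.set_title("Category co-occurrence (darker = larger Cohen effect)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
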