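"""Pairwise agreement counts, F scores, adjudication and phase arithmetic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from depsignal.agreement import (
    ALL,
    EVIDENCE,
    NOT_OBSERVED,
    AgreementCounts,
    adjudicate,
    agreement_report,
    f_score,
    pair_counts,
    phase_plan,
)
from depsignal.corpus import GOLD
from depsignal.scheme import DEFAULT_SCHEME

CATS = DEFAULT_SCHEME.evidence_categories[:5]


class TestPairCounts:
    def test_identical_annotations(self, build_corpus):
        records = [(f"t{i}", "w", {"A1": ["fatigue"], "A2": ["fatigue"]}) for i in range(10)]
        c = pair_counts(build_corpus(records), "A1", "A2")
        assert (c.matches, c.mismatches) == (10, 0)

    def test_disjoint_label_sets(self, build_corpus):
        records = [
            (f"t{i}", "w", {"A1": ["fatigue"], "A2": ["depressed_mood"]}) for i in range(4)
        ]
        c = pair_counts(build_corpus(records), "A1", "A2")
        assert c.matches == 0
        assert c.type1_mismatches == c.type2_mismatches == 4

    def test_single_disagreement_counts_both_directions(self, build_corpus):
        corpus = build_corpus([("t1", "w", {"A1": ["fatigue"], "A2": ["weather"]})])
        c = pair_counts(corpus, "A1", "A2")
        assert (c.matches, c.type1_mismatches, c.type2_mismatches) == (0, 1, 1)

    def test_non_coannotated_tweets_excluded(self, build_corpus):
        corpus = build_corpus(
            [
                ("t1", "w", {"A1": ["fatigue"], "A2": ["fatigue"]}),
                ("t2", "w", {"A1": ["weather"]}),  # A2 never saw t2
            ]
        )
        c = pair_counts(corpus, "A1", "A2")
        assert (c.matches, c.mismatches) == (1, 0)

    def test_empty_comparison_set(self, build_corpus):
        corpus = build_corpus(
            [("t1", "w", {"A1": ["fatigue"]}), ("t2", "w", {"A2": ["fatigue"]})]
        )
        with pytest.raises(ValueError, match="empty comparison set"):
            pair_counts(corpus, "A1", "A2")

    def test_per_category_counts_sum_to_overall(self, build_corpus):
        rng = np.random.default_rng(7)
        records = []
        for i in range(40):
            labels = {}
            for a in ("A1", "A2"):
                picks = rng.choice(len(CATS), size=rng.integers(1, 3), replace=False)
                labels[a] = [CATS[j] for j in picks]
            records.append((f"t{i}", "w", labels))
        corpus = build_corpus(records)
        overall = pair_counts(corpus, "A1", "A2", ALL)
        summed = AgreementCounts(0, 0, 0)
        for cat in DEFAULT_SCHEME.categories:
            summed = summed + pair_counts(corpus, "A1", "A2", cat)
        assert summed == overall


class TestFScore:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (AgreementCounts(10, 0, 0), 100.0),
            (AgreementCounts(0, 3, 2), 0.0),
            (AgreementCounts(3, 1, 1), 75.0),  # 6 / 8 by the printed formula
        ],
    )
    def test_values(self, counts, expected):
        assert f_score(counts) == expected

    def test_not_observed_sentinel(self):
        assert f_score(AgreementCounts(0, 0, 0)) is NOT_OBSERVED
        assert str(NOT_OBSERVED) == "—"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            AgreementCounts(-1, 0, 0)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_symmetry_under_annotator_swap(self, m, t1, t2):
        counts = AgreementCounts(m, t1, t2)
        a, b = f_score(counts), f_score(counts.swapped())
        assert (a is NOT_OBSERVED and b is NOT_OBSERVED) or a == pytest.approx(b)

    def test_agrees_with_set_based_f1_oracle(self, build_corpus):
        """F equals harmonic-mean F1 with either annotator as reference."""
        from sklearn.metrics import f1_score as sk_f1

        rng = np.random.default_rng(42)
        for _ in range(200):
            records = []
            for i in range(rng.integers(2, 9)):
                labels = {}
                for a in ("A1", "A2"):
                    picks = rng.choice(len(CATS), size=rng.integers(1, 3), replace=False)
                    labels[a] = [CATS[j] for j in picks]
                records.append((f"t{i}", "w", labels))
            corpus = build_corpus(records)
            ours = f_score(pair_counts(corpus, "A1", "A2"))
            a_set, b_set = corpus.assertions("A1"), corpus.assertions("A2")
            universe = sorted(a_set | b_set)
            y_a = [k in a_set for k in universe]
            y_b = [k in b_set for k in universe]
            oracle = 100 * sk_f1(y_a, y_b, zero_division=0)
            assert ours == pytest.approx(oracle, abs=1e-9)


class TestAdjudicate:
    def test_agreement_passes_through(self, build_corpus):
        corpus = build_corpus(
            [("t1", "w", {"A1": ["fatigue"], "A2": ["fatigue"]})]
        )
        gold = adjudicate(corpus, ("A1", "A2"), "A3")
        assert [(g.tweet_id, g.annotator_id, g.category) for g in gold] == [
            ("t1", GOLD, "fatigue")
        ]

    def test_disagreement_resolved_by_adjudicator(self, build_corpus):
        corpus = build_corpus(
            [("t1", "w", {"A1": ["fatigue"], "A2": ["weather"], "A3": ["weather"]})]
        )
        gold = adjudicate(corpus, ("A1", "A2"), "A3")
        assert [g.category for g in gold] == ["weather"]

    def test_missing_adjudicator_label_is_error(self, build_corpus):
        corpus = build_corpus([("t1", "w", {"A1": ["fatigue"], "A2": ["weather"]})])
        with pytest.raises(ValueError, match="t1"):
            adjudicate(corpus, ("A1", "A2"), "A3")

    def test_output_only_contains_seen_assertions(self, build_corpus):
        rng = np.random.default_rng(3)
        records = []
        for i in range(30):
            labels = {
                a: [CATS[rng.integers(len(CATS))]] for a in ("A1", "A2", "A3")
            }
            records.append((f"t{i}", "w", labels))
        corpus = build_corpus(records)
        gold = adjudicate(corpus, ("A1", "A2"), "A3")
        seen = (
            corpus.assertions("A1") | corpus.assertions("A2") | corpus.assertions("A3")
        )
        assert all((g.tweet_id, g.category) in seen for g in gold)


class TestPhasePlan:
    @pytest.mark.parametrize(
        "args, expected",
        [((300, 300, 2700, 1200), 9300), ((0, 0, 0, 0), 0), ((100, 0, 0, 0), 100)],
    )
    def test_totals(self, args, expected):
        assert phase_plan(*args).total_unique_tweets == expected

    def test_negative_sizes_rejected(self):
        with pytest.raises(ValueError):
            phase_plan(-1, 0, 0, 0)


class TestAgreementReport:
    def test_layout(self, build_corpus):
        corpus = build_corpus(
            [
                ("t1", "w", {"A1": ["fatigue"], "A2": ["fatigue"]}),
                ("t2", "w", {"A1": ["no_evidence"], "A2": ["no_evidence"]}),
            ]
        )
        report = agreement_report(corpus)
        assert list(report.columns) == ["A1/A2"]
        assert report.loc["overall", "A1/A2"] == 100.0
        assert report.loc["fatigue", "A1/A2"] == 100.0
        assert np.isnan(report.loc["weather", "A1/A2"])  # not observed

    def test_evidence_pooling_excludes_no_evidence(self, build_corpus):
        corpus = build_corpus(
            [
                ("t1", "w", {"A1": ["no_evidence"], "A2": ["no_evidence"]}),
                ("t2", "w", {"A1": ["fatigue"], "A2": ["weather"]}),
            ]
        )
        overall = pair_counts(corpus, "A1", "A2", ALL)
        evidence = pair_counts(corpus, "A1", "A2", EVIDENCE)
        assert overall.matches == 1 and evidence.matches == 0
        assert evidence.mismatches == 2
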