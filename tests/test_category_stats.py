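"""Frequency reports, phi coefficients, Cohen bins, and the heatmap."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from depsignal.agreement import NOT_OBSERVED
from depsignal.category_stats import (
    COHEN_BINS,
    cohen_bin,
    frequency_report,
    heatmap,
    indicator_matrix,
    phi,
    phi_matrix,
)
from depsignal.corpus import GOLD


class TestFrequencyReport:
    def test_single_label_all_no_evidence(self, build_corpus):
        corpus = build_corpus(
            [(f"t{i}", "w", {GOLD: ["no_evidence"]}) for i in range(10)]
        )
        rep = frequency_report(corpus)
        assert rep.no_evidence_pct == 100.0
        assert rep.multilabel == {1: 10, 2: 0, 3: 0}

    def test_multilabel_distribution_counts_tweets(self, build_corpus):
        records = [(f"t{i}", "w", {GOLD: ["no_evidence"]}) for i in range(9)]
        records.append(("t9", "w", {GOLD: ["fatigue", "disturbed_sleep"]}))
        rep = frequency_report(build_corpus(records))
        assert rep.multilabel == {1: 9, 2: 1, 3: 0}
        assert rep.total_annotations == 11  # shares are over annotations

    def test_group_split(self, build_corpus):
        corpus = build_corpus(
            [
                ("t1", "w", {GOLD: ["fatigue"]}),
                ("t2", "w", {GOLD: ["educational_problems"]}),
                ("t3", "w", {GOLD: ["no_evidence"]}),
            ]
        )
        rep = frequency_report(corpus)
        assert rep.symptom_count == 1
        assert rep.stressor_count == 1
        assert rep.evidence_pct + rep.no_evidence_pct == pytest.approx(100.0)

    def test_empty_corpus_is_error(self, build_corpus):
        with pytest.raises(ValueError, match="empty"):
            frequency_report(build_corpus([]))


class TestIndicatorMatrix:
    def test_rows_reflect_gold_labels(self, build_corpus):
        corpus = build_corpus(
            [
                ("t1", "w", {GOLD: ["depressed_mood", "educational_problems"]}),
                ("t2", "w", {GOLD: ["no_evidence"]}),
            ]
        )
        ind = indicator_matrix(corpus)
        assert ind.shape == (2, 21)
        assert ind.loc["t1"].sum() == 2
        assert ind.loc["t1", "depressed_mood"] == 1
        assert ind.loc["t2"].sum() == 0  # no-evidence row is all zero

    def test_row_sums_match_multilabel_distribution(self, build_corpus):
        records = [
            ("t1", "w", {GOLD: ["fatigue", "disturbed_sleep"]}),
            ("t2", "w", {GOLD: ["fatigue"]}),
            ("t3", "w", {GOLD: ["no_evidence"]}),
        ]
        corpus = build_corpus(records)
        sums = sorted(indicator_matrix(corpus).sum(axis=1))
        assert sums == [0, 1, 2]


class TestPhi:
    def test_identical_vectors(self):
        assert phi([0, 1, 0, 1], [0, 1, 0, 1]) == pytest.approx(1.0)

    def test_derived_2x2_value(self):
        # 2x2 table n11=40, n10=10, n01=10, n00=40 expanded to 0/1 vectors
        x = [1] * 50 + [0] * 50
        y = [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40
        assert phi(x, y) == pytest.approx(0.6)

    def test_constant_vector_not_observed(self):
        assert phi([1, 1, 1], [0, 1, 0]) is NOT_OBSERVED

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            phi([0, 1], [0, 1, 1])

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=2, max_size=60))
    def test_matches_product_moment_oracle(self, pairs):
        x = np.array([a for a, _ in pairs], dtype=float)
        y = np.array([b for _, b in pairs], dtype=float)
        ours = phi(x, y)
        if x.std() == 0 or y.std() == 0:
            assert ours is NOT_OBSERVED
        else:
            assert ours == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=4, max_size=40))
    def test_relabeling_symmetries(self, pairs):
        x = np.array([a for a, _ in pairs], dtype=int)
        y = np.array([b for _, b in pairs], dtype=int)
        ours = phi(x, y)
        if ours is NOT_OBSERVED:
            return
        # flipping both vectors preserves phi; flipping one negates it
        assert phi(1 - x, 1 - y) == pytest.approx(ours, abs=1e-12)
        assert phi(1 - x, y) == pytest.approx(-ours, abs=1e-12)


class TestCohenBins:
    @pytest.mark.parametrize(
        "r, label",
        [
            (0.0, "less-than-small"),
            (0.095, "less-than-small"),  # the printed 0.09-0.1 gap closes at 0.1
            (0.1, "small-to-medium"),
            (0.3, "medium-to-large"),
            (0.49, "medium-to-large"),
            (0.5, "greater-than-large"),
            (0.6, "greater-than-large"),
            (-0.6, "greater-than-large"),  # magnitude binning
            (1.0, "greater-than-large"),
        ],
    )
    def test_boundaries(self, r, label):
        assert cohen_bin(r) == label

    def test_bins_cover_unit_interval(self):
        edges = [b.lower for b in COHEN_BINS] + [COHEN_BINS[-1].upper]
        assert edges == [0.0, 0.1, 0.3, 0.5, 1.0]

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            cohen_bin(1.2)


class TestPhiMatrix:
    def test_structure(self, build_corpus):
        records = []
        for i in range(30):
            cats = ["fatigue", "disturbed_sleep"] if i < 12 else ["no_evidence"]
            records.append((f"t{i}", "w", {GOLD: cats}))
        records.append(("t30", "w", {GOLD: ["fatigue"]}))
        m = phi_matrix(build_corpus(records))
        assert m.r.loc["fatigue", "fatigue"] == pytest.approx(1.0)
        assert m.r.loc["fatigue", "disturbed_sleep"] == m.r.loc["disturbed_sleep", "fatigue"]
        assert not bool(m.observed.loc["weather", "media"])  # never annotated
        assert m.effect_bin.loc["fatigue", "disturbed_sleep"] in {
            b.label for b in COHEN_BINS
        }
        counts = m.bin_counts()
        assert sum(counts.values()) == int(m.observed.to_numpy()[np.triu_indices(21, 1)].sum())

    def test_symmetric_and_bounded(self, build_corpus):
        rng = np.random.default_rng(5)
        cats = ("fatigue", "disturbed_sleep", "weather", "media")
        records = []
        for i in range(80):
            chosen = [c for c in cats if rng.random() < 0.3] or ["no_evidence"]
            records.append((f"t{i}", "w", {GOLD: chosen}))
        m = phi_matrix(build_corpus(records))
        r = m.r.to_numpy()
        defined = ~np.isnan(r)
        assert np.allclose(r[defined], r.T[defined])
        assert np.all(np.abs(r[defined]) <= 1 + 1e-12)

    def test_heatmap_written(self, build_corpus, tmp_path):
        corpus = build_corpus(
            [("t1", "w", {GOLD: ["fatigue"]}), ("t2", "w", {GOLD: ["no_evidence"]})]
        )
        out = tmp_path / "heat.png"
        heatmap(phi_matrix(corpus), out)
        assert out.stat().st_size > 0
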