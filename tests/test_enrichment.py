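import math

import numpy as np
import pytest

from confsel.classifiers import PredictionSet
from confsel.enrichment import (DEFAULT_PERCENTS, FilterSpec, apply_filter,
                                base_enrichment_ratio, default_filters,
                                enrichment_report, final_enrichment_ratio,
                                ml_enrichment_ratio)


class TestRatios:
    def test_base_ratio(self):
        assert base_enrichment_ratio([1, 0, 0, 0]) == 0.25
        assert base_enrichment_ratio([1, 1, 1]) == 1.0
        labels = np.r_[np.ones(851), np.zeros(2147)]
        assert base_enrichment_ratio(labels) == pytest.approx(851 / 2998)

    def test_ml_ratio(self):
        assert ml_enrichment_ratio(9, 3) == 0.75
        assert ml_enrichment_ratio(4, 0) == 1.0
        assert ml_enrichment_ratio(0, 4) == 0.0

    def test_final_ratio(self):
        assert final_enrichment_ratio(0.75, 0.25) == 3.0
        assert final_enrichment_ratio(0.4, 0.4) == 1.0
        assert final_enrichment_ratio(0.75, 851 / 2998) == pytest.approx(
            0.75 * 2998 / 851)

    def test_error_contracts(self):
        with pytest.raises(ValueError):
            base_enrichment_ratio([0, 0])
        with pytest.raises(ValueError):
            base_enrichment_ratio([])
        with pytest.raises(ValueError):
            ml_enrichment_ratio(0, 0)
        with pytest.raises(ValueError):
            final_enrichment_ratio(0.5, 0.0)


def preds_from(truth, proba, threshold=0.5):
    return PredictionSet(np.asarray(truth), np.asarray(proba), threshold)


class TestApplyFilter:
    def test_ceiling_subset_size(self):
        truth = np.ones(200, dtype=int)
        proba = np.linspace(1, 0, 200)
        ps = preds_from(truth, proba)
        f = FilterSpec("A", "stage2", True, 1.0)
        tp, fn = apply_filter(ps, f)
        assert tp + fn == 2  # ceil(1% of 200)

    def test_percent_100_equals_global_tally(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 150)
        proba = rng.random(150)
        ps = preds_from(truth, proba)
        tp, fn = apply_filter(ps, FilterSpec("A", "stage2", True, 100.0))
        c = ps.confusion()
        assert (tp, fn) == (c.tp, c.fn)

    def test_constructed_ranking_fixture(self):
        # 10 binding rows, probabilities descending, first five above the
        # threshold: the best-first top half is all TP
        truth = np.ones(10, dtype=int)
        proba = np.linspace(0.95, 0.05, 10)
        ps = preds_from(truth, proba)
        assert apply_filter(ps, FilterSpec("A", "stage2", True, 50.0)) == (5, 0)
        assert apply_filter(ps, FilterSpec("D", "stage2", False, 50.0)) == (0, 5)

    def test_only_positive_truth_rows_considered(self):
        truth = np.array([1, 0, 1, 0, 1, 0])
        proba = np.array([0.9, 0.95, 0.8, 0.85, 0.1, 0.99])
        ps = preds_from(truth, proba)
        tp, fn = apply_filter(ps, FilterSpec("A", "stage2", True, 100.0))
        assert tp + fn == 3

    def test_stage1_and_mean_keys(self):
        truth = np.ones(4, dtype=int)
        s2 = np.array([0.9, 0.1, 0.9, 0.1])
        s1 = np.array([0.0, 1.0, 0.2, 0.8])
        ps = preds_from(truth, s2)
        tp, fn = apply_filter(ps, FilterSpec("B", "stage1", True, 50.0),
                              stage1_probability=s1)
        assert (tp, fn) == (0, 2)  # stage-1 ranks the low-s2 rows first
        with pytest.raises(ValueError, match="stage-1"):
            apply_filter(ps, FilterSpec("B", "stage1", True, 50.0))

    def test_external_scores_key(self):
        truth = np.ones(4, dtype=int)
        proba = np.array([0.9, 0.9, 0.1, 0.1])
        docking = np.array([-12.0, -2.0, -11.0, -1.0])  # lower = better
        ps = preds_from(truth, proba)
        tp, fn = apply_filter(
            ps, FilterSpec("E", "external", False, 50.0),
            external_scores=docking)
        assert (tp, fn) == (1, 1)

    def test_no_positive_truth_rejected(self):
        ps = preds_from([0, 0], [0.4, 0.6])
        with pytest.raises(ValueError, match="no binding"):
            apply_filter(ps, FilterSpec("A", "stage2", True, 10.0))

    def test_kept_size_monotone_in_percent(self):
        rng = np.random.default_rng(1)
        ps = preds_from(rng.integers(0, 2, 97), rng.random(97))
        sizes = [sum(apply_filter(ps, FilterSpec("A", "stage2", True, p)))
                 for p in (0.5, 1, 2, 5, 10, 50, 100)]
        assert sizes == sorted(sizes)


class TestReport:
    def test_perfect_classifier_hits_ceiling(self):
        rng = np.random.default_rng(2)
        truth = rng.integers(0, 2, 200)
        ps = preds_from(truth, truth.astype(float))
        rep = enrichment_report(ps, truth, stage1_probability=truth)
        base = truth.mean()
        assert np.allclose(rep.cells["ml_ratio"], 1.0)
        assert np.allclose(rep.cells["final_ratio"], 1.0 / base)

    def test_all_fn_classifier_floors_at_zero(self):
        truth = np.r_[np.ones(20, dtype=int), np.zeros(80, dtype=int)]
        ps = preds_from(truth, np.zeros(100))
        rep = enrichment_report(ps, truth, stage1_probability=np.zeros(100))
        assert np.allclose(rep.cells["final_ratio"], 0.0)

    def test_sixteen_cells_match_independent_recomputation(self):
        rng = np.random.default_rng(3)
        truth = rng.integers(0, 2, 300)
        s2 = rng.random(300)
        s1 = rng.random(300)
        ps = preds_from(truth, s2)
        rep = enrichment_report(ps, truth, stage1_probability=s1)
        assert len(rep.cells) == 16
        base = truth.mean()
        scores = {"A": -s2, "B": -s1, "C": -(s1 + s2) / 2, "D": s2}
        for _, row in rep.cells.iterrows():
            pos = np.flatnonzero(truth == 1)
            order = pos[np.argsort(scores[row["filter"]][pos], kind="stable")]
            keep = order[: max(1, math.ceil(row["percent"] / 100 * len(pos)))]
            tp = int((ps.hard[keep] == 1).sum())
            assert (row["tp"], row["fn"]) == (tp, len(keep) - tp)
            assert row["ml_ratio"] == pytest.approx(tp / len(keep))
            assert row["final_ratio"] == pytest.approx(tp / len(keep) / base)
        mx = rep.maxima()
        assert mx["final_ratio"] == rep.cells["final_ratio"].max()

    def test_random_equivalence_gives_final_one(self):
        # subset TP fraction equal to the base rate -> no enrichment
        truth = np.ones(40, dtype=int)
        hard = np.r_[np.ones(10), np.zeros(30)]  # TP fraction 0.25
        ps = preds_from(truth, hard * 0.9 + 0.05)
        base_labels = np.r_[np.ones(25, dtype=int), np.zeros(75, dtype=int)]
        tp, fn = apply_filter(ps, FilterSpec("A", "stage2", True, 100.0))
        final = final_enrichment_ratio(
            ml_enrichment_ratio(tp, fn), base_enrichment_ratio(base_labels))
        assert final == pytest.approx(1.0)

    def test_summary_row_layout(self):
        rng = np.random.default_rng(4)
        truth = rng.integers(0, 2, 100)
        ps = preds_from(truth, rng.random(100))
        rep = enrichment_report(ps, truth, stage1_probability=rng.random(100))
        row = rep.summary_row("XGBoost + GANs-CNN")
        assert list(row.columns) == [
            "classifier", "maxima", "maxima_filter", "maxima_percent",
            "minima", "minima_filter", "minima_percent"]

    def test_default_filters_and_percents(self):
        fids = [f.id for f in default_filters()]
        assert fids == ["A", "B", "C", "D"]
        assert DEFAULT_PERCENTS == (0.5, 1.0, 5.0, 10.0)
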