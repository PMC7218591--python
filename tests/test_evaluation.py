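import math

import numpy as np
import pandas as pd
import pytest

from ddx.errors import CoverageError
from ddx.evaluation import (
    PredictionRecord,
    aggregate_precision,
    aggregate_recall,
    cosine_similarity,
    evaluate_study,
    jaccard_similarity,
    per_disease_precision_recall,
    read_predictions,
    top_k_accuracy,
    upper_tailed_t_test,
    write_predictions,
)
from ddx.vignettes import VignetteSet

from conftest import make_differential, make_vignette
from oracles import welch_upper_tail


def predict(vid, ids, sureties=(50, 30, 20), source="model"):
    return PredictionRecord(vid, source, make_differential(*zip(ids, sureties)))


class TestTopKAccuracy:
    def test_perfect_predictions(self, small_gold_set):
        preds = [predict(v.id, v.gold.disease_ids) for v in small_gold_set]
        assert top_k_accuracy(preds, small_gold_set) == 1.0

    def test_seven_of_ten_hits(self, small_gold_set):
        preds = []
        for i, v in enumerate(small_gold_set):
            if i < 7:  # gold primary parked at rank 3
                ids = ("x", "y", v.gold.primary)
            else:
                ids = ("x", "y", "z")
            preds.append(predict(v.id, ids))
        assert top_k_accuracy(preds, small_gold_set, k=3) == pytest.approx(0.7)

    def test_rank3_hit_counts_for_k3_not_k1(self, small_gold_set):
        preds = [predict(v.id, ("x", "y", v.gold.primary)) for v in small_gold_set]
        assert top_k_accuracy(preds, small_gold_set, k=3) == 1.0
        assert top_k_accuracy(preds, small_gold_set, k=1) == 0.0

    def test_non_decreasing_in_k(self, small_gold_set):
        rng = np.random.default_rng(0)
        pool = ["a", "b", "c", "d", "x"]
        preds = [
            predict(v.id, tuple(rng.choice(pool, size=3, replace=False))) for v in small_gold_set
        ]
        accs = [top_k_accuracy(preds, small_gold_set, k=k) for k in (1, 2, 3)]
        assert accs == sorted(accs)

    def test_duplicate_and_unmatched_predictions_rejected(self, small_gold_set):
        v0 = small_gold_set.vignettes[0]
        with pytest.raises(CoverageError, match="duplicate"):
            top_k_accuracy(
                [predict(v0.id, ("a", "b", "c")), predict(v0.id, ("a", "b", "c"))],
                small_gold_set,
            )
        with pytest.raises(CoverageError, match="unknown"):
            top_k_accuracy([predict("ghost", ("a", "b", "c"))], small_gold_set)


class TestPerDiseasePrecisionRecall:
    def test_hand_counted_confusion(self):
        # disease A predicted primary 4 times, correct 3 of them
        gold = VignetteSet(
            tuple(
                make_vignette(f"v{i}", (g, "y", "z"))
                for i, g in enumerate(["A", "A", "A", "B", "B"])
            )
        )
        preds = [
            predict("v0", ("A", "y", "z")),
            predict("v1", ("A", "y", "z")),
            predict("v2", ("A", "y", "z")),
            predict("v3", ("A", "y", "z")),  # wrong: gold is B
            predict("v4", ("B", "y", "z")),
        ]
        table = per_disease_precision_recall(preds, gold).set_index("disease_id")
        assert table.loc["A", "precision"] == pytest.approx(0.75)
        assert table.loc["A", "recall"] == pytest.approx(1.0)
        assert table.loc["B", "recall"] == pytest.approx(0.5)
        assert table.loc["A", "gold_count"] == 3
        assert table.loc["A", "predicted_count"] == 4

    def test_all_correct_gives_unit_scores(self, small_gold_set):
        preds = [predict(v.id, v.gold.disease_ids) for v in small_gold_set]
        table = per_disease_precision_recall(preds, small_gold_set)
        gold_present = table[table["gold_count"] > 0]
        assert (gold_present["precision"] == 1.0).all()
        assert (gold_present["recall"] == 1.0).all()

    def test_vacuous_disease_excluded(self, small_gold_set):
        preds = [predict(v.id, v.gold.disease_ids) for v in small_gold_set]
        table = per_disease_precision_recall(preds, small_gold_set)
        # 'z' never gold primary, never predicted primary
        assert "z" not in set(table["disease_id"])


class TestAggregates:
    def test_weighted_mean_worked_example(self):
        # frequencies 60/40, precisions 1.0/0.5 -> 0.8
        table = pd.DataFrame(
            {
                "disease_id": ["A", "B"],
                "precision": [1.0, 0.5],
                "recall": [1.0, 0.5],
                "gold_count": [60, 40],
                "predicted_count": [60, 80],
                "tp": [60, 40],
            }
        )
        assert aggregate_precision(table) == pytest.approx(0.8)
        assert aggregate_recall(table) == pytest.approx(0.8)

    def test_uniform_weights_reduce_to_plain_mean(self):
        table = pd.DataFrame(
            {
                "disease_id": list("ABC"),
                "precision": [0.9, 0.6, 0.3],
                "recall": [0.9, 0.6, 0.3],
                "gold_count": [5, 5, 5],
                "predicted_count": [5, 5, 5],
                "tp": [4, 3, 1],
            }
        )
        assert aggregate_precision(table) == pytest.approx(0.6)

    def test_single_disease_aggregate_is_its_value(self):
        table = pd.DataFrame(
            {
                "disease_id": ["A"],
                "precision": [0.7],
                "recall": [0.4],
                "gold_count": [10],
                "predicted_count": [9],
                "tp": [7],
            }
        )
        assert aggregate_precision(table) == pytest.approx(0.7)
        assert aggregate_recall(table) == pytest.approx(0.4)

    def test_undefined_precision_policies(self):
        # B occurs in gold but is never predicted: precision undefined (0/0)
        table = pd.DataFrame(
            {
                "disease_id": ["A", "B"],
                "precision": [1.0, math.nan],
                "recall": [1.0, 0.0],
                "gold_count": [5, 5],
                "predicted_count": [10, 0],
                "tp": [5, 0],
            }
        )
        assert aggregate_precision(table, "zero") == pytest.approx(0.5)
        assert aggregate_precision(table, "exclude") == pytest.approx(1.0)

    def test_empty_gold_rejected(self):
        table = pd.DataFrame(
            {
                "disease_id": ["A"],
                "precision": [1.0],
                "recall": [math.nan],
                "gold_count": [0],
                "predicted_count": [3],
                "tp": [0],
            }
        )
        with pytest.raises(ValueError, match="empty gold"):
            aggregate_precision(table)


class TestSimilarities:
    def test_jaccard_identical_and_disjoint(self):
        a = make_differential(("a", 50), ("b", 30), ("c", 20))
        b = make_differential(("c", 10), ("b", 40), ("a", 50))
        d = make_differential(("x", 50), ("y", 30), ("z", 20))
        assert jaccard_similarity(a, b) == 1.0
        assert jaccard_similarity(a, d) == 0.0

    def test_jaccard_partial_overlap(self):
        a = make_differential(("a", 50), ("b", 30), ("c", 20))
        b = make_differential(("a", 50), ("b", 30), ("d", 20))
        assert jaccard_similarity(a, b) == pytest.approx(0.5)

    def test_cosine_identical_is_one(self):
        a = make_differential(("a", 50), ("b", 30), ("c", 20))
        assert cosine_similarity(a, a, ["a", "b", "c", "d"]) == pytest.approx(1.0)

    def test_cosine_disjoint_is_zero(self):
        a = make_differential(("a", 50), ("b", 30), ("c", 20))
        b = make_differential(("x", 50), ("y", 30), ("z", 20))
        assert cosine_similarity(a, b, ["a", "b", "c", "x", "y", "z"]) == 0.0

    def test_cosine_hand_worked_dot_product(self):
        u = make_differential(("a", 50), ("b", 30), ("c", 20))
        v = make_differential(("a", 20), ("b", 30), ("c", 50))
        expected = 2900 / 3800  # (1000 + 900 + 1000) / (sqrt(3800) * sqrt(3800))
        assert cosine_similarity(u, v, ["a", "b", "c"]) == pytest.approx(expected, abs=1e-9)

    def test_cosine_one_iff_proportional_sureties(self):
        a = make_differential(("a", 60), ("b", 30), ("c", 10))
        b = make_differential(("a", 50), ("b", 30), ("c", 20))
        assert jaccard_similarity(a, b) == 1.0  # same sets
        assert cosine_similarity(a, b, ["a", "b", "c"]) < 1.0  # but not proportional


class TestWelch:
    def test_identical_samples_give_half_p(self):
        res = upper_tailed_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.5)

    def test_separated_samples_drive_p_to_zero(self):
        rng = np.random.default_rng(1)
        a = 1.0 + rng.normal(0, 1e-3, 50)
        b = rng.normal(0, 1e-3, 50)
        assert upper_tailed_t_test(a, b).p_value < 1e-12

    def test_fixed_vectors_match_textbook_computation(self):
        a = [0.9, 0.8, 1.0, 0.7]
        b = [0.5, 0.6, 0.4, 0.7]
        res = upper_tailed_t_test(a, b)
        t, p = welch_upper_tail(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            na, nb = rng.integers(2, 30, size=2)
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), na)
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), nb)
            res = upper_tailed_t_test(a, b)
            t, p = welch_upper_tail(a, b)
            assert res.statistic == pytest.approx(t, abs=1e-9)
            assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_degenerate_constant_samples(self):
        res = upper_tailed_t_test([1.0, 1.0], [1.0, 1.0])
        assert (res.statistic, res.p_value, res.degenerate) == (0.0, 0.5, True)
        up = upper_tailed_t_test([2.0, 2.0], [1.0, 1.0])
        assert up.p_value == 0.0 and up.degenerate

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            upper_tailed_t_test([1.0], [1.0, 2.0])


class TestEvaluateStudy:
    def test_perfect_single_source(self, small_gold_set):
        preds = {
            "model": [
                predict(v.id, v.gold.disease_ids, tuple(s for _, s in v.gold.items))
                for v in small_gold_set
            ]
        }
        reports, comparisons = evaluate_study(small_gold_set, preds)
        assert comparisons == []  # no non-model source to compare against
        for r in reports:
            assert r.top3_accuracy == 1.0
            assert r.precision_aggregate == 1.0
            assert r.recall_aggregate == 1.0
            assert r.jaccard_mean == 1.0
            assert r.cosine_mean == pytest.approx(1.0)
        assert {r.stratum for r in reports} == {"overall", "high", "moderate", "low"}

    def test_aggregates_recomputable_from_per_disease_table(self, small_gold_set):
        rng = np.random.default_rng(2)
        pool = ["a", "b", "c", "d", "x"]
        preds = {
            "model": [
                predict(v.id, tuple(rng.choice(pool, size=3, replace=False)))
                for v in small_gold_set
            ]
        }
        reports, _ = evaluate_study(small_gold_set, preds)
        for r in reports:
            t = r.per_disease[r.per_disease["gold_count"] > 0]
            vals = t["precision"].fillna(0.0).to_numpy()
            w = t["gold_count"].to_numpy(dtype=float)
            assert r.precision_aggregate == pytest.approx(float(np.average(vals, weights=w)))

    def test_ordering_invariance(self, small_gold_set):
        rng = np.random.default_rng(4)
        pool = ["a", "b", "c", "d", "x"]
        model = [predict(v.id, tuple(rng.choice(pool, 3, replace=False))) for v in small_gold_set]
        rater = [
            predict(v.id, tuple(rng.choice(pool, 3, replace=False)), source="rater-1")
            for v in small_gold_set
        ]
        r1, c1 = evaluate_study(small_gold_set, {"model": model, "rater-1": rater})
        r2, c2 = evaluate_study(
            small_gold_set, {"rater-1": rater[::-1], "model": model[::-1]}
        )
        for a, b in zip(r1, r2):
            assert (a.source, a.stratum, a.top3_accuracy, a.jaccard_mean) == (
                b.source,
                b.stratum,
                b.top3_accuracy,
                b.jaccard_mean,
            )
        assert [(c.metric, c.statistic) for c in c1] == [(c.metric, c.statistic) for c in c2]

    def test_coverage_gap_names_source_and_ids(self, small_gold_set):
        preds = {"model": [predict(v.id, v.gold.disease_ids) for v in list(small_gold_set)[:-1]]}
        with pytest.raises(CoverageError) as exc:
            evaluate_study(small_gold_set, preds)
        assert exc.value.missing_by_source == {"model": ["v9"]}


class TestPredictionIO:
    def test_round_trip(self, small_gold_set, tmp_path):
        preds = [predict(v.id, v.gold.disease_ids) for v in small_gold_set]
        path = tmp_path / "p.jsonl"
        write_predictions(preds, path)
        assert read_predictions(path) == preds
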