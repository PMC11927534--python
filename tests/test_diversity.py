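"""Diversity metrics, composite indices and ranking against brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

import hdestack as h
from hdestack.diversity import (
    DEFAULT_DIRECTIONS,
    METRIC_NAMES,
    PairCounts,
    build_report,
)

# Printed candidate-evaluation tables used as worked-example inputs:
# per-candidate accuracy/precision/recall/F1 (%) and composite indices.
TABLE_PERF = {
    "LR": (73.33, 73.12, 74.5, 73.81),
    "DT": (61.52, 63.15, 61.9, 61.52),
    "MLP": (82.12, 83.65, 82.43, 83.03),
    "KNN": (70.00, 70.8, 69.75, 70.27),
    "GP": (73.03, 74.56, 72.98, 73.76),
    "SVM": (72.73, 72.45, 73.33, 72.89),
}
TABLE_COMPOSITES = {
    # model: (Dci, Pci, printed comprehensive score)
    "LR": (0.7707, 0.3472, 0.5589),
    "DT": (0.7297, 0.2864, 0.5580),  # printed score inconsistent with the rule
    "SVM": (0.6889, 0.3432, 0.5160),
    "KNN": (0.5788, 0.3182, 0.4485),
    "GP": (0.4819, 0.3364, 0.4091),
    "MLP": (0.6710, 0.3773, 0.5241),
}


class TestPairCounts:
    def test_all_correct(self):
        truth = np.zeros(10, dtype=int)
        pc = h.pair_counts(truth, truth, truth)
        assert (pc.a, pc.b, pc.c, pc.d) == (10, 0, 0, 0)

    def test_x_right_y_wrong(self):
        truth = np.zeros(8, dtype=int)
        wrong = np.ones(8, dtype=int)
        pc = h.pair_counts(truth, wrong, truth)
        assert (pc.a, pc.b, pc.c, pc.d) == (0, 8, 0, 0)

    def test_matches_loop_oracle(self, rng):
        truth = rng.integers(0, 3, 50)
        px = rng.integers(0, 3, 50)
        py = rng.integers(0, 3, 50)
        pc = h.pair_counts(px, py, truth)
        a = b = c = d = 0
        for i in range(50):
            cx, cy = px[i] == truth[i], py[i] == truth[i]
            if cx and cy:
                a += 1
            elif cx:
                b += 1
            elif cy:
                c += 1
            else:
                d += 1
        assert (pc.a, pc.b, pc.c, pc.d) == (a, b, c, d)
        assert pc.n == 50

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            h.pair_counts([0, 1], [0], [0, 1])


class TestPairwiseMetric:
    def test_perfect_agreement(self):
        pc = PairCounts(a=5, b=0, c=0, d=5)
        assert h.pairwise_metric(pc, "Dis") == 0.0
        assert h.pairwise_metric(pc, "Qs") == 1.0
        assert h.pairwise_metric(pc, "Cor") == 1.0

    def test_perfect_disagreement(self):
        pc = PairCounts(a=0, b=5, c=5, d=0)
        assert h.pairwise_metric(pc, "Dis") == 1.0
        assert h.pairwise_metric(pc, "Qs") == -1.0

    def test_matches_direct_arithmetic(self):
        a, b, c, d = 40.0, 5.0, 10.0, 45.0
        n = a + b + c + d
        pc = PairCounts(a=40, b=5, c=10, d=45)
        assert h.pairwise_metric(pc, "Dis") == pytest.approx((b + c) / n, abs=1e-12)
        assert h.pairwise_metric(pc, "Qs") == pytest.approx(
            (a * d - b * c) / (a * d + b * c), abs=1e-12
        )
        assert h.pairwise_metric(pc, "Cor") == pytest.approx(
            (a * d - b * c) / math.sqrt((a + b) * (a + c) * (c + d) * (b + d)),
            abs=1e-12,
        )
        p_obs = (a + d) / n
        p_chance = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
        assert h.pairwise_metric(pc, "Ks") == pytest.approx(
            (p_obs - p_chance) / (1 - p_chance), abs=1e-12
        )

    def test_zero_denominator_gives_nan(self):
        assert math.isnan(h.pairwise_metric(PairCounts(a=10, b=0, c=0, d=0), "Qs"))
        assert math.isnan(h.pairwise_metric(PairCounts(a=10, b=0, c=0, d=0), "Ks"))


class TestComposites:
    def test_two_symmetric_models_equal_dci(self, rng):
        truth = rng.integers(0, 2, 30)
        preds = {"A": rng.integers(0, 2, 30), "B": rng.integers(0, 2, 30)}
        mats = h.pairwise_matrices(preds, truth)
        dci = h.diversity_composite(mats)
        assert dci["A"] == pytest.approx(dci["B"])

    def test_outlier_model_attains_largest_dci(self):
        """Three models; one maximally different from the other two."""
        truth = np.zeros(12, dtype=int)
        agree = np.zeros(12, dtype=int)
        preds = {
            "A": agree,
            "B": agree.copy(),
            "C": np.ones(12, dtype=int),  # always wrong: maximal disagreement
        }
        mats = h.pairwise_matrices(preds, truth)
        dci = h.diversity_composite(mats)
        # brute-force share-sum oracle over the metric matrices
        expected = {}
        for m in preds:
            total = 0.0
            for t in METRIC_NAMES:
                mat = mats[t].to_numpy()
                vals = mat.copy()
                np.fill_diagonal(vals, np.nan)
                if DEFAULT_DIRECTIONS[t] == "smaller":
                    vals = 1.0 - vals
                d = np.nansum(vals, axis=1)
                if d.sum() == 0:
                    continue
                total += d[list(preds).index(m)] / d.sum()
            expected[m] = total
        for m in preds:
            assert dci[m] == pytest.approx(expected[m], abs=1e-12)
        assert dci.idxmax() == "C"

    def test_directions_default(self):
        assert DEFAULT_DIRECTIONS["Dis"] == "bigger"
        for m in ("Qs", "Ks", "Cor"):
            assert DEFAULT_DIRECTIONS[m] == "smaller"

    def test_identical_performance_gives_uniform_pci(self):
        perf = pd.DataFrame(
            {"accuracy": [70.0] * 4, "f1": [68.0] * 4}, index=list("ABCD")
        )
        pci = h.performance_composite(perf)
        assert np.allclose(pci, 2 / 4)  # share-sum: S / M
        assert np.allclose(h.performance_composite(perf, scale="normalized"), 1 / 4)

    def test_dominating_model_has_larger_pci(self):
        perf = pd.DataFrame(
            {"accuracy": [90.0, 70.0], "f1": [88.0, 60.0]}, index=["A", "B"]
        )
        pci = h.performance_composite(perf)
        assert pci["A"] > pci["B"]

    def test_printed_table_reproduces_top_performance_ordering(self):
        perf = pd.DataFrame(TABLE_PERF, index=["accuracy", "precision", "recall", "f1"]).T
        pci = h.performance_composite(perf)
        assert pci["MLP"] > pci["LR"] > pci["SVM"]


class TestComprehensiveScore:
    def test_r_one_returns_dci(self):
        dci = pd.Series({"A": 0.7, "B": 0.3})
        pci = pd.Series({"A": 0.1, "B": 0.9})
        px, _ = h.comprehensive_score(dci, pci, r=1.0)
        assert np.allclose(px, dci)

    def test_worked_examples_match_printed_scores(self):
        dci = pd.Series({m: v[0] for m, v in TABLE_COMPOSITES.items()})
        pci = pd.Series({m: v[1] for m, v in TABLE_COMPOSITES.items()})
        px, _ = h.comprehensive_score(dci, pci, r=0.5)
        for m in ("LR", "SVM", "KNN", "GP", "MLP"):
            assert px[m] == pytest.approx(TABLE_COMPOSITES[m][2], abs=1e-4)

    def test_equal_weight_symmetric_in_dci_pci(self):
        dci = pd.Series({"A": 0.7, "B": 0.3})
        pci = pd.Series({"A": 0.2, "B": 0.6})
        px_a, _ = h.comprehensive_score(dci, pci, r=0.5)
        px_b, _ = h.comprehensive_score(pci, dci, r=0.5)
        assert np.allclose(px_a, px_b)

    def test_tie_break_by_pci_then_name(self):
        # all three share P_x = 0.5; C wins on Pci, then A beats B by name
        dci = pd.Series({"B": 0.5, "A": 0.5, "C": 0.4})
        pci = pd.Series({"B": 0.5, "A": 0.5, "C": 0.6})
        _, order = h.comprehensive_score(dci, pci, r=0.5)
        assert order == ["C", "A", "B"]

    def test_invalid_r_rejected(self):
        s = pd.Series({"A": 0.5})
        with pytest.raises(ValueError):
            h.comprehensive_score(s, s, r=1.5)


class TestPerformanceMetrics:
    def test_perfect_predictions(self):
        truth = np.repeat(np.arange(3), 5)
        m = h.performance_metrics(truth, truth)
        assert all(v == pytest.approx(100.0) for v in m.values())

    @pytest.mark.parametrize(
        "p,r,f1", [(73.12, 74.5, 73.81), (83.65, 82.43, 83.03), (74.56, 72.98, 73.76)]
    )
    def test_f1_from_macro_precision_recall(self, p, r, f1):
        assert 2 * p * r / (p + r) == pytest.approx(f1, abs=0.01)

    def test_macro_matches_sklearn_on_random_preds(self, rng):
        from sklearn.metrics import precision_score, recall_score

        truth = rng.integers(0, 4, 80)
        pred = rng.integers(0, 4, 80)
        m = h.performance_metrics(pred, truth)
        assert m["precision"] == pytest.approx(
            100 * precision_score(truth, pred, average="macro", zero_division=0)
        )
        assert m["recall"] == pytest.approx(
            100 * recall_score(truth, pred, average="macro", zero_division=0)
        )


class TestSelection:
    def test_printed_scores_select_top3(self):
        # ranking the printed comprehensive-score column picks LR, DT, MLP
        px = pd.Series({m: v[2] for m, v in TABLE_COMPOSITES.items()})
        _, ranking = h.comprehensive_score(px, px, r=0.5)  # blend of equal scores
        assert set(ranking[:3]) == {"LR", "DT", "MLP"}

    def test_k_extremes(self, rng):
        truth = rng.integers(0, 3, 40)
        preds = {f"M{i}": rng.integers(0, 3, 40) for i in range(4)}
        rep = build_report(preds, truth)
        assert h.select_base_learners(rep, 4) == rep.ranking
        assert h.select_base_learners(rep, 1) == [rep.px.idxmax()]
        with pytest.raises(ValueError):
            h.select_base_learners(rep, 0)


class TestReportProperties:
    def test_matrices_symmetric_with_nan_diagonal(self, rng):
        truth = rng.integers(0, 3, 60)
        preds = {f"M{i}": rng.integers(0, 3, 60) for i in range(4)}
        mats = h.pairwise_matrices(preds, truth)
        for mat in mats.values():
            v = mat.to_numpy()
            assert np.all(np.isnan(np.diag(v)))
            off = ~np.eye(4, dtype=bool)
            assert np.allclose(v[off], v.T[off], equal_nan=True)

    def test_vectorized_matches_naive_nested_loops(self, rng):
        """Full Dci/Pci/P_x pipeline against an index-by-index reimplementation."""
        truth = rng.integers(0, 3, 60)
        preds = {f"M{i}": rng.integers(0, 3, 60) for i in range(4)}
        rep = build_report(preds, truth)
        names = list(preds)

        def naive_metric(x, y, which):
            return h.pairwise_metric(h.pair_counts(preds[x], preds[y], truth), which)

        dci_naive = {}
        for x in names:
            total = 0.0
            for t in METRIC_NAMES:
                col = 0.0
                mine = 0.0
                for xx in names:
                    d_x = 0.0
                    for yy in names:
                        if yy == xx:
                            continue
                        v = naive_metric(xx, yy, t)
                        if math.isnan(v):
                            continue
                        d_x += v if DEFAULT_DIRECTIONS[t] == "bigger" else 1 - v
                    col += d_x
                    if xx == x:
                        mine = d_x
                if col > 0:
                    total += mine / col
            dci_naive[x] = total
        for x in names:
            assert rep.dci[x] == pytest.approx(dci_naive[x], abs=1e-12)

        perf = {x: h.performance_metrics(preds[x], truth) for x in names}
        for x in names:
            pci_naive = sum(
                perf[x][s] / sum(perf[y][s] for y in names)
                for s in ("accuracy", "precision", "recall", "f1")
            )
            assert rep.pci[x] == pytest.approx(pci_naive, abs=1e-12)
            assert rep.px[x] == pytest.approx(
                0.5 * dci_naive[x] + 0.5 * pci_naive, abs=1e-12
            )

    def test_report_serialization(self, rng, tmp_path):
        truth = rng.integers(0, 2, 30)
        preds = {"A": rng.integers(0, 2, 30), "B": rng.integers(0, 2, 30),
                 "C": rng.integers(0, 2, 30)}
        rep = build_report(preds, truth)
        rep.to_json(tmp_path / "report.json")
        rep.matrices_to_csv(tmp_path / "mats")
        import json

        payload = json.loads((tmp_path / "report.json").read_text())
        assert payload["ranking"] == rep.ranking
        assert (tmp_path / "mats" / "diversity_Dis.csv").exists()
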