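import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from phistruct import (
    ABSTAIN,
    ClassCounts,
    confusion_counts,
    confusion_matrix,
    decide,
    evaluate_at_k,
    macro_metrics,
    pr_curve,
    weighted_metrics,
)

from ._oracles import random_prediction_set, tally_metrics

C3 = ["c0", "c1", "c2"]


class TestDecide:
    def test_k_zero_never_abstains(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(4))
            assert decide(p, 0.0, ["a", "b", "c", "d"]) != ABSTAIN

    def test_margin_below_k_abstains(self):
        assert decide([0.5, 0.4, 0.1], 0.2, C3) == ABSTAIN

    def test_margin_above_k_emits_argmax(self):
        assert decide([0.9, 0.05, 0.05], 0.8, C3) == "c0"

    def test_exact_margin_emits(self):
        assert decide([0.6, 0.4, 0.0], 0.2, C3) == "c0"

    def test_tie_takes_earlier_class(self):
        assert decide([0.5, 0.5, 0.0], 0.0, C3) == "c0"

    def test_invalid_vector_rejected(self):
        with pytest.raises(ValueError):
            decide([0.5, 0.4], 0.0, C3)


class TestConfusionCounts:
    def test_all_correct(self):
        truth = ["c0", "c1", "c2"] * 2
        counts = confusion_counts(truth, truth, C3)
        assert all(counts.fp[c] == 0 and counts.fn[c] == 0 for c in C3)
        assert all(counts.tp[c] == 2 for c in C3)

    def test_all_abstain(self):
        truth = ["c0"] * 3 + ["c1"] * 2 + ["OUTGROUP"]
        counts = confusion_counts(truth, [ABSTAIN] * 6, C3)
        assert all(counts.tp[c] == 0 and counts.fp[c] == 0 for c in C3)
        assert counts.fn == {"c0": 3, "c1": 2, "c2": 0}

    def test_outgroup_confident_prediction_is_fp(self):
        counts = confusion_counts(["OUTGROUP"], ["c1"], C3)
        assert counts.fp["c1"] == 1
        assert counts.N == 0  # outgroup not counted in N by default

    def test_count_outgroup_in_n_flag(self):
        counts = confusion_counts(["OUTGROUP", "c0"], ["c1", "c0"], C3,
                                  count_outgroup_in_n=True)
        assert counts.N == 2

    def test_hand_built_table_matches_tally(self):
        truth = ["c0", "c0", "c0", "c1", "c1", "c2", "c2", "c2",
                 "OUTGROUP", "OUTGROUP", "c1", "c0"]
        decisions = ["c0", "c1", ABSTAIN, "c1", "c1", "c2", "c0", ABSTAIN,
                     "c2", ABSTAIN, "c2", "c0"]
        counts = confusion_counts(truth, decisions, C3)
        oracle = tally_metrics(truth, decisions, C3)
        assert counts.tp == oracle["tp"]
        assert counts.fp == oracle["fp"]
        assert counts.fn == oracle["fn"]
        assert counts.n_per_class == oracle["n_c"]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(["weird"], ["c0"], C3)


def _hand_counts():
    # two classes: TP=(2,1), FP=(1,0), FN=(0,2), n=(2,3), N=5
    return ClassCounts(
        classes=["a", "b"],
        tp={"a": 2, "b": 1},
        fp={"a": 1, "b": 0},
        fn={"a": 0, "b": 2},
        tn={"a": 0, "b": 0},
        n_per_class={"a": 2, "b": 3},
        N=5,
    )


class TestMetricFormulas:
    def test_perfect_predictions(self):
        truth = ["c0", "c1", "c2"] * 3
        counts = confusion_counts(truth, truth, C3)
        assert macro_metrics(counts) == (1.0, 1.0, 1.0)

    def test_all_abstain_recall_zero(self):
        counts = confusion_counts(["c0", "c1"], [ABSTAIN, ABSTAIN], C3)
        _, recall, _ = macro_metrics(counts)
        assert recall == 0.0

    def test_macro_hand_computation(self):
        # class a: P=2/3, R=1, F1=0.8; class b: P=1, R=1/3, F1=0.5
        p, r, f = macro_metrics(_hand_counts())
        assert p == pytest.approx((2 / 3 + 1) / 2)
        assert r == pytest.approx((1 + 1 / 3) / 2)
        assert f == pytest.approx((0.8 + 0.5) / 2)

    def test_weighted_hand_computation(self):
        p, r, f = weighted_metrics(_hand_counts())
        assert p == pytest.approx((2 * 2 / 3 + 3 * 1) / 5)
        assert r == pytest.approx((2 * 1 + 3 / 3) / 5)
        assert f == pytest.approx((2 * 0.8 + 3 * 0.5) / 5)

    def test_weighted_equals_macro_for_equal_sizes_no_outgroup(self):
        truth = ["c0"] * 4 + ["c1"] * 4 + ["c2"] * 4
        decisions = ["c0"] * 3 + ["c1"] + ["c1"] * 4 + ["c2"] * 2 + ["c0", ABSTAIN]
        counts = confusion_counts(truth, decisions, C3)
        assert np.allclose(macro_metrics(counts), weighted_metrics(counts))

    def test_zero_n_rejected(self):
        counts = confusion_counts(["OUTGROUP"], [ABSTAIN], C3)
        with pytest.raises(ValueError):
            weighted_metrics(counts)

    def test_matches_sklearn_without_abstention_or_outgroup(self, rng):
        truth = [C3[i] for i in rng.integers(0, 3, 60)]
        pred = [C3[i] for i in rng.integers(0, 3, 60)]
        counts = confusion_counts(truth, pred, C3)
        p, r, f = macro_metrics(counts)
        sp, sr, sf, _ = precision_recall_fscore_support(
            truth, pred, labels=C3, average="macro", zero_division=0
        )
        assert (p, r, f) == pytest.approx((sp, sr, sf))

    def test_oracle_equivalence_random_sets(self, rng):
        for _ in range(100):
            classes, truth, decisions = random_prediction_set(rng)
            counts = confusion_counts(truth, decisions, classes)
            oracle = tally_metrics(truth, decisions, classes)
            assert np.allclose(macro_metrics(counts), oracle["macro"], atol=1e-12)
            assert np.allclose(
                weighted_metrics(counts), oracle["weighted"], atol=1e-12
            )

    def test_macro_f1_between_class_extremes(self, rng):
        for _ in range(30):
            classes, truth, decisions = random_prediction_set(rng)
            counts = confusion_counts(truth, decisions, classes)
            per_f1 = []
            for c in classes:
                tp, fp, fn = counts.tp[c], counts.fp[c], counts.fn[c]
                p = tp / (tp + fp) if tp + fp else 0
                r = tp / (tp + fn) if tp + fn else 0
                per_f1.append(2 * p * r / (p + r) if p + r else 0)
            _, _, f = macro_metrics(counts)
            assert min(per_f1) - 1e-12 <= f <= max(per_f1) + 1e-12


class TestPrCurve:
    def test_default_grid_has_ten_rows(self, rng):
        probs = rng.dirichlet(np.ones(3), size=30)
        truth = [C3[i] for i in rng.integers(0, 3, 30)]
        table = pr_curve(probs, truth, classes=C3)
        assert len(table) == 10
        assert table["k"].tolist() == pytest.approx(
            [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
        )

    def test_one_hot_probs_constant_across_k(self, rng):
        idx = rng.integers(0, 3, 25)
        probs = np.eye(3)[idx]
        truth = [C3[i] for i in rng.integers(0, 3, 25)]
        table = pr_curve(probs, truth, classes=C3)
        assert table["macro_f1"].nunique() == 1
        assert (table["coverage"] == 1.0).all()

    def test_coverage_non_increasing(self, rng):
        probs = rng.dirichlet(np.ones(4) * 0.7, size=80)
        truth = [f"c{i}" for i in rng.integers(0, 4, 80)]
        table = pr_curve(probs, truth, classes=[f"c{i}" for i in range(4)])
        cov = table["coverage"].to_numpy()
        assert (np.diff(cov) <= 1e-12).all()

    def test_unsorted_grid_rejected(self, rng):
        probs = rng.dirichlet(np.ones(3), size=5)
        with pytest.raises(ValueError):
            pr_curve(probs, ["c0"] * 5, k_grid=[0.5, 0.1], classes=C3)


class TestConfusionMatrix:
    def test_perfect_identity_pattern(self):
        truth = ["c0", "c1", "c2"] * 2
        table = confusion_matrix(truth, truth, C3)
        block = table.loc[C3, C3].to_numpy()
        assert np.array_equal(block, 2 * np.eye(3))

    def test_true_normalized_rows_sum_to_one(self, rng):
        truth = [C3[i] for i in rng.integers(0, 3, 40)] + ["OUTGROUP"] * 5
        decisions = [
            (C3[i] if i < 3 else ABSTAIN) for i in rng.integers(0, 4, 45)
        ]
        table = confusion_matrix(truth, decisions, C3, normalize="true")
        sums = table.sum(axis=1)
        for idx, total in sums.items():
            assert total == pytest.approx(1.0) or total == 0.0

    def test_diagonal_is_per_class_recall(self, rng):
        probs = rng.dirichlet(np.ones(3), size=60)
        truth = [C3[i] for i in rng.integers(0, 3, 60)]
        k = 0.2
        decisions = [decide(p, k, C3) for p in probs]
        table = confusion_matrix(truth, decisions, C3, normalize="true")
        counts = confusion_counts(truth, decisions, C3)
        for c in C3:
            tp, fn = counts.tp[c], counts.fn[c]
            recall = tp / (tp + fn) if tp + fn else 0.0
            assert table.loc[c, c] == pytest.approx(recall)

    def test_pred_normalized_diagonal_is_precision(self, rng):
        truth = [C3[i] for i in rng.integers(0, 3, 50)]
        decisions = [C3[i] for i in rng.integers(0, 3, 50)]
        table = confusion_matrix(truth, decisions, C3, normalize="pred")
        counts = confusion_counts(truth, decisions, C3)
        for c in C3:
            tp, fp = counts.tp[c], counts.fp[c]
            precision = tp / (tp + fp) if tp + fp else 0.0
            assert table.loc[c, c] == pytest.approx(precision)
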