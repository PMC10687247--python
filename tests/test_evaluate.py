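import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathsound.evaluate import (
    SplitSpec,
    binary_metrics,
    class_distribution,
    per_patient_stats,
    roc_curve,
    round_half_away,
    split_train_test,
    three_class_metrics,
)

from .oracles import auc_pairwise

labels_strategy = st.lists(
    st.sampled_from(["NS", "VS", "SS"]), min_size=6, max_size=60
).filter(lambda ls: all(ls.count(c) >= 2 for c in set(ls)))


class TestSplit:
    def test_80_20(self):
        train, test = split_train_test(["NS"] * 5 + ["VS"] * 5, SplitSpec(seed=0))
        assert len(train) == 8 and len(test) == 2

    def test_stratified_per_class_rounding(self):
        labels = ["NS"] * 60 + ["VS"] * 20 + ["SS"] * 20
        train, test = split_train_test(labels, SplitSpec(seed=1))
        labels = np.array(labels)
        counts = {c: int(np.sum(labels[train] == c)) for c in ("NS", "VS", "SS")}
        assert counts == {"NS": 48, "VS": 16, "SS": 16}

    def test_determinism(self):
        labels = ["NS"] * 10 + ["SS"] * 10
        a = split_train_test(labels, SplitSpec(seed=3))
        b = split_train_test(labels, SplitSpec(seed=3))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="stratified"):
            split_train_test(["NS", "NS", "VS"], SplitSpec())

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0)

    @given(labels_strategy, st.integers(0, 100))
    @settings(max_examples=30, deadline=None)
    def test_disjoint_exhaustive(self, labels, seed):
        train, test = split_train_test(labels, SplitSpec(seed=seed))
        combined = np.sort(np.concatenate([train, test]))
        np.testing.assert_array_equal(combined, np.arange(len(labels)))


class TestBinaryMetrics:
    def test_perfect(self):
        y = ["NS", "VS", "SS", "NS"]
        rep = binary_metrics(y, y, scores=[0, 1, 1, 0])
        for key in ("accuracy", "sensitivity", "specificity", "ppv", "npv", "auc"):
            assert rep.binary[key] == pytest.approx(1.0), key

    def test_hand_confusion(self):
        # TP=3, FN=1, TN=2, FP=2 (positive = abnormal)
        y_true = ["VS", "VS", "SS", "VS", "NS", "NS", "NS", "NS"]
        y_pred = ["VS", "VS", "SS", "NS", "NS", "NS", "VS", "SS"]
        rep = binary_metrics(y_true, y_pred)
        assert rep.binary["sensitivity"] == pytest.approx(0.75)
        assert rep.binary["specificity"] == pytest.approx(0.5)
        assert rep.binary["accuracy"] == pytest.approx(0.625)
        assert rep.binary["ppv"] == pytest.approx(0.6)
        assert rep.binary["npv"] == pytest.approx(2 / 3)
        assert rep.binary_confusion.to_numpy().sum() == 8

    def test_undefined_ratio_absent(self):
        rep = binary_metrics(["NS", "NS"], ["NS", "NS"])
        assert rep.binary["sensitivity"] is None  # no positives
        assert rep.binary["ppv"] is None
        assert rep.binary["specificity"] == pytest.approx(1.0)

    def test_auc_limits(self):
        y = ["NS", "NS", "VS", "VS"]
        sep = binary_metrics(y, y, scores=[0.1, 0.2, 0.8, 0.9]).binary["auc"]
        tied = binary_metrics(y, y, scores=[0.5, 0.5, 0.5, 0.5]).binary["auc"]
        assert sep == pytest.approx(1.0)
        assert tied == pytest.approx(0.5)

    def test_positive_class_flip(self):
        y_true = ["VS", "VS", "SS", "VS", "NS", "NS", "NS", "NS"]
        y_pred = ["VS", "VS", "SS", "NS", "NS", "NS", "VS", "SS"]
        rep = binary_metrics(y_true, y_pred, positive="normal")
        assert rep.binary["sensitivity"] == pytest.approx(0.5)
        assert rep.binary["specificity"] == pytest.approx(0.75)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            binary_metrics(["NS"], ["NS", "VS"])


class TestROC:
    def test_perfect_separation_passes_01(self):
        points, auc = roc_curve(["NS", "NS", "VS", "SS"], [0.1, 0.2, 0.9, 0.8])
        assert (0.0, 1.0) in points
        assert auc == pytest.approx(1.0)

    def test_staircase_monotone(self):
        rng = np.random.default_rng(0)
        y = ["VS" if v else "NS" for v in rng.integers(0, 2, 200)]
        points, _ = roc_curve(y, rng.random(200))
        arr = np.array(points)
        assert np.all(np.diff(arr[:, 0]) >= 0)
        assert np.all(np.diff(arr[:, 1]) >= 0)
        assert tuple(arr[0]) == (0.0, 0.0) and tuple(arr[-1]) == (1.0, 1.0)

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(1)
        y = ["VS" if v else "NS" for v in rng.integers(0, 2, 1000)]
        _, auc = roc_curve(y, rng.random(1000))
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(50):
            n = int(rng.integers(6, 30))
            y = np.array(["NS"] * n + ["VS"] * n)
            scores = np.round(rng.random(2 * n), 2)  # coarse -> many ties
            _, auc = roc_curve(y, scores)
            assert auc == pytest.approx(auc_pairwise(y, scores, "VS"), abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        y = ["VS" if v else "NS" for v in rng.integers(0, 2, 100)]
        s = rng.random(100)
        _, a1 = roc_curve(y, s)
        _, a2 = roc_curve(y, np.exp(5 * s))
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(["NS", "NS"], [0.1, 0.2])


class TestThreeClassMetrics:
    def test_all_correct(self):
        rep = three_class_metrics(["NS", "VS", "SS"], ["NS", "VS", "SS"])
        assert rep.three_class["total_accuracy"] == pytest.approx(1.0)
        assert rep.three_class["accuracy_in_abnormal"] == pytest.approx(1.0)

    def test_hand_example(self):
        rep = three_class_metrics(
            ["NS", "VS", "SS", "SS"], ["NS", "SS", "SS", "VS"]
        )
        assert rep.three_class["total_accuracy"] == pytest.approx(0.5)
        assert rep.three_class["accuracy_in_abnormal"] == pytest.approx(1 / 3)

    def test_no_abnormal_absent(self):
        rep = three_class_metrics(["NS", "NS"], ["NS", "VS"])
        assert rep.three_class["accuracy_in_abnormal"] is None

    def test_confusion_totals(self):
        rng = np.random.default_rng(4)
        y_true = np.array(["NS", "VS", "SS"])[rng.integers(0, 3, 50)]
        y_pred = np.array(["NS", "VS", "SS"])[rng.integers(0, 3, 50)]
        rep = three_class_metrics(y_true, y_pred)
        cm = rep.three_class_confusion
        assert cm.to_numpy().sum() == 50
        assert np.trace(cm.to_numpy()) / 50 == pytest.approx(
            rep.three_class["total_accuracy"]
        )

    def test_binary_collapse_consistency(self):
        rng = np.random.default_rng(5)
        y_true = np.array(["NS", "VS", "SS"])[rng.integers(0, 3, 80)]
        y_pred = np.array(["NS", "VS", "SS"])[rng.integers(0, 3, 80)]
        rep = binary_metrics(y_true, y_pred)
        cm = rep.binary_confusion.to_numpy()
        assert (cm[0, 0] + cm[1, 1]) / cm.sum() == pytest.approx(
            rep.binary["accuracy"]
        )


class TestSummaries:
    def test_paper_table_percentages(self):
        labels = ["NS"] * 1449 + ["VS"] * 1313 + ["SS"] * 1188
        dist = class_distribution(labels)
        assert dist.loc["NS", "percent"] == 36.7
        assert dist.loc["VS", "percent"] == 33.2
        assert dist.loc["SS", "percent"] == 30.1
        assert dist["count"].sum() == 3950

    def test_single_class(self):
        dist = class_distribution(["VS", "VS"])
        assert dist.loc["VS", "percent"] == 100.0

    def test_tally_oracle(self):
        rng = np.random.default_rng(6)
        labels = list(np.array(["NS", "VS", "SS"])[rng.integers(0, 3, 123)])
        dist = class_distribution(labels)
        for cls in ("NS", "VS", "SS"):
            assert dist.loc[cls, "count"] == sum(1 for l in labels if l == cls)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            class_distribution([])

    def test_per_patient_mean_overall(self):
        # 3950 sounds over 23 patients -> mean 171.7 at table precision
        rng = np.random.default_rng(7)
        counts = rng.multinomial(3950, np.ones(23) / 23)
        stats = per_patient_stats(counts)
        assert round_half_away(stats.loc["value", "mean"], 1) == 171.7

    def test_per_patient_class_means(self):
        ns = np.full(23, 63)  # 1449 = 23 * 63
        stats = per_patient_stats(ns)
        assert stats.loc["value", "mean"] == pytest.approx(63.0)

    def test_single_patient_flagged(self):
        stats = per_patient_stats([5])
        assert stats.loc["value", "mean"] == pytest.approx(5.0)
        assert stats.loc["value", "n"] == 1
        assert np.isnan(stats.loc["value", "sd"])

    def test_dataframe_input_totals(self):
        df = pd.DataFrame({"NS": [2, 4], "VS": [1, 3]})
        stats = per_patient_stats(df)
        assert stats.loc["NS", "mean"] == pytest.approx(3.0)
        assert stats.loc["total", "mean"] == pytest.approx(5.0)

    def test_empty_patients_rejected(self):
        with pytest.raises(ValueError):
            per_patient_stats([])

    def test_round_half_away(self):
        assert round_half_away(36.7088 * 10 / 10, 1) == 36.7
        assert round_half_away(0.25, 1) == 0.3
        assert round_half_away(-0.25, 1) == -0.3


class TestAccuracyTraceProperty:
    @given(st.integers(0, 1000), st.integers(10, 60))
    @settings(max_examples=25, deadline=None)
    def test_accuracy_equals_trace_over_n(self, seed, n):
        rng = np.random.default_rng(seed)
        y_true = np.array(["NS", "VS", "SS"])[rng.integers(0, 3, n)]
        y_pred = np.array(["NS", "VS", "SS"])[rng.integers(0, 3, n)]
        rep = three_class_metrics(y_true, y_pred)
        cm = rep.three_class_confusion.to_numpy()
        assert rep.three_class["total_accuracy"] == pytest.approx(np.trace(cm) / n)
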