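"""Metric formulas against brute-force tallies, aggregation, t-tests, gains."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from imfcnet.evaluation import (ConfusionMatrix, FoldMetrics,
                                average_p_value, class_imbalance_percent,
                                confusion, f1_of_means, gain_report,
                                metrics_from_cm, aggregate, paired_ttest,
                                report_table, round_half_up)

LABELS = ("C1", "C2", "C3", "C4")


def brute_force_metrics(y_true, y_pred, labels):
    """Independent tally straight from the label pairs."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    precisions, recalls = [], []
    for cls in labels:
        tp = np.sum((y_true == cls) & (y_pred == cls))
        fp = np.sum((y_true != cls) & (y_pred == cls))
        fn = np.sum((y_true == cls) & (y_pred != cls))
        precisions.append(tp / (tp + fp) if tp + fp else 0.0)
        recalls.append(tp / (tp + fn) if tp + fn else 0.0)
    acc = 100.0 * np.mean(y_true == y_pred)
    ap = 100.0 * np.mean(precisions)
    ar = 100.0 * np.mean(recalls)
    f1 = 2 * ap * ar / (ap + ar) if ap + ar else 0.0
    return acc, ap, ar, f1


def test_confusion_hand_counts():
    cm = confusion(["C1", "C1", "C2", "C2"], ["C1", "C2", "C2", "C2"], LABELS)
    assert cm.counts[0].tolist() == [1, 1, 0, 0]
    assert cm.counts[1].tolist() == [0, 2, 0, 0]
    assert cm.total == 4


def test_confusion_perfect_predictions_diagonal():
    y = ["C1", "C2", "C3", "C4"]
    cm = confusion(y, y, LABELS)
    assert np.array_equal(cm.counts, np.eye(4, dtype=int))


def test_confusion_rejects_unknown_labels():
    with pytest.raises(ValueError, match="C9"):
        confusion(["C1"], ["C9"], LABELS)


def test_confusion_row_normalized_diagonal_is_recall():
    cm = ConfusionMatrix(np.array([[5, 1, 0, 0], [2, 4, 0, 0],
                                   [0, 0, 6, 0], [0, 0, 0, 6]]), LABELS)
    rn = cm.row_normalized()
    assert np.allclose(np.diag(rn), [500 / 6, 400 / 6, 100, 100])


def test_metrics_from_cm_hand_tally():
    cm = ConfusionMatrix(np.array([[5, 1, 0, 0], [2, 4, 0, 0],
                                   [0, 0, 6, 0], [0, 0, 0, 6]]), LABELS)
    fm = metrics_from_cm(cm)
    assert fm.acc == pytest.approx(100 * 21 / 24)
    # per-class precision: 5/7, 4/5, 1, 1; recall: 5/6, 4/6, 1, 1
    assert fm.ap == pytest.approx(100 * (5 / 7 + 4 / 5 + 1 + 1) / 4)
    assert fm.ar == pytest.approx(100 * (5 / 6 + 4 / 6 + 1 + 1) / 4)
    assert fm.f1 == pytest.approx(2 * fm.ap * fm.ar / (fm.ap + fm.ar))


def test_metrics_perfect_diagonal():
    fm = metrics_from_cm(ConfusionMatrix(np.eye(4, dtype=int) * 5, LABELS))
    assert (fm.acc, fm.ap, fm.ar, fm.f1) == (100.0, 100.0, 100.0, 100.0)


def test_metrics_match_brute_force_on_1000_random_vectors(rng):
    """The confusion-matrix route must agree with direct label-pair tallies."""
    for _ in range(1000):
        n = rng.integers(4, 40)
        y_true = rng.choice(LABELS, size=n)
        y_pred = rng.choice(LABELS, size=n)
        fm = metrics_from_cm(confusion(y_true, y_pred, LABELS))
        acc, ap, ar, f1 = brute_force_metrics(y_true, y_pred, LABELS)
        assert fm.acc == pytest.approx(acc, abs=1e-9)
        assert fm.ap == pytest.approx(ap, abs=1e-9)
        assert fm.ar == pytest.approx(ar, abs=1e-9)
        assert fm.f1 == pytest.approx(f1, abs=1e-9)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(0, 3), min_size=8, max_size=40),
       st.lists(st.integers(0, 3), min_size=8, max_size=40),
       st.permutations(range(4)))
def test_metrics_invariant_under_class_relabeling(true_ids, pred_ids, perm):
    n = min(len(true_ids), len(pred_ids))
    labels = np.array(LABELS)
    y_true, y_pred = labels[true_ids[:n]], labels[pred_ids[:n]]
    fm = metrics_from_cm(confusion(y_true, y_pred, LABELS))
    mapping = {LABELS[i]: LABELS[perm[i]] for i in range(4)}
    y_true_p = np.array([mapping[v] for v in y_true])
    y_pred_p = np.array([mapping[v] for v in y_pred])
    fm_p = metrics_from_cm(confusion(y_true_p, y_pred_p, LABELS))
    for m in ("acc", "ap", "ar", "f1"):
        assert getattr(fm, m) == pytest.approx(getattr(fm_p, m), abs=1e-9)


def test_never_predicted_class_warns_and_counts_zero_precision():
    cm = ConfusionMatrix(np.array([[3, 0, 0, 0], [3, 0, 0, 0],
                                   [0, 0, 3, 0], [0, 0, 0, 3]]), LABELS)
    with pytest.warns(UserWarning, match="never predicted"):
        fm = metrics_from_cm(cm)
    assert fm.ap == pytest.approx(100 * (0.5 + 0 + 1 + 1) / 4)


def _folds(values, metric_values=None):
    return [FoldMetrics(acc=v, ap=v, ar=v, f1=v, fold_id=i)
            for i, v in enumerate(values)]


def test_aggregate_two_point_formula():
    agg = aggregate(_folds([80.0, 90.0]))
    assert agg["acc"][0] == pytest.approx(85.0)
    assert agg["acc"][1] == pytest.approx(np.sqrt(50.0))  # ~7.071


def test_aggregate_constant_folds_zero_std_and_single_fold_warns():
    assert aggregate(_folds([70.0, 70.0, 70.0]))["f1"][1] == 0.0
    with pytest.warns(UserWarning, match="single fold"):
        agg = aggregate(_folds([88.0]))
    assert agg["acc"] == (88.0, 0.0)


def test_report_table_roundtrips_mean_and_std():
    folds = _folds([80.0, 90.0, 85.0])
    table = report_table({"model": folds})
    assert table.loc[0, "ACC ± Std"] == "85.00 ± 5.00"


def test_per_fold_f1_differs_from_f1_of_means():
    folds = [FoldMetrics(acc=0, ap=90.0, ar=80.0, f1=2 * 90 * 80 / 170),
             FoldMetrics(acc=0, ap=60.0, ar=95.0, f1=2 * 60 * 95 / 155)]
    mean_f1 = np.mean([f.f1 for f in folds])
    assert mean_f1 != pytest.approx(f1_of_means(folds))


def test_paired_ttest_identical_folds_p_one():
    folds = _folds([80.0, 85.0, 90.0])
    with pytest.warns(UserWarning, match="zero variance"):
        report = paired_ttest(folds, _folds([80.0, 85.0, 90.0]))
    assert all(p == 1.0 for p in report.p_values.values())
    assert report.average_p == 1.0
    assert report.verdict == "not significant"


def test_paired_ttest_matches_scipy_and_verdicts(rng):
    a_vals = rng.normal(90, 2, size=10)
    b_vals = a_vals - rng.normal(4, 0.5, size=10)
    a = _folds(list(a_vals))
    b = _folds(list(b_vals))
    report = paired_ttest(a, b)
    expected = stats.ttest_rel(a_vals, b_vals).pvalue
    assert report.p_values["acc"] == pytest.approx(expected)
    assert report.gains["acc"] == pytest.approx(a_vals.mean() - b_vals.mean())
    assert report.verdict in ("95% confidence", "99% confidence")


def test_paired_ttest_requires_matching_folds():
    with pytest.raises(ValueError, match="equal length"):
        paired_ttest(_folds([1, 2, 3]), _folds([1, 2]))
    b = _folds([1.0, 2.0, 3.0])
    for f in b:
        f.fold_id += 1
    with pytest.raises(ValueError, match="fold ids differ"):
        paired_ttest(_folds([1.0, 2.0, 3.0]), b)


def test_average_p_values_match_reported_rounding():
    # the two published per-metric p-value sets and their averages
    p_inception = (0.0599, 0.0246, 0.0343, 0.029)
    assert round_half_up(average_p_value(p_inception), 3) == 0.037
    p_mobilenet = (0.0012, 0.0002, 0.001, 0.0002)
    assert round_half_up(average_p_value(p_mobilenet), 4) == 0.0007


def test_gain_report_reproduces_published_gains():
    proposed = {"acc": 89.09, "ap": 89.54, "ar": 86.57, "f1": 87.94}
    inception = {"acc": 85.77, "ap": 86.25, "ar": 81.76, "f1": 83.85}
    mobilenet = {"acc": 83.22, "ap": 81.41, "ar": 79.81, "f1": 80.56}
    g1 = gain_report(proposed, inception)
    assert round_half_up(g1["acc"], 2) == 3.32
    assert round_half_up(g1["ap"], 2) == 3.29
    g2 = gain_report(proposed, mobilenet)
    assert round_half_up(g2["acc"], 2) == 5.87
    assert round_half_up(g2["ap"], 2) == 8.13
    assert gain_report(proposed, proposed) == {m: 0.0 for m in proposed}


def test_class_imbalance_percentages():
    assert round_half_up(class_imbalance_percent(294, 83), 2) == 71.77
    assert round_half_up(class_imbalance_percent(149, 83), 1) == 44.3


def test_round_half_up():
    assert round_half_up(0.00065, 4) == 0.0007
    assert round_half_up(2.345, 2) == 2.35
    assert round_half_up(87.944999, 2) == 87.94
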