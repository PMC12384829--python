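"""Cross-validation plan, model selection, metrics, ROC/AUC, transitions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pdcognet as p
from pdcognet import network as net
from pdcognet.evaluation import FoldResult, round_half_up
from pdcognet.preprocessing import IMPAIRED, INTACT


def _labels(n_pos, n_neg):
    return np.array([IMPAIRED] * n_pos + [INTACT] * n_neg)


# ------------------------------------------------------------------- folds
def test_folds_divisible_case_is_exact():
    plan = p.make_stratified_folds(_labels(10, 40), k=5, seed=0)
    y = _labels(10, 40)
    for fold in range(5):
        sel = plan.assignments == fold
        assert (y[sel] == IMPAIRED).sum() == 2
        assert (y[sel] == INTACT).sum() == 8


def test_folds_cohort_sized_counts():
    # 192 impaired in 5 folds -> per-fold counts in {38, 39}
    plan = p.make_stratified_folds(_labels(192, 426), k=5, seed=1)
    y = _labels(192, 426)
    counts = [
        int((y[plan.assignments == f] == IMPAIRED).sum()) for f in range(5)
    ]
    assert sorted(set(counts)) == [38, 39]
    assert sum(counts) == 192


def test_folds_reject_small_class():
    with pytest.raises(ValueError):
        p.make_stratified_folds(_labels(4, 40), k=5, seed=0)


def test_folds_stratified_across_many_seeds():
    y = _labels(31, 87)
    global_prop = 31 / 118
    for seed in range(100):
        plan = p.make_stratified_folds(y, k=5, seed=seed)
        for fold in range(5):
            sel = plan.assignments == fold
            n_pos = (y[sel] == IMPAIRED).sum()
            assert abs(n_pos - global_prop * sel.sum()) <= 1


def test_folds_deterministic():
    y = _labels(30, 70)
    a = p.make_stratified_folds(y, k=5, seed=7)
    b = p.make_stratified_folds(y, k=5, seed=7)
    assert np.array_equal(a.assignments, b.assignments)


# --------------------------------------------------------------- cross-val
def test_cross_validation_partitions_subjects(fold_results, preprocessed):
    _, _, X, _ = preprocessed
    all_idx = np.concatenate([r.test_indices for r in fold_results])
    assert len(all_idx) == len(X)
    assert len(np.unique(all_idx)) == len(X)
    for r in fold_results:
        assert r.impaired_recall is None or 0 <= r.impaired_recall <= 1


def test_cross_validation_deterministic(preprocessed):
    fm, gmap, X, y = preprocessed
    plan = p.make_stratified_folds(y, k=3, seed=5)
    Y = net.labels_to_onehot(y)
    tc = net.TrainConfig(seed=5, max_epochs=8)
    r1 = p.cross_validate(X, Y, plan, tc)
    r2 = p.cross_validate(X, Y, plan, tc)
    for a, b in zip(r1, r2):
        assert a.confusion == b.confusion


# ---------------------------------------------------------- model selection
def _fold_result(fold, recall_frac, intact_errors):
    tp, fn = recall_frac
    return FoldResult(
        fold=fold,
        params=net.init_network(2, (2,), seed=fold),
        confusion=p.ConfusionCounts(TP=tp, FN=fn, FP=intact_errors, TN=50),
        test_indices=np.arange(1),
    )


def test_select_best_model_tie_breaks():
    # recalls (.8,.9,.85,.9,.7), intact errors (10,12,9,8,20) -> fold 3 (0-based)
    recalls = [(8, 2), (9, 1), (85, 15), (9, 1), (7, 3)]
    errors = [10, 12, 9, 8, 20]
    results = [_fold_result(i, r, e) for i, (r, e) in enumerate(zip(recalls, errors))]
    best_fold, _ = p.select_best_model(results)
    assert best_fold == 3


def test_select_best_model_single_and_full_tie():
    single = [_fold_result(0, (5, 5), 2)]
    assert p.select_best_model(single)[0] == 0
    tied = [_fold_result(i, (5, 5), 2) for i in range(5)]
    assert p.select_best_model(tied)[0] == 0


def test_select_best_model_permutation_equivariant():
    results = [_fold_result(i, (5, 5), 2) for i in range(4)]
    rev = list(reversed(results))
    assert p.select_best_model(rev)[0] == min(r.fold for r in rev)


# ----------------------------------------------------------------- confusion
def test_confusion_perfect_predictions():
    y = _labels(3, 4)
    c = p.confusion_from_predictions(y, y)
    assert (c.FP, c.FN) == (0, 0)
    assert (c.TP, c.TN) == (3, 4)


def test_confusion_all_predicted_impaired():
    y = _labels(3, 4)
    c = p.confusion_from_predictions(y, np.array([IMPAIRED] * 7))
    assert c.TN == 0 and c.FP == 4


def test_confusion_rejects_unknown_label():
    with pytest.raises(ValueError):
        p.confusion_from_predictions([INTACT], ["Borderline"])


def test_confusion_from_published_misclassification_table():
    """The per-transition-class totals (371/92/100/55) and misclassification
    counts (84/3/15/36) imply (TP, FN, TN, FP) = (174, 18, 306, 120)."""
    tp = (92 - 3) + (100 - 15)  # impaired at follow-up, correctly flagged
    fn = 3 + 15
    tn = (371 - 84) + (55 - 36)  # intact at follow-up, correctly cleared
    fp = 84 + 36
    assert (tp, fn, tn, fp) == (174, 18, 306, 120)
    y_true = _labels(tp + fn, tn + fp)
    y_pred = np.array(
        [IMPAIRED] * tp + [INTACT] * fn + [INTACT] * tn + [IMPAIRED] * fp
    )
    c = p.confusion_from_predictions(y_true, y_pred)
    assert (c.TP, c.FN, c.TN, c.FP) == (174, 18, 306, 120)
    assert c.total == 618


# ------------------------------------------------------------------- metrics
def test_metrics_worked_example_full_table():
    c = p.ConfusionCounts(TP=174, FN=18, TN=306, FP=120)
    m = p.metrics_from_confusion(c)
    assert m.impaired["recall"] == pytest.approx(174 / 192)
    assert round_half_up(m.impaired["recall"]) == 0.91
    assert round_half_up(m.impaired["precision"]) == 0.59
    assert round_half_up(m.impaired["f1"]) == 0.72
    assert round_half_up(m.intact["precision"]) == 0.94
    assert round_half_up(m.intact["recall"]) == 0.72
    assert round_half_up(m.intact["f1"]) == 0.82
    assert round_half_up(m.accuracy) == 0.78
    assert round_half_up(m.macro_recall) == 0.81


def test_metrics_perfect_predictions():
    m = p.metrics_from_confusion(p.ConfusionCounts(TP=5, FN=0, TN=5, FP=0))
    assert m.impaired == {"precision": 1.0, "recall": 1.0, "f1": 1.0}
    assert m.accuracy == 1.0 and m.macro_recall == 1.0


def test_metrics_undefined_ratios_are_none_not_zero():
    m = p.metrics_from_confusion(p.ConfusionCounts(TP=0, FP=0, TN=5, FN=3))
    assert m.impaired["precision"] is None
    assert m.impaired["recall"] == 0.0
    assert m.macro_recall is not None  # both recalls defined here


@given(
    st.tuples(
        st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
    ).filter(lambda t: sum(t) > 0)
)
def test_micro_accuracy_is_prevalence_weighted_recall(counts):
    tp, fp, tn, fn = counts
    m = p.metrics_from_confusion(p.ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
    total = tp + fp + tn + fn
    weighted = 0.0
    if tp + fn:
        weighted += (tp + fn) / total * m.impaired["recall"]
    if tn + fp:
        weighted += (tn + fp) / total * m.intact["recall"]
    assert m.accuracy == pytest.approx(weighted)


def test_f1_is_harmonic_mean():
    m = p.metrics_from_confusion(p.ConfusionCounts(TP=30, FP=20, TN=40, FN=10))
    pr, rc = m.impaired["precision"], m.impaired["recall"]
    assert m.impaired["f1"] == pytest.approx(2 * pr * rc / (pr + rc))


def test_round_half_up_convention():
    assert round_half_up(0.905) == 0.91
    assert round_half_up(0.775) == 0.78


# --------------------------------------------------------------------- ROC
def _auc_pair_count(y, scores):
    """Brute-force rank statistic: P(impaired score > intact score), ties 0.5."""
    pos = [s for s, l in zip(scores, y) if l == IMPAIRED]
    neg = [s for s, l in zip(scores, y) if l == INTACT]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


def test_roc_perfect_separation():
    y = _labels(3, 3)
    roc = p.roc_and_auc(y, [0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
    assert roc.auc == pytest.approx(1.0)
    assert roc.tpr[0] == 0 and roc.fpr[0] == 0
    assert roc.tpr[-1] == 1 and roc.fpr[-1] == 1


def test_roc_constant_scores_is_chance():
    y = _labels(4, 6)
    roc = p.roc_and_auc(y, np.full(10, 0.5))
    assert roc.auc == pytest.approx(0.5)


def test_roc_three_point_example():
    # scores (0.9, 0.8, 0.3) with labels (1, 0, 1): pairs (0.9 vs 0.8) win,
    # (0.3 vs 0.8) loss -> AUC 0.5... by pair counting
    y = np.array([IMPAIRED, INTACT, IMPAIRED])
    scores = [0.9, 0.8, 0.3]
    expected = _auc_pair_count(y, scores)
    roc = p.roc_and_auc(y, scores)
    assert roc.auc == pytest.approx(expected)


def test_roc_monotone_curve_and_requires_both_classes():
    rng = np.random.default_rng(0)
    y = _labels(20, 30)
    scores = rng.random(50)
    roc = p.roc_and_auc(y, scores)
    assert (np.diff(roc.tpr) >= 0).all() and (np.diff(roc.fpr) >= 0).all()
    assert (np.diff(roc.thresholds) <= 0).all()
    with pytest.raises(ValueError):
        p.roc_and_auc(np.array([IMPAIRED, IMPAIRED]), [0.1, 0.9])


@pytest.mark.parametrize("seed", range(5))
def test_roc_trapezoid_equals_pair_count_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 150
    y = np.where(rng.random(n) < 0.35, IMPAIRED, INTACT)
    if len(set(y)) < 2:
        y[0], y[1] = IMPAIRED, INTACT
    scores = rng.choice([0.1, 0.25, 0.5, 0.5, 0.8, 0.93], size=n)  # many ties
    roc = p.roc_and_auc(y, scores)
    sk = pytest.importorskip("sklearn.metrics")
    assert roc.auc == pytest.approx(_auc_pair_count(y, scores), abs=1e-12)
    assert roc.auc == pytest.approx(
        sk.roc_auc_score(y == IMPAIRED, scores), abs=1e-12
    )


# -------------------------------------------------------------- transitions
def test_transition_table_perfect_predictor(cohort):
    y = cohort.followup_labels
    table = p.transition_error_table(cohort.transition_classes, y, y)
    assert (table["misclassified"] == 0).all()
    assert table["count"].sum() == len(y)


def test_transition_table_errors_sum_to_fp_plus_fn(cohort, preprocessed, best_model):
    _, _, X, y = preprocessed
    pred = net.predict(best_model, X)
    table = p.transition_error_table(cohort.transition_classes, y, pred)
    c = p.confusion_from_predictions(y, pred)
    assert table["misclassified"].sum() == c.FP + c.FN
    assert (table["misclassified"] <= table["count"]).all()


def test_transition_table_published_shape_implies_accuracy():
    # totals (371, 92, 100, 55), misclassified (84, 3, 15, 36) -> acc (618-138)/618
    counts = np.array([371, 92, 100, 55])
    wrong = np.array([84, 3, 15, 36])
    acc = (counts.sum() - wrong.sum()) / counts.sum()
    assert acc == pytest.approx(480 / 618)
    assert round_half_up(acc) == 0.78
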