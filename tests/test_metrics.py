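"""Metric correctness against independent oracles: brute-force pairwise AUC,
hand-computed F1 and quartile/fence arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import blastcurve as bc
from blastcurve.metrics import MetricError


def brute_force_auc(scores, labels):
    """Pairwise oracle: P(random positive outscores random negative), ties half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(4, 21))
            # discrete scores force ties; ensure both classes present
            scores = rng.integers(0, 6, size=n) / 5.0
            labels = np.zeros(n, int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            assert bc.roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_worked_examples(self):
        assert bc.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        # 3 concordant of 4 positive-negative pairs
        assert bc.roc_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)
        assert bc.roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(MetricError):
            bc.roc_auc([0.1, 0.9], [1, 1])

    def test_complement_symmetry_without_ties(self):
        rng = np.random.default_rng(7)
        scores = rng.permutation(20) / 20.0
        labels = (rng.random(20) < 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        a = bc.roc_auc(scores, labels)
        b = bc.roc_auc(scores, 1 - labels)
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestRocCurveAndMean:
    def test_curve_shape_and_auc(self):
        c = bc.roc_curve([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0])
        assert c.false_positive_rate[0] == 0.0 and c.false_positive_rate[-1] == 1.0
        assert c.true_positive_rate[-1] == 1.0
        assert c.auc == pytest.approx(0.75)

    def test_mean_of_one_curve_is_itself(self):
        c = bc.roc_curve([0.9, 0.1, 0.8, 0.2], [1, 0, 1, 0])
        mean_curve, mean_auc = bc.mean_roc([c])
        assert mean_auc == pytest.approx(c.auc)
        assert mean_curve.auc == pytest.approx(c.auc, abs=1e-9)

    def test_mean_of_identical_curves(self):
        c = bc.roc_curve([0.9, 0.4, 0.8, 0.2, 0.3], [1, 0, 1, 0, 1])
        mean_curve, mean_auc = bc.mean_roc([c, c])
        assert mean_auc == pytest.approx(c.auc)
        single, _ = bc.mean_roc([c])
        assert np.allclose(mean_curve.true_positive_rate, single.true_positive_rate)

    def test_mean_of_perfect_and_chance(self):
        perfect = bc.RocCurve(
            thresholds=np.array([np.inf, 1.0, 0.0]),
            false_positive_rate=np.array([0.0, 0.0, 1.0]),
            true_positive_rate=np.array([0.0, 1.0, 1.0]),
            auc=1.0,
        )
        chance = bc.RocCurve(
            thresholds=np.array([np.inf, 0.0]),
            false_positive_rate=np.array([0.0, 1.0]),
            true_positive_rate=np.array([0.0, 1.0]),
            auc=0.5,
        )
        mean_curve, mean_auc = bc.mean_roc([perfect, chance])
        assert mean_auc == pytest.approx(0.75)
        assert mean_curve.auc == pytest.approx(0.75, abs=0.01)  # grid resolution


class TestF1Macro:
    def test_perfect(self):
        assert bc.f1_macro(list("AABBCC"), list("AABBCC")) == 1.0

    def test_hand_computed_example(self):
        # truth AABBCC, pred ABBBCA: F1_A=1/2, F1_B=4/5, F1_C=2/3 -> 59/90
        true = list("AABBCC")
        pred = list("ABBBCA")
        assert bc.f1_macro(pred, true) == pytest.approx(59 / 90, abs=1e-4)

    def test_no_match_is_zero(self):
        assert bc.f1_macro(list("BBB"), list("AAA")) == 0.0

    def test_permutation_and_relabel_invariance(self, rng):
        true = rng.choice(list("ABC"), size=30)
        pred = rng.choice(list("ABC"), size=30)
        base = bc.f1_macro(pred, true)
        perm = rng.permutation(30)
        assert bc.f1_macro(pred[perm], true[perm]) == pytest.approx(base)
        relabel = {"A": "X", "B": "Y", "C": "Z"}
        assert bc.f1_macro(
            [relabel[p] for p in pred], [relabel[t] for t in true]
        ) == pytest.approx(base)

    def test_empty_errors(self):
        with pytest.raises(MetricError):
            bc.f1_macro([], [])


class TestConfusion:
    def test_perfect_diagonal(self):
        cm = bc.confusion(list("AABB"), list("AABB"), ["A", "B"])
        assert np.array_equal(cm.counts, [[2, 0], [0, 2]])
        assert np.allclose(np.diag(cm.row_percent), 100.0)

    def test_hand_counts(self):
        cm = bc.confusion(["A", "B", "B"], ["A", "A", "B"], ["A", "B"])
        assert np.allclose(cm.row_percent[0], [50.0, 50.0])
        assert np.allclose(cm.row_percent[1], [0.0, 100.0])
        assert list(cm.per_class_n) == [2, 1]

    def test_rows_sum_to_100(self, rng):
        true = rng.choice(list("ABC"), size=50)
        pred = rng.choice(list("ABC"), size=50)
        cm = bc.confusion(pred, true, ["A", "B", "C"])
        assert np.allclose(cm.row_percent.sum(axis=1), 100.0, atol=1e-9)

    def test_empty_class_row_flagged_not_zero(self):
        cm = bc.confusion(["A", "A"], ["A", "A"], ["A", "B"])
        assert np.isnan(cm.row_percent[1]).all()

    def test_unknown_label_named(self):
        with pytest.raises(MetricError, match="Q"):
            bc.confusion(["A", "Q"], ["A", "A"], ["A", "B"])


class TestSummarizeBox:
    def test_five_point_quartiles(self):
        box = bc.summarize_box([0.5, 0.7, 0.8, 0.9, 0.95])
        assert box.median == pytest.approx(0.8)
        assert box.q1 == pytest.approx(0.7)
        assert box.q3 == pytest.approx(0.9)
        assert box.whisker_low == 0.5 and box.whisker_high == 0.95
        assert len(box.outliers) == 0

    def test_degenerate_all_equal(self):
        box = bc.summarize_box([0.4] * 6)
        assert box.median == box.q1 == box.q3 == box.whisker_low == box.whisker_high == 0.4
        assert len(box.outliers) == 0

    def test_low_outlier_flagged(self):
        # q1=0.8, q3=0.82, IQR=0.02 -> lower fence 0.77: 0.1 is an outlier
        box = bc.summarize_box([0.1, 0.8, 0.81, 0.82, 0.83])
        assert list(box.outliers) == [0.1]
        assert box.whisker_low == 0.8

    def test_whiskers_within_data_range(self, rng):
        vals = rng.random(40)
        box = bc.summarize_box(vals)
        assert vals.min() <= box.whisker_low <= box.q1 <= box.median
        assert box.median <= box.q3 <= box.whisker_high <= vals.max()

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_box_invariants_property(self, vals):
        box = bc.summarize_box(vals)
        assert box.q1 <= box.median <= box.q3
        assert min(vals) <= box.whisker_low <= box.whisker_high <= max(vals)
        # every value is either inside the whiskers or an outlier
        assert len(box.outliers) + sum(
            box.whisker_low <= v <= box.whisker_high for v in vals
        ) >= len(vals)


@given(
    st.lists(st.integers(0, 7), min_size=4, max_size=16),
    st.data(),
)
@settings(deadline=None, derandomize=True, max_examples=60)
def test_roc_auc_brute_force_property(raw_scores, data):
    """AUC equals the pairwise-comparison oracle on arbitrary tied scores."""
    n = len(raw_scores)
    n_pos = data.draw(st.integers(1, n - 1))
    scores = np.asarray(raw_scores) / 7.0
    labels = np.zeros(n, int)
    labels[:n_pos] = 1
    assert bc.roc_auc(scores, labels) == pytest.approx(
        brute_force_auc(scores, labels), abs=1e-12
    )
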