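"""Confusion metrics, exact AUC, fold construction and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octfundus.core import ProbabilityMap, ValidationError, VesselMask
from octfundus.evaluation import (
    ConfusionCounts, MetricSet, aggregate_folds, confusion, make_folds,
    metrics, roc_auc,
)


def brute_force_auc(p: np.ndarray, t: np.ndarray) -> float:
    """O(P*N) pairwise Mann-Whitney oracle (ties count half)."""
    pos = p[t.astype(bool)]
    neg = p[~t.astype(bool)]
    wins = 0.0
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_prediction(self):
        m = VesselMask((np.arange(16).reshape(4, 4) % 3 == 0).astype(np.uint8))
        c = confusion(m, m)
        assert c.FP == 0 and c.FN == 0
        assert c.total == 16

    def test_inverted_prediction(self):
        t = VesselMask((np.arange(16).reshape(4, 4) % 3 == 0).astype(np.uint8))
        p = VesselMask(1 - t.pixels)
        c = confusion(p, t)
        assert c.TP == 0 and c.TN == 0

    def test_matches_pixel_loop_oracle(self):
        rng = np.random.default_rng(0)
        pred = VesselMask((rng.random((10, 10)) > 0.6).astype(np.uint8))
        truth = VesselMask((rng.random((10, 10)) > 0.7).astype(np.uint8))
        c = confusion(pred, truth)
        tp = tn = fp = fn = 0
        for i in range(10):
            for j in range(10):
                p, t = pred.pixels[i, j], truth.pixels[i, j]
                tp += p and t
                tn += (not p) and (not t)
                fp += p and not t
                fn += (not p) and t
        assert (c.TP, c.TN, c.FP, c.FN) == (tp, tn, fp, fn)

    def test_roi_restricts_counts(self):
        pred = VesselMask(np.ones((4, 4), np.uint8))
        truth = VesselMask(np.zeros((4, 4), np.uint8))
        roi = np.zeros((4, 4), bool)
        roi[0] = True
        assert confusion(pred, truth, roi).total == 4

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            confusion(VesselMask(np.zeros((2, 2), np.uint8)),
                      VesselMask(np.zeros((3, 3), np.uint8)))


class TestMetrics:
    def test_worked_example(self):
        ms = metrics(ConfusionCounts(TP=8, TN=88, FP=2, FN=2))
        assert ms.accuracy == pytest.approx(0.96)
        assert ms.sensitivity == pytest.approx(0.8)
        assert ms.precision == pytest.approx(0.8)
        assert ms.f1 == pytest.approx(0.8)
        assert ms.specificity == pytest.approx(88 / 90)

    def test_zero_denominators_yield_undefined_marker(self):
        ms = metrics(ConfusionCounts(TP=0, TN=10, FP=0, FN=0))
        assert ms.precision is None and ms.sensitivity is None and ms.f1 is None
        assert ms.specificity == 1.0

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValidationError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_agreement_with_independent_formulas(self):
        """Textbook-formula second implementation on random confusions."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(0, 50, 4)
            if tp + tn + fp + fn == 0:
                continue
            ms = metrics(ConfusionCounts(tp, tn, fp, fn))
            assert ms.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn), abs=1e-12)
            if tp + fn:
                assert ms.sensitivity == pytest.approx(tp / (tp + fn), abs=1e-12)
            if tp + fp:
                assert ms.precision == pytest.approx(tp / (tp + fp), abs=1e-12)
            if fp + tn:
                assert ms.specificity == pytest.approx(tn / (fp + tn), abs=1e-12)
            if 2 * tp + fp + fn:
                assert ms.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn), abs=1e-12)

    @given(tp=st.integers(0, 100), tn=st.integers(0, 100),
           fp=st.integers(0, 100), fn=st.integers(0, 100))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_metric_identities(self, tp, tn, fp, fn):
        """Accuracy decomposition and F1 harmonic-mean identity."""
        if tp + tn + fp + fn == 0:
            return
        ms = metrics(ConfusionCounts(tp, tn, fp, fn))
        P, N = tp + fn, tn + fp
        if P and N:
            acc = (ms.sensitivity * P + ms.specificity * N) / (P + N)
            assert ms.accuracy == pytest.approx(acc, abs=1e-12)
        if ms.precision and ms.sensitivity:
            h = 2 * ms.precision * ms.sensitivity / (ms.precision + ms.sensitivity)
            assert ms.f1 == pytest.approx(h, abs=1e-12)


class TestAUC:
    def test_perfect_separation(self):
        t = VesselMask(np.array([[1, 1, 0, 0]], np.uint8))
        p = ProbabilityMap(np.array([[0.9, 0.8, 0.2, 0.1]]))
        assert roc_auc(p, t) == 1.0

    def test_all_ties_is_half(self):
        t = VesselMask(np.array([[1, 0, 1, 0]], np.uint8))
        p = ProbabilityMap(np.full((1, 4), 0.5))
        assert roc_auc(p, t) == pytest.approx(0.5)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            t = (rng.random(30) > 0.5).astype(np.uint8)
            if t.all() or not t.any():
                continue
            # quantized probabilities force ties to be handled
            p = np.round(rng.random(30), 1)
            auc = roc_auc(ProbabilityMap(p[None]), VesselMask(t[None]))
            assert auc == pytest.approx(brute_force_auc(p, t), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        p = rng.random(40)
        t = (rng.random(40) > 0.6).astype(np.uint8)
        a1 = roc_auc(ProbabilityMap(p[None]), VesselMask(t[None]))
        a2 = roc_auc(ProbabilityMap((p ** 3)[None]), VesselMask(t[None]))
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="both classes"):
            roc_auc(ProbabilityMap(np.zeros((2, 2))),
                    VesselMask(np.ones((2, 2), np.uint8)))


class TestFolds:
    def test_study_protocol_24_items_6_folds(self):
        split = make_folds(list(range(24)), 6, seed=0)
        assert split.n_folds == 6
        all_test = []
        for fold in split:
            assert len(fold["train"]) == 20 and len(fold["test"]) == 4
            assert not set(fold["train"]) & set(fold["test"])
            all_test += fold["test"]
        assert sorted(all_test) == list(range(24))

    def test_leave_one_out(self):
        split = make_folds(list("abcdef"), 6, seed=1)
        for fold in split:
            assert len(fold["test"]) == 1 and len(fold["train"]) == 5

    def test_subject_pairing_never_split(self):
        items = [f"s{i}_{eye}" for i in range(12) for eye in ("L", "R")]
        pairing = {it: it.split("_")[0] for it in items}
        split = make_folds(items, 6, seed=3, pairing=pairing)
        for fold in split:
            test_subjects = {pairing[it] for it in fold["test"]}
            train_subjects = {pairing[it] for it in fold["train"]}
            assert not test_subjects & train_subjects

    def test_deterministic_given_seed(self):
        a = make_folds(list(range(24)), 6, seed=9)
        b = make_folds(list(range(24)), 6, seed=9)
        assert a.folds == b.folds

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValidationError):
            make_folds([1, 2, 3], 4)


class TestAggregate:
    def test_single_fold_identity(self):
        ms = MetricSet(accuracy=0.9, f1=0.8)
        mean, table = aggregate_folds([ms])
        assert mean.accuracy == 0.9 and mean.f1 == 0.8
        assert len(table) == 1

    def test_two_fold_mean(self):
        mean, _ = aggregate_folds([MetricSet(f1=0.9), MetricSet(f1=0.7)])
        assert mean.f1 == pytest.approx(0.8)

    def test_undefined_entries_excluded(self):
        mean, table = aggregate_folds([MetricSet(f1=0.9, precision=None),
                                       MetricSet(f1=0.7, precision=0.5)])
        assert mean.f1 == pytest.approx(0.8)
        assert mean.precision == pytest.approx(0.5)
        assert table[0]["precision"] is None
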