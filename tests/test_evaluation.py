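"""Evaluation battery: confusion metrics, ROC/PR, thresholding, trimming
and identity-binned AUC, cross-checked against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idrbrnn import (
    ChainScores,
    ConfusionCounts,
    auc_by_identity_bins,
    auc_pr,
    auc_roc,
    binary_metrics,
    confusion,
    evaluate_scores,
    pr_curve,
    roc_curve,
    threshold_at_fpr,
    trim_termini,
)


def pair_count_auc(scores, labels):
    """Mann-Whitney oracle: fraction of (positive, negative) pairs ranked
    correctly, ties counting one half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    total = wins = 0.0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                wins += 1
            elif p == n:
                wins += 0.5
    return wins / total


class TestConfusion:
    def test_threshold_zero_everything_positive(self):
        c = confusion([0.1, 0.9, 0.4], "101", 0.0)
        assert (c.tn, c.fn) == (0, 0) and c.tp + c.fp == 3

    def test_threshold_above_one_everything_negative(self):
        c = confusion([0.1, 0.9, 0.4], "101", 1.01)
        assert (c.tp, c.fp) == (0, 0) and c.tn + c.fn == 3

    def test_hand_enumerated_table(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05]
        labels = "1101001010"
        c = confusion(scores, labels, 0.5)
        # by hand: scored >= 0.5 are the first five
        assert (c.tp, c.fp, c.tn, c.fn) == (3, 2, 3, 2)

    def test_equal_to_threshold_is_positive(self):
        c = confusion([0.5], "1", 0.5)
        assert c.tp == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion([], "", 0.5)


class TestBinaryMetrics:
    def test_perfect_classifier(self):
        m = binary_metrics(ConfusionCounts(tp=10, fp=0, tn=90, fn=0))
        assert (m.sensitivity, m.specificity, m.precision) == (1, 1, 1)
        assert m.balanced_accuracy == 1 and m.mcc == 1

    def test_hand_computed_example(self):
        m = binary_metrics(ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(5 / 6)
        assert m.precision == pytest.approx(0.75)
        assert m.balanced_accuracy == pytest.approx((0.75 + 5 / 6) / 2)
        assert m.mcc == pytest.approx(14 / 24)

    def test_mcc_zero_denominator_convention(self):
        m = binary_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=2))
        assert m.mcc == 0.0

    def test_mcc_invariant_under_class_swap(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(0, 50, size=4)
            a = binary_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            b = binary_metrics(ConfusionCounts(int(tn), int(fn), int(tp), int(fp)))
            assert a.mcc == pytest.approx(b.mcc)


class TestROC:
    def test_perfect_separation_auc_one(self):
        assert auc_roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_random_scores_auc_half(self, rng):
        scores = rng.uniform(size=10000)
        labels = rng.integers(0, 2, size=10000)
        assert abs(auc_roc(scores, labels) - 0.5) < 0.02

    def test_four_point_pair_counting(self):
        # 3 of 4 positive/negative pairs correctly ordered
        assert auc_roc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_roc([0.1, 0.2], [1, 1])

    def test_curve_monotone(self, rng):
        scores = rng.uniform(size=200)
        labels = rng.integers(0, 2, size=200)
        curve = roc_curve(scores, labels)
        assert np.all(np.diff(curve.points[:, 0]) >= 0)
        assert np.all(np.diff(curve.points[:, 1]) >= 0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 9), st.booleans()), min_size=4, max_size=50
        )
    )
    def test_auc_equals_pair_counting_oracle(self, data):
        scores = np.array([d[0] / 10 for d in data])
        labels = np.array([int(d[1]) for d in data])
        if labels.min() == labels.max():
            return
        assert auc_roc(scores, labels) == pytest.approx(
            pair_count_auc(scores, labels), abs=1e-12
        )

    def test_metrics_reproduce_curve_points(self, rng):
        scores = rng.uniform(size=60)
        labels = rng.integers(0, 2, size=60)
        curve = roc_curve(scores, labels)
        for t in np.unique(scores):
            m = binary_metrics(confusion(scores, labels, t))
            point = (1 - m.specificity, m.sensitivity)
            assert any(
                np.allclose(point, p, atol=1e-12) for p in curve.points
            )

    def test_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.uniform(size=500)
        labels = rng.integers(0, 2, size=500)
        assert auc_roc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestPR:
    def test_perfect_classifier_auc_one(self):
        assert auc_pr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_constant_scores_precision_is_prevalence(self):
        curve = pr_curve([0.5] * 10, [1, 0, 0, 0, 1, 0, 0, 0, 0, 0])
        # single threshold group: full recall at precision = prevalence
        assert curve.points[-1] == pytest.approx((1.0, 0.2))
        assert curve.area == pytest.approx(0.2)

    def test_four_point_case_matches_exhaustive_sweep(self):
        scores = np.array([0.9, 0.8, 0.4, 0.2])
        labels = np.array([1, 0, 1, 0])
        # brute force: precision/recall at each distinct threshold, descending
        pts = []
        for t in sorted(set(scores), reverse=True):
            pred = scores >= t
            tp = int((pred & (labels == 1)).sum())
            fp = int((pred & (labels == 0)).sum())
            pts.append((tp / 2, tp / (tp + fp)))
        recalls = [0.0] + [r for r, _ in pts]
        precs = [pts[0][1]] + [p for _, p in pts]
        expect = np.trapezoid(precs, recalls)
        assert auc_pr(scores, labels) == pytest.approx(expect)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            auc_pr([0.5, 0.4], [0, 0])


class TestThresholdAtFPR:
    def test_target_one_gives_minimal_threshold(self, rng):
        scores = rng.uniform(size=100)
        labels = rng.integers(0, 2, size=100)
        t = threshold_at_fpr(scores, labels, 1.0)
        assert t == scores.min()

    def test_target_zero_excludes_every_negative(self, rng):
        scores = rng.uniform(size=100)
        labels = rng.integers(0, 2, size=100)
        t = threshold_at_fpr(scores, labels, 0.0)
        assert not np.any(scores[labels == 0] >= t)

    def test_realized_fpr_within_granularity(self, rng):
        scores = rng.uniform(size=2000)
        labels = (rng.uniform(size=2000) < 0.1).astype(int)
        t = threshold_at_fpr(scores, labels, 0.05)
        neg = scores[labels == 0]
        fpr = (neg >= t).mean()
        assert fpr <= 0.05
        assert fpr > 0.05 - 1.0 / neg.size

    def test_all_tied_scores_warn_and_exceed_max(self):
        with pytest.warns(UserWarning):
            t = threshold_at_fpr([0.4] * 10, [1, 0] * 5, 0.0)
        assert t > 0.4


class TestTrimming:
    def test_zero_trim_is_identity(self, rng):
        chains = [ChainScores("a", rng.uniform(size=30), rng.integers(0, 2, 30))]
        assert trim_termini(chains, 0) == chains

    def test_short_chain_drops_out_and_lengths_shrink(self, rng):
        chains = [
            ChainScores("a", rng.uniform(size=25), rng.integers(0, 2, 25)),
            ChainScores("b", rng.uniform(size=20), rng.integers(0, 2, 20)),
        ]
        out = trim_termini(chains, 10)
        assert [c.id for c in out] == ["a"]
        assert len(out[0].scores) == 5

    def test_metrics_match_mask_oracle(self, rng):
        chains = [
            ChainScores(
                f"c{i}",
                rng.uniform(size=40 + i),
                rng.integers(0, 2, size=40 + i),
            )
            for i in range(5)
        ]
        trimmed = trim_termini(chains, 10)
        s = np.concatenate([c.scores for c in trimmed])
        y = np.concatenate([c.labels for c in trimmed])
        # mask-based oracle over the original arrays
        ms, my = [], []
        for c in chains:
            mask = np.zeros(len(c.scores), bool)
            mask[10:-10] = True
            ms.append(c.scores[mask])
            my.append(c.labels[mask])
        np.testing.assert_array_equal(s, np.concatenate(ms))
        np.testing.assert_array_equal(y, np.concatenate(my))


class TestIdentityBins:
    def test_single_bin_table(self, rng):
        chains = [
            ChainScores("a", rng.uniform(size=50), rng.integers(0, 2, 50)),
            ChainScores("b", rng.uniform(size=50), rng.integers(0, 2, 50)),
        ]
        table = auc_by_identity_bins(chains, {"a": 0.62, "b": 0.65})
        defined = table.dropna(subset=["auc"])
        assert len(defined) == 1
        assert defined.iloc[0].bin_lo == pytest.approx(0.6)
        assert defined.iloc[0].n_chains == 2

    def test_boundary_half_open(self, rng):
        chains = [ChainScores("a", rng.uniform(size=50), rng.integers(0, 2, 50))]
        table = auc_by_identity_bins(chains, {"a": 0.5})
        row = table[table.n_chains == 1].iloc[0]
        assert row.bin_lo == pytest.approx(0.5)

    def test_top_bin_closed(self, rng):
        chains = [ChainScores("a", rng.uniform(size=50), rng.integers(0, 2, 50))]
        table = auc_by_identity_bins(chains, {"a": 1.0})
        row = table[table.n_chains == 1].iloc[0]
        assert row.bin_lo == pytest.approx(0.9)

    def test_single_class_bin_undefined(self):
        chains = [ChainScores("a", np.array([0.1, 0.2]), np.array([0, 0]))]
        table = auc_by_identity_bins(chains, {"a": 0.3})
        assert np.isnan(table[table.n_chains == 1].iloc[0].auc)


def test_report_round_trip(rng):
    scores = rng.uniform(size=300)
    labels = rng.integers(0, 2, size=300)
    rep = evaluate_scores(scores, labels, 0.5)
    d = rep.to_dict()
    assert d["tp"] + d["fp"] + d["tn"] + d["fn"] == 300
    assert 0 <= d["auc_roc"] <= 1 and 0 <= d["auc_pr"] <= 1
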