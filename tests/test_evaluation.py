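"""SE/SP/ACC formulas, ROC/AUC and the resampling protocol."""

import math

import numpy as np
import pytest

from hairpinnet import (Confusion, HairpinError, RfConfig, confusion,
                        resampling_protocol, roc_auc, se_sp_acc,
                        vertical_average_roc)
from hairpinnet.evaluation import evaluate_split
from hairpinnet.forest import HairpinForestClassifier

import _oracles as oracle

from conftest import gaussian_design

P, N = "positive", "negative"


class TestConfusion:
    def test_all_correct(self):
        c = confusion([P, N, P], [P, N, P])
        assert (c.FP, c.FN) == (0, 0) and (c.TP, c.TN) == (2, 1)

    def test_all_wrong_direction(self):
        c = confusion([P] * 4, [N] * 4)
        assert (c.TP, c.FN) == (0, 4)

    def test_counts_partition_records(self):
        rng = np.random.default_rng(0)
        truth = rng.choice([P, N], 30)
        pred = rng.choice([P, N], 30)
        c = confusion(truth, pred)
        assert c.n == 30

    def test_negative_counts_rejected(self):
        with pytest.raises(HairpinError):
            Confusion(TP=-1, TN=0, FP=0, FN=0)


class TestSeSpAcc:
    def test_perfect_sensitivity_on_worked_positive_counts(self):
        se, _, _ = se_sp_acc(Confusion(TP=30, FN=0, TN=0, FP=0))
        assert se == 1.0

    def test_specificity_on_worked_negative_counts(self):
        _, sp, _ = se_sp_acc(Confusion(TN=895, FP=105, TP=0, FN=0))
        assert sp == pytest.approx(0.895)

    def test_balanced_half(self):
        assert se_sp_acc(Confusion(1, 1, 1, 1)) == (0.5, 0.5, 0.5)

    def test_undefined_metric_is_nan(self):
        se, sp, acc = se_sp_acc(Confusion(TP=0, FN=0, TN=3, FP=1))
        assert math.isnan(se) and sp == 0.75


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [P, P, N, N])
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_auc([0.5] * 6, [P, P, P, N, N, N])
        assert auc == 0.5

    def test_half_ordered_pairs(self):
        _, auc = roc_auc([0.9, 0.2, 0.4, 0.8], [P, P, N, N])
        assert auc == 0.5  # 2 of the 4 (pos, neg) pairs correctly ordered

    def test_curve_endpoints_and_monotonicity(self):
        curve, _ = roc_auc([0.3, 0.7, 0.6, 0.1], [P, N, P, N])
        assert tuple(curve[0]) == (0.0, 0.0) and tuple(curve[-1]) == (1.0, 1.0)
        assert (np.diff(curve[:, 0]) >= 0).all()

    def test_matches_pair_counting_oracle_on_random_scores(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 20))
            labels = [P, N] + list(rng.choice([P, N], n - 2))
            scores = list(np.round(rng.random(n), 1))  # ties likely
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(
                oracle.auc_pair_counting(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(HairpinError):
            roc_auc([0.1, 0.2], [P, P])


class TestVerticalAverageRoc:
    def test_identical_curves_zero_band_width(self):
        curve, _ = roc_auc([0.9, 0.4, 0.6, 0.1], [P, N, P, N])
        bands = vertical_average_roc([curve] * 5)
        assert (bands["tpr_p10"] == bands["tpr_p90"]).all()
        assert (bands["tpr_mean"] == bands["tpr_p50"]).all()

    def test_percentile_bands_ordered(self):
        rng = np.random.default_rng(1)
        curves = []
        for _ in range(10):
            labels = [P, N] * 10
            curves.append(roc_auc(rng.random(20), labels)[0])
        bands = vertical_average_roc(curves)
        for lo, hi in (("tpr_p10", "tpr_p25"), ("tpr_p25", "tpr_p50"),
                       ("tpr_p50", "tpr_p75"), ("tpr_p75", "tpr_p90")):
            assert (bands[lo] <= bands[hi] + 1e-12).all()

    def test_two_step_curves_interpolate_linearly(self):
        a = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0]])   # perfect
        b = np.array([[0.0, 0.0], [1.0, 1.0]])               # diagonal
        bands = vertical_average_roc([a, b])
        grid = bands["fpr"].to_numpy()
        expected = (1.0 + grid) / 2.0  # mean of TPR=1 and TPR=fpr
        assert bands["tpr_mean"].to_numpy() == pytest.approx(expected)


class TestResamplingProtocol:
    @pytest.fixture(scope="class")
    def design(self):
        return gaussian_design(n_per_class=60, shifts=[2.0, 2.0], n_noise=2,
                               seed=13)

    def test_single_repeat_equals_single_split(self, design):
        cfg = RfConfig(ntree=80, mtry=2, seed=0)
        report = resampling_protocol(design, n_train_per_class=40, repeats=1,
                                     seed=42, cfg=cfg)
        # recompute the one split by replaying the seeded draw
        rng = np.random.default_rng(42)
        y = np.asarray(design.y, dtype=object)
        classes = np.unique(y)
        train_idx = np.concatenate([
            rng.choice(np.flatnonzero(y == c), size=40, replace=False)
            for c in classes])
        mask = np.zeros(len(y), dtype=bool)
        mask[train_idx] = True
        clf = HairpinForestClassifier(80, 2,
                                      random_state=int(rng.integers(2**31 - 1)))
        clf.fit(design.X[mask], y[mask])
        se, sp, acc, auc, _ = evaluate_split(clf, design.X[~mask], y[~mask])
        assert (report.se, report.sp, report.acc, report.auc) == \
            (se, sp, acc, auc)

    def test_report_means_match_per_repeat_table(self, design):
        report = resampling_protocol(design, n_train_per_class=40, repeats=5,
                                     seed=3, cfg=RfConfig(ntree=60, mtry=2))
        assert report.auc == pytest.approx(report.per_repeat["AUC"].mean())
        assert report.se == pytest.approx(report.per_repeat["SE"].mean())

    def test_identical_seed_identical_report(self, design):
        kwargs = dict(n_train_per_class=40, repeats=3, seed=9,
                      cfg=RfConfig(ntree=60, mtry=2))
        r1 = resampling_protocol(design, **kwargs)
        r2 = resampling_protocol(design, **kwargs)
        assert r1.per_repeat.equals(r2.per_repeat)
        assert r1.roc.equals(r2.roc)

    def test_insufficient_class_size_rejected(self, design):
        with pytest.raises(HairpinError):
            resampling_protocol(design, n_train_per_class=60, repeats=1,
                                seed=0)
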