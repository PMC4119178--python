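"""Confusion tables, accuracy measures, ROC/AUC, cross-validation."""

import math

import numpy as np
import pytest
import sklearn.metrics

from mutacyp.evaluation import (
    ConfusionTable,
    compare_methods,
    confusion,
    cross_validate,
    cv_consensus_labels,
    metrics,
    roc_auc,
    select_final_model,
)
from mutacyp.evaluation import FoldResult, CVResult, MetricsReport
from mutacyp.synthetic import SimConfig, simulate_dataset

D, B = "deleterious", "benign"


class TestConfusion:
    def test_all_correct(self):
        labels = [D] * 6 + [B] * 4
        ct = confusion(labels, labels)
        assert (ct.tp, ct.tn, ct.fp, ct.fn) == (6, 4, 0, 0)

    def test_all_wrong_two_rows(self):
        ct = confusion([D, B], [B, D])
        assert (ct.tp, ct.tn, ct.fp, ct.fn) == (0, 0, 1, 1)

    def test_matches_hand_count_on_seeded_fixture(self, rng):
        labels = [D if v else B for v in rng.random(50) > 0.4]
        preds = [D if v else B for v in rng.random(50) > 0.5]
        ct = confusion(labels, preds)
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for l, p in zip(labels, preds):
            key = ("t" if l == p else "f") + ("p" if p == D else "n")
            tally[key] += 1
        assert (ct.tp, ct.tn, ct.fp, ct.fn) == (
            tally["tp"], tally["tn"], tally["fp"], tally["fn"]
        )
        assert ct.total == 50

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            confusion([D, B], [D])

    def test_bd_count_layout(self):
        ct = ConfusionTable.from_bd_counts(bb=55, bd=18, db=13, dd=184)
        assert (ct.tn, ct.fp, ct.fn, ct.tp) == (55, 18, 13, 184)


class TestMetrics:
    @pytest.mark.parametrize(
        "bb,bd,db,dd,q2,r,p,mcc",
        [
            # published benchmark rows: counts → printed metrics
            (55, 18, 13, 184, 88.52, 93.40, 91.09, 0.70),
            (56, 17, 26, 171, 84.07, 86.80, 90.96, 0.61),
            (48, 25, 19, 178, 83.70, 90.36, 87.68, 0.58),
            (50, 18, 31, 108, 76.33, 77.70, 85.71, 0.49),
        ],
    )
    def test_benchmark_confusion_rows(self, bb, bd, db, dd, q2, r, p, mcc):
        rep = metrics(ConfusionTable.from_bd_counts(bb, bd, db, dd))
        assert round(rep.q2, 2) == q2
        assert round(rep.recall, 2) == r
        assert round(rep.precision, 2) == p
        assert round(rep.mcc, 2) == mcc

    def test_perfect_table(self):
        rep = metrics(ConfusionTable(tp=7, tn=5, fp=0, fn=0))
        assert rep.mcc == 1.0 and rep.q2 == 100.0

    def test_undefined_recall_precision_are_nan_not_zero(self):
        rep = metrics(ConfusionTable(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(rep.recall) and math.isnan(rep.precision)
        assert rep.mcc == 0.0  # zero marginal convention

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics(ConfusionTable(0, 0, 0, 0))

    def test_label_swap_negates_mcc(self, rng):
        labels = [D if v else B for v in rng.random(60) > 0.5]
        preds = [D if v else B for v in rng.random(60) > 0.5]
        swapped = [B if p == D else D for p in preds]
        m1 = metrics(confusion(labels, preds)).mcc
        m2 = metrics(confusion(labels, swapped)).mcc
        assert m2 == pytest.approx(-m1, abs=1e-12)

    def test_q2_is_prevalence_weighted_combination_of_rates(self, rng):
        labels = [D if v else B for v in rng.random(80) > 0.3]
        preds = [D if v else B for v in rng.random(80) > 0.5]
        ct = confusion(labels, preds)
        rep = metrics(ct)
        n_pos = ct.tp + ct.fn
        n_neg = ct.tn + ct.fp
        tnr = ct.tn / n_neg * 100
        expected = (n_pos * rep.recall + n_neg * tnr) / (n_pos + n_neg)
        assert rep.q2 == pytest.approx(expected, abs=1e-9)


class TestROC:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        assert roc_auc(scores, [D, D, B, B]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 10, [D] * 4 + [B] * 6) == 0.5

    def test_trapezoid_equals_pairwise_mann_whitney(self, rng):
        scores = np.round(rng.random(300), 2)  # rounding forces ties
        labels = [D if v else B for v in rng.random(300) > 0.45]
        pos = scores[np.array(labels) == D]
        neg = scores[np.array(labels) == B]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        expected = wins / (len(pos) * len(neg))
        assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_matches_reference_implementation(self, rng):
        scores = rng.random(200)
        labels = [D if v else B for v in rng.random(200) > 0.5]
        ref = sklearn.metrics.roc_auc_score(np.array(labels) == D, scores)
        assert roc_auc(scores, labels) == pytest.approx(ref, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(150)
        labels = [D if v else B for v in rng.random(150) > 0.5]
        assert roc_auc(np.exp(3 * scores), labels) == pytest.approx(
            roc_auc(scores, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.9], [D, D])


@pytest.fixture(scope="module")
def separable_set():
    data = simulate_dataset(SimConfig(separation_scale=2.0, seed=42), mode="direct")
    return data.features.to_numpy(float), data.labels


class TestCrossValidation:
    def test_folds_partition_and_validation_disjoint(self, separable_set):
        X, y = separable_set
        cv = cross_validate(X, y, model="lda", seed=0)
        all_test = np.concatenate([f.test_indices for f in cv.folds])
        assert sorted(all_test.tolist()) == list(range(len(X)))
        assert len(cv.folds) == 5

    def test_separable_set_reaches_high_mcc(self, separable_set):
        X, y = separable_set
        cv = cross_validate(X, y, model="rprop", seed=1, n_restarts=3)
        assert cv.mean_test_mcc >= 0.9

    def test_label_permutation_null(self, separable_set):
        X, y = separable_set
        perm = np.random.default_rng(0).permutation(len(y))
        cv = cross_validate(X, [y[i] for i in perm], model="lda", seed=1)
        assert abs(cv.mean_test_mcc) <= 0.15

    def test_same_seed_reproduces_everything(self, separable_set):
        X, y = separable_set
        cv1 = cross_validate(X, y, model="rprop", seed=3, n_restarts=2)
        cv2 = cross_validate(X, y, model="rprop", seed=3, n_restarts=2)
        np.testing.assert_array_equal(cv1.fold_assignments, cv2.fold_assignments)
        assert [f.test.mcc for f in cv1.folds] == [f.test.mcc for f in cv2.folds]
        assert select_final_model(cv1).model_id == select_final_model(cv2).model_id

    def test_summary_reports_mean_and_sd(self, separable_set):
        X, y = separable_set
        cv = cross_validate(X, y, model="lda", seed=0)
        s = cv.summary()
        mccs = [f.test.mcc for f in cv.folds]
        assert s.loc["MCC", "mean"] == pytest.approx(np.mean(mccs))
        assert s.loc["MCC", "sd"] == pytest.approx(np.std(mccs, ddof=1))

    def test_tiny_dataset_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(ValueError, match="25"):
            cross_validate(X, [D] * 5 + [B] * 5)

    def test_consensus_over_fold_winners(self, separable_set):
        X, y = separable_set
        cv = cross_validate(X, y, model="lda", seed=0)
        calls = cv_consensus_labels(cv, X, mode="majority")
        assert len(calls) == len(X)
        # separable data: consensus should agree with truth almost everywhere
        agree = np.mean([c == t for c, t in zip(calls, y)])
        assert agree > 0.95


class TestFinalModelSelection:
    @staticmethod
    def _fold(i, test_mcc, val_mcc):
        rep_t = MetricsReport(q2=0, recall=0, precision=0, mcc=test_mcc)
        rep_v = MetricsReport(q2=0, recall=0, precision=0, mcc=val_mcc)
        return FoldResult(fold=i, model=None, model_id=f"m{i}",
                          validation=rep_v, test=rep_t,
                          test_indices=np.array([i]))

    def test_max_test_mcc_with_gap_tie_break(self):
        folds = [
            self._fold(0, 0.5, 0.55),
            self._fold(1, 0.7, 0.72),   # gap 0.02
            self._fold(2, 0.7, 0.80),   # gap 0.10
            self._fold(3, 0.6, 0.60),
            self._fold(4, 0.4, 0.45),
        ]
        cv = CVResult(folds=folds, fold_assignments=np.zeros(5, int))
        assert select_final_model(cv).model_id == "m1"

    def test_single_fold(self):
        cv = CVResult(folds=[self._fold(0, 0.3, 0.3)],
                      fold_assignments=np.zeros(1, int))
        assert select_final_model(cv).model_id == "m0"


class TestCompareMethods:
    def test_self_comparison(self, rng):
        s = rng.random(40)
        labels = [D if v else B for v in rng.random(40) > 0.5]
        out = compare_methods({"a": s, "b": s}, labels)
        assert out["correlation"].loc["a", "b"] == pytest.approx(1.0)
        assert out["unanimity"] == 1.0

    def test_anticorrelated_scores(self, rng):
        s = rng.random(40)
        out = compare_methods({"a": s, "b": 1 - s})
        assert out["correlation"].loc["a", "b"] == pytest.approx(-1.0)

    def test_missing_predictions_dropped_pairwise(self, rng):
        """Methods with per-mutation gaps are correlated over the shared
        subset only, with the retained count reported."""
        s1 = rng.random(50)
        s2 = rng.random(50)
        s2[:10] = np.nan
        out = compare_methods({"a": s1, "b": s2})
        assert out["pairwise_n"].loc["a", "b"] == 40
        from mutacyp.feature_selection import pearson_r
        assert out["correlation"].loc["a", "b"] == pytest.approx(
            pearson_r(s1[10:], s2[10:]), abs=1e-12
        )
        assert out["calls"]["b"]["missing"] == 10

    def test_tallies_match_independent_recomputation(self, rng):
        tables = {m: rng.random(30) for m in ("a", "b", "c")}
        out = compare_methods(tables)
        for m, s in tables.items():
            assert out["calls"][m]["deleterious"] == int(np.sum(s >= 0.5))
            assert out["calls"][m]["benign"] == int(np.sum(s < 0.5))
        call_mat = np.stack([tables[m] >= 0.5 for m in tables])
        expected_unanimity = np.mean(np.all(call_mat == call_mat[0], axis=0))
        assert out["unanimity"] == pytest.approx(expected_unanimity)
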