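"""Tests of the SVM grid search, LOOCV, metrics, ROC and holdout variant."""

import numpy as np
import pytest

from conftest import make_matrix
from hurstfmri.classify import (
    FoldOutcome,
    GridPoint,
    confusion_metrics,
    grid_search,
    grid_values,
    holdout_validation,
    loocv_at_point,
    retention_analysis,
    roc_auc,
    train_predict,
)
from hurstfmri.exceptions import InvalidInputError, InvalidParameterError
from hurstfmri.selection import SelectionResult, select_features


def outcomes_from(scores_mci, scores_hc, preds=None):
    out = []
    for i, s in enumerate(scores_mci):
        p = preds[i] if preds else ("MCI" if s > 0 else "HC")
        out.append(FoldOutcome(f"m{i}", "MCI", p, float(s), []))
    for i, s in enumerate(scores_hc):
        p = preds[len(scores_mci) + i] if preds else ("MCI" if s > 0 else "HC")
        out.append(FoldOutcome(f"h{i}", "HC", p, float(s), []))
    return out


def brute_force_auc(outcomes):
    """Pairwise Mann-Whitney concordance with ties counted one half."""
    pos = [o.decision_value for o in outcomes if o.true_label == "MCI"]
    neg = [o.decision_value for o in outcomes if o.true_label == "HC"]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestGridValues:
    def test_default_grid_has_33_values(self):
        vals = grid_values()
        assert len(vals) == 33
        assert vals[0] == pytest.approx(2.0 ** -8)
        assert vals[-1] == pytest.approx(2.0 ** 8)
        assert vals[1] == pytest.approx(2.0 ** -7.5)

    def test_degenerate_and_coarse_grids(self):
        np.testing.assert_allclose(grid_values(0, 0, 0.5), [1.0])
        np.testing.assert_allclose(grid_values(-1, 1, 1), [0.5, 1.0, 2.0])

    def test_bad_step(self):
        with pytest.raises(InvalidParameterError):
            grid_values(-8, 8, 0)


class TestTrainPredict:
    def test_separable_clusters_perfect(self, separable_matrix):
        train = separable_matrix.subset(np.arange(0, 16, 2))
        test = separable_matrix.subset(np.arange(1, 16, 2))
        for point in [GridPoint(1.0, 1.0), GridPoint(0.125, 8.0)]:
            out = train_predict(train, test, point)
            assert all(o.predicted_label == o.true_label for o in out)

    def test_train_equals_test_perfect(self, separable_matrix):
        out = train_predict(separable_matrix, separable_matrix, GridPoint(1.0, 1.0))
        assert all(o.predicted_label == o.true_label for o in out)

    def test_label_swap_flips_decision_sign(self, separable_matrix):
        train = separable_matrix
        test = separable_matrix.subset(np.arange(4))
        out = train_predict(train, test, GridPoint(0.5, 2.0))
        swapped = make_matrix(
            n_mci=8, n_hc=8, n_features=2, effect=8.0, affected=(0, 1),
            noise=0.5, seed=7,
        )
        swapped.groups = ["HC" if g == "MCI" else "MCI" for g in swapped.groups]
        out_sw = train_predict(swapped, test, GridPoint(0.5, 2.0))
        for a, b in zip(out, out_sw):
            # sign symmetry up to the SVM solver's numerical tolerance
            assert a.decision_value == pytest.approx(-b.decision_value, abs=1e-3)

    def test_single_class_training_rejected(self, separable_matrix):
        train = separable_matrix.subset(np.arange(8))  # MCI only
        with pytest.raises(InvalidInputError):
            train_predict(train, separable_matrix, GridPoint(1.0, 1.0))


class TestLoocv:
    def test_fold_count_and_strong_effect_accuracy(self):
        fm = make_matrix(n_mci=12, n_hc=12, n_features=6, effect=2.5,
                         affected=(0, 1, 2), noise=0.5, seed=3)
        acc, outcomes = loocv_at_point(fm, GridPoint(0.25, 4.0))
        assert len(outcomes) == 24
        assert {o.held_out_id for o in outcomes} == set(fm.subject_ids)
        assert acc >= 0.75

    def test_null_accuracy_within_chance_interval(self):
        fm = make_matrix(n_mci=15, n_hc=15, n_features=8, seed=11)
        acc, _ = loocv_at_point(fm, GridPoint(1.0, 1.0))
        half_width = 1.96 * np.sqrt(0.25 / 30)
        assert 0.5 - half_width <= acc <= 0.5 + half_width

    def test_single_point_grid_equals_loocv(self):
        fm = make_matrix(n_mci=8, n_hc=8, n_features=4, effect=1.5,
                         affected=(0,), seed=5)
        point = GridPoint(0.5, 2.0)
        acc, outcomes = loocv_at_point(fm, point)
        res = grid_search(fm, gammas=[0.5], Cs=[2.0])
        assert res.accuracy == acc
        assert res.best_point == point
        for a, b in zip(res.fold_outcomes, outcomes):
            assert a.predicted_label == b.predicted_label
            assert a.decision_value == pytest.approx(b.decision_value)


class TestGridSearch:
    @pytest.fixture(scope="class")
    def effect_result(self):
        fm = make_matrix(n_mci=10, n_hc=10, n_features=6, effect=2.0,
                         affected=(0, 1), noise=0.8, seed=2)
        gammas = grid_values(-4, 4, 2)
        return fm, grid_search(fm, gammas, gammas)

    def test_table_shape_matches_grid(self, effect_result):
        _, res = effect_result
        assert res.per_point_accuracy.shape == (5, 5)

    def test_best_at_least_any_point(self, effect_result):
        _, res = effect_result
        assert res.accuracy == res.per_point_accuracy.max()
        assert (res.per_point_accuracy <= res.accuracy + 1e-12).all()

    def test_tie_break_independent_of_grid_order(self, effect_result):
        fm, res = effect_result
        gam = grid_values(-4, 4, 2)
        res_rev = grid_search(fm, gam[::-1].copy(), gam[::-1].copy())
        assert res_rev.best_point == res.best_point

    def test_deterministic_rerun(self, effect_result):
        fm, res = effect_result
        gam = grid_values(-4, 4, 2)
        res2 = grid_search(fm, gam, gam)
        np.testing.assert_array_equal(res.per_point_accuracy, res2.per_point_accuracy)
        np.testing.assert_array_equal(res.retention_counts, res2.retention_counts)
        assert [o.predicted_label for o in res.fold_outcomes] == [
            o.predicted_label for o in res2.fold_outcomes
        ]

    def test_auc_matches_brute_force(self, effect_result):
        _, res = effect_result
        assert res.auc == pytest.approx(brute_force_auc(res.fold_outcomes), abs=1e-12)


class TestConfusionMetrics:
    def test_printed_rates_consistent(self):
        """53/64 patients and 50/60 controls correct give the canonical
        82.8% / 83.3% / 83.1% sensitivity / specificity / accuracy triple."""
        preds = (["MCI"] * 53 + ["HC"] * 11) + (["HC"] * 50 + ["MCI"] * 10)
        out = outcomes_from([0] * 64, [0] * 60, preds)
        acc, sens, spec = confusion_metrics(out)
        assert round(100 * sens, 1) == 82.8
        assert round(100 * spec, 1) == 83.3
        assert round(100 * acc, 1) == 83.1
        assert acc == pytest.approx(103 / 124)

    def test_all_correct(self):
        out = outcomes_from([1, 2], [-1, -2])
        assert confusion_metrics(out) == (1.0, 1.0, 1.0)

    def test_all_predicted_positive(self):
        out = outcomes_from([1, 1], [1, 1], ["MCI"] * 4)
        acc, sens, spec = confusion_metrics(out)
        assert (sens, spec) == (1.0, 0.0)


class TestRocAuc:
    def test_perfect_ordering(self):
        _, _, auc = roc_auc(outcomes_from([3, 2], [1, 0]))
        assert auc == 1.0

    def test_interleaved_hand_count(self):
        _, _, auc = roc_auc(outcomes_from([3, 1], [2, 0]))
        assert auc == 0.75

    def test_label_swap_complements(self, rng):
        s_m, s_h = rng.standard_normal(7), rng.standard_normal(5)
        _, _, auc = roc_auc(outcomes_from(s_m, s_h))
        _, _, auc_sw = roc_auc(outcomes_from(s_h, s_m))
        assert auc_sw == pytest.approx(1.0 - auc)

    def test_equals_concordance_with_ties(self, rng):
        scores = rng.integers(-2, 3, size=12).astype(float)  # forces ties
        out = outcomes_from(scores[:6], scores[6:])
        _, _, auc = roc_auc(out)
        assert auc == pytest.approx(brute_force_auc(out), abs=1e-12)


class TestRetention:
    @staticmethod
    def _sels(retained_lists, n_feat):
        return [
            SelectionResult(
                retained=r,
                p_values=np.full(n_feat, 0.01),
                fisher_scores=np.arange(n_feat, dtype=float),
                alpha=0.05,
            )
            for r in retained_lists
        ]

    def test_threshold_124_folds(self):
        sels = self._sels([[0]] * 124, 3)
        _, threshold, stable, _ = retention_analysis(sels, 3)
        assert threshold == 118
        assert stable == [0]

    def test_threshold_100_folds(self):
        sels = self._sels([[1, 2]] * 100, 4)
        counts, threshold, stable, fs = retention_analysis(sels, 4)
        assert threshold == 95
        assert stable == [1, 2]
        np.testing.assert_array_equal(counts, [0, 100, 100, 0])

    def test_feature_below_threshold_excluded(self):
        sels = self._sels([[0]] * 90 + [[1]] * 10, 2)
        _, _, stable, _ = retention_analysis(sels, 2)
        assert stable == []


class TestLeakageGuard:
    def test_poisoning_held_out_row_changes_nothing(self):
        """Fold-level selection and training never see the held-out subject:
        replacing that subject's features with sentinels leaves the fold's
        retained set and standardized training design bit-identical."""
        from hurstfmri.classify import _prepare_loocv_folds

        fm = make_matrix(n_mci=6, n_hc=6, n_features=5, effect=1.5,
                         affected=(0, 1), seed=9)
        base = _prepare_loocv_folds(fm, alpha=0.05)
        for i in range(fm.n_subjects):
            poisoned = make_matrix(n_mci=6, n_hc=6, n_features=5, effect=1.5,
                                   affected=(0, 1), seed=9)
            poisoned.values[i] = 1e6
            folds = _prepare_loocv_folds(poisoned, alpha=0.05)
            assert folds[i]["selection"].retained == base[i]["selection"].retained
            np.testing.assert_array_equal(
                folds[i]["selection"].p_values, base[i]["selection"].p_values
            )
            np.testing.assert_array_equal(folds[i]["xtr"], base[i]["xtr"])
            np.testing.assert_array_equal(folds[i]["ytr"], base[i]["ytr"])


class TestHoldout:
    def test_infeasible_split_rejected(self):
        fm = make_matrix(n_mci=5, n_hc=5)
        with pytest.raises(InvalidParameterError):
            holdout_validation(fm, 4, 4, 3, 3)

    def test_strong_effect_generalizes(self):
        fm = make_matrix(n_mci=20, n_hc=20, n_features=6, effect=2.5,
                         affected=(0, 1, 2), noise=0.6, seed=13)
        gam = grid_values(-3, 3, 1.5)
        res = holdout_validation(fm, 13, 13, 7, 7, gammas=gam, Cs=gam, seed=0)
        assert res.accuracy >= 0.75
        assert len(res.test_ids) == 14
        assert set(res.train_ids).isdisjoint(res.test_ids)

    def test_null_within_chance(self):
        fm = make_matrix(n_mci=20, n_hc=20, n_features=6, seed=17)
        gam = grid_values(-2, 2, 2)
        res = holdout_validation(fm, 13, 13, 7, 7, gammas=gam, Cs=gam, seed=1)
        half_width = 1.96 * np.sqrt(0.25 / 14)
        assert 0.5 - half_width <= res.accuracy <= 0.5 + half_width

    def test_seeded_split_reproducible(self):
        fm = make_matrix(n_mci=10, n_hc=10, n_features=4, effect=1.0,
                         affected=(0,), seed=19)
        gam = grid_values(-1, 1, 1)
        a = holdout_validation(fm, 6, 6, 3, 3, gammas=gam, Cs=gam, seed=4)
        b = holdout_validation(fm, 6, 6, 3, 3, gammas=gam, Cs=gam, seed=4)
        assert a.train_ids == b.train_ids
        assert a.accuracy == b.accuracy
        assert a.best_point == b.best_point
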