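"""Metric correctness, CV protocol guarantees, specificity analysis,
label-shuffle control and condition-level correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn import metrics as skm

from hepatox import (ConfusionCounts, EndpointCombination, Pipeline,
                     SmoteConfig, accuracy_report, combination_metrics,
                     combination_table, condition_correlation, confusion,
                     f1, full_metrics, kfold_cv, mcc, round_half_up,
                     y_randomization)
from hepatox.models import RFConfig, build_and_train_rf
from hepatox.features import compute_fold_changes, gene_feature_matrix

from conftest import small_config
from hepatox import generate_study


def rf_model_fn(X, y, seed):
    return build_and_train_rf(X, y, RFConfig(n_trees=60, seed=seed))


class TestConfusion:
    def test_all_correct(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert (c.fp, c.fn) == (0, 0)

    def test_swapping_predictions_swaps_counts(self):
        y = np.array([1, 1, 0, 0, 1])
        p = np.array([1, 0, 0, 1, 1])
        c = confusion(y, p)
        cswap = confusion(y, 1 - p)
        assert (cswap.tp, cswap.fn) == (c.fn, c.tp)
        assert (cswap.tn, cswap.fp) == (c.fp, c.tn)

    def test_four_sample_enumeration(self):
        c = confusion([1, 0, 1, 0], [1, 1, 0, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 1, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1], [1, 0])

    def test_negative_or_empty_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestMccF1:
    def test_perfect_prediction(self):
        assert mcc(ConfusionCounts(5, 5, 0, 0)) == 1.0

    def test_degenerate_denominator_convention(self):
        # no positive predictions at all -> 0 by convention
        assert mcc(ConfusionCounts(tp=0, tn=4, fp=0, fn=2)) == 0.0
        assert f1(ConfusionCounts(tp=0, tn=4, fp=0, fn=0)) == 0.0

    def test_antisymmetry_under_prediction_inversion(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            y = rng.integers(0, 2, 12)
            p = rng.integers(0, 2, 12)
            c, cinv = confusion(y, p), confusion(y, 1 - p)
            if 0 < y.sum() < 12 and 0 < p.sum() < 12:
                assert mcc(cinv) == pytest.approx(-mcc(c))

    def test_agrees_with_sklearn_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            n = int(rng.integers(2, 30))
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            c = confusion(y, p)
            assert mcc(c) == pytest.approx(skm.matthews_corrcoef(y, p),
                                           abs=1e-12)
            assert f1(c) == pytest.approx(
                skm.f1_score(y, p, zero_division=0), abs=1e-12)


class TestFullMetrics:
    def test_perfect_case_all_ones(self):
        rep = full_metrics(ConfusionCounts(3, 7, 0, 0))
        for name in ("mcc", "f1", "sensitivity", "specificity", "ppv",
                     "npv", "balanced_accuracy", "accuracy"):
            assert getattr(rep, name) == 1.0

    def test_all_negative_world_flags_degenerate_sensitivity(self):
        rep = full_metrics(confusion([0, 0, 0], [0, 0, 0]))
        assert rep.specificity == 1.0
        assert rep.sensitivity == 0.0
        assert "sensitivity" in rep.degenerate

    def test_half_up_rounding(self):
        assert round_half_up(0.675, 2) == 0.68
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(-0.0014, 2) == -0.0


class TestAccuracyReport:
    @pytest.mark.parametrize("correct, total, expect", [
        (265, 269, 98.5), (269, 269, 100.0), (0, 10, 0.0)])
    def test_percent(self, correct, total, expect):
        assert accuracy_report(correct, total) == expect

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            accuracy_report(5, 4)


@pytest.fixture(scope="module")
def cv_setup():
    study, truth = generate_study(small_config(seed=21, n_chemicals=24,
                                               animals_per_cohort=3))
    feats = gene_feature_matrix(compute_fold_changes(study),
                                truth.all_signal_genes(), "planted").values
    return study, feats


class TestKFoldCV:
    def test_fold_partition_and_single_oof_prediction(self, cv_setup):
        study, feats = cv_setup
        pipe = Pipeline(lambda s: feats, rf_model_fn, endpoint=2,
                        smote=SmoteConfig(seed=1))
        res = kfold_cv(pipe, study, k=4, seed=5)
        assert (res.fold_of_sample >= 0).all()
        assert len(res.fold_metrics) == 4
        # every sample out-of-fold exactly once, folds partition samples
        sizes = np.bincount(res.fold_of_sample)
        assert sizes.sum() == len(res.sample_ids)
        assert sizes.max() - sizes.min() <= 1

    def test_stratification_preserves_class_balance(self):
        """k=2 on 10 balanced samples: each fold holds 5 samples with the
        same class split."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 2))
        y = np.array([0, 1] * 5)
        from sklearn.model_selection import StratifiedKFold
        folds = list(StratifiedKFold(2, shuffle=True,
                                     random_state=0).split(X, y))
        for _, te in folds:
            assert len(te) == 5 and y[te].sum() in (2, 3)

    def test_leakage_guard_train_and_test_disjoint(self, cv_setup):
        study, feats = cv_setup
        pipe = Pipeline(lambda s: feats, rf_model_fn, endpoint=2,
                        smote=SmoteConfig(seed=1))
        res = kfold_cv(pipe, study, k=3, seed=2)
        for fold, tr in enumerate(res.train_fold_indices):
            held_out = np.where(res.fold_of_sample == fold)[0]
            assert not set(tr) & set(held_out)

    def test_summary_matches_fold_arithmetic(self, cv_setup):
        study, feats = cv_setup
        pipe = Pipeline(lambda s: feats, rf_model_fn, endpoint=2,
                        smote=SmoteConfig(seed=1))
        res = kfold_cv(pipe, study, k=3, seed=7)
        mccs = res.fold_metrics["mcc"].to_numpy()
        summ = res.summary()
        ep = res.fold_metrics["endpoint"].iloc[0]
        assert summ.loc[(ep, "mean"), "mcc"] == pytest.approx(mccs.mean())
        assert summ.loc[(ep, "sd"), "mcc"] == pytest.approx(
            mccs.std(ddof=1))

    def test_seed_determinism(self, cv_setup):
        study, feats = cv_setup
        pipe = Pipeline(lambda s: feats, rf_model_fn, endpoint=2,
                        smote=SmoteConfig(seed=1))
        r1 = kfold_cv(pipe, study, k=3, seed=9)
        r2 = kfold_cv(pipe, study, k=3, seed=9)
        pd.testing.assert_frame_equal(r1.fold_metrics, r2.fold_metrics)
        np.testing.assert_array_equal(r1.oof_pred, r2.oof_pred)

    def test_too_few_positives_suggests_smaller_k(self, cv_setup):
        study, feats = cv_setup
        pipe = Pipeline(lambda s: feats, rf_model_fn, endpoint=1)
        with pytest.raises(ValueError, match="k <="):
            kfold_cv(pipe, study, k=200, seed=0)


class TestCombinationAnalysis:
    def test_perfect_predictions_score_one_for_realized_patterns(self):
        rng = np.random.default_rng(3)
        T = rng.integers(0, 2, size=(40, 3))
        table = combination_table(T, T)
        realized = {tuple(r) for r in T if tuple(r) != (0, 0, 0)}
        for _, row in table.iterrows():
            pat = (row["bh"], row["fib"], row["nec"])
            if pat in realized:
                assert row["mcc"] == 1.0

    def test_six_sample_hand_enumeration(self):
        T = np.array([[1, 0, 0], [1, 0, 0], [0, 1, 0],
                      [0, 0, 1], [1, 1, 0], [0, 0, 0]])
        P = np.array([[1, 0, 0], [0, 0, 1], [0, 1, 0],
                      [0, 0, 1], [1, 0, 0], [0, 0, 0]])
        c, rep = combination_metrics(T, P, EndpointCombination(1, 0, 0))
        # truth-positive: rows 0,1; predicted-positive: rows 0,4
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 3)
        c2, _ = combination_metrics(T, P, EndpointCombination(0, 0, 1))
        assert (c2.tp, c2.fn, c2.fp) == (1, 0, 1)

    def test_counts_sum_to_n_for_every_pattern(self):
        rng = np.random.default_rng(4)
        T = rng.integers(0, 2, size=(25, 3))
        P = rng.integers(0, 2, size=(25, 3))
        table = combination_table(T, P)
        totals = table[["tp", "tn", "fn", "fp"]].sum(axis=1)
        assert (totals == 25).all()

    def test_all_zero_pattern_rejected(self):
        with pytest.raises(ValueError):
            EndpointCombination(0, 0, 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combination_metrics(np.zeros((3, 3)), np.zeros((4, 3)),
                                EndpointCombination(1, 0, 0))


class TestYRandomization:
    def test_shuffled_models_lose_signal_and_runs_are_deterministic(
            self, cv_setup):
        study, feats = cv_setup
        pipe = Pipeline(lambda s: feats, rf_model_fn, endpoint=2,
                        smote=SmoteConfig(seed=1))
        t1 = y_randomization(pipe, study, endpoint=2, n_shuffles=3,
                             seed=13, k=3)
        t2 = y_randomization(pipe, study, endpoint=2, n_shuffles=3,
                             seed=13, k=3)
        pd.testing.assert_frame_equal(t1, t2)
        assert len(t1) == 3
        real = kfold_cv(pipe, study, k=3, seed=13).mean_metric("mcc")
        assert real > t1["mean_mcc"].abs().mean() + 0.2


class TestConditionCorrelation:
    def test_strictly_increasing_pairs(self):
        rho, _ = condition_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == 1.0

    def test_reversed_pairs(self):
        rho, _ = condition_correlation([1, 2, 3], [3, 2, 1])
        assert rho == -1.0

    def test_tied_case_matches_brute_force_rank_formula(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0])
        rho, _ = condition_correlation(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)  # average ranks
        expect = np.corrcoef(rx, ry)[0, 1]  # Pearson on ranks
        assert rho == pytest.approx(expect, abs=1e-12)

    def test_too_few_conditions(self):
        with pytest.raises(ValueError, match="3 conditions"):
            condition_correlation([1, 2], [1, 2])
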