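import math

import numpy as np
import pandas as pd
import pytest

from repforce.errors import ConfigError, InputError
from repforce.evaluate import (
    CVScheme,
    bland_altman,
    compare_models,
    continuous_metrics,
    cross_validate,
    evaluate_predictions,
    make_folds,
    report_table,
    tolerance_metrics,
)
from repforce.model import ModelSpec

from conftest import cohort_table


FAST_RF = ModelSpec("rf", hyperparams={"n_estimators": 60}, seed=0)


def oracle_continuous(pred, true):
    n = len(pred)
    mae = sum(abs(p - t) for p, t in zip(pred, true)) / n
    rmse = math.sqrt(sum((p - t) ** 2 for p, t in zip(pred, true)) / n)
    tbar = sum(true) / n
    pbar = sum(pred) / n
    ss_res = sum((t - p) ** 2 for p, t in zip(pred, true))
    ss_tot = sum((t - tbar) ** 2 for t in true)
    r2 = 1 - ss_res / ss_tot
    num = sum((p - pbar) * (t - tbar) for p, t in zip(pred, true))
    den = math.sqrt(
        sum((p - pbar) ** 2 for p in pred) * sum((t - tbar) ** 2 for t in true)
    )
    return r2, mae, rmse, num / den


class TestMakeFolds:
    def test_groupkfold_keeps_subject_rows_together(self):
        table = cohort_table(seed=1, n_subjects=32)
        groups = table["subject_id"].to_numpy()
        folds = make_folds(CVScheme("groupkfold", 5, 0), len(table), groups)
        for train, test in folds:
            assert not set(groups[train]) & set(groups[test])
        # each subject's 14 rows (2 limbs x 7 sets) land in exactly one test fold
        for g in np.unique(groups):
            in_test = [np.sum(groups[test] == g) for _, test in folds]
            assert sorted(in_test)[-1] == 14
            assert sum(1 for c in in_test if c > 0) == 1

    def test_kfold_test_sizes_balanced(self):
        folds = make_folds(CVScheme("kfold5", 5, 0), 103)
        sizes = [len(test) for _, test in folds]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 103

    def test_same_seed_identical_assignment(self):
        a = make_folds(CVScheme("kfold5", 5, 3), 50)
        b = make_folds(CVScheme("kfold5", 5, 3), 50)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            np.testing.assert_array_equal(te1, te2)

    def test_too_few_groups(self):
        with pytest.raises(InputError):
            make_folds(CVScheme("groupkfold", 5, 0), 8, np.array(list("aabbccdd")))

    def test_unknown_scheme(self):
        with pytest.raises(ConfigError):
            CVScheme("loocv")


class TestContinuousMetrics:
    def test_perfect_prediction(self):
        m = continuous_metrics(np.arange(5.0), np.arange(5.0))
        assert m == {"r2": 1.0, "mae": 0.0, "rmse": 0.0, "pearson_r": 1.0}

    def test_constant_offset(self):
        true = np.array([1.0, 2.0, 3.0, 4.0])
        m = continuous_metrics(true + 1.0, true)
        assert m["mae"] == 1.0
        assert m["rmse"] == 1.0
        assert m["pearson_r"] == pytest.approx(1.0)
        ss_tot = np.sum((true - true.mean()) ** 2)
        assert m["r2"] == pytest.approx(1 - len(true) / ss_tot)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        pred = rng.normal(size=100)
        true = rng.normal(size=100)
        m = continuous_metrics(pred, true)
        r2, mae, rmse, r = oracle_continuous(list(pred), list(true))
        assert m["r2"] == pytest.approx(r2, abs=1e-12)
        assert m["mae"] == pytest.approx(mae, abs=1e-12)
        assert m["rmse"] == pytest.approx(rmse, abs=1e-12)
        assert m["pearson_r"] == pytest.approx(r, abs=1e-12)

    def test_constant_truth_flagged(self):
        m = continuous_metrics(np.array([1.0, 2.0]), np.array([3.0, 3.0]))
        assert math.isnan(m["r2"]) and math.isnan(m["pearson_r"])


class TestToleranceMetrics:
    def test_worked_example(self):
        out = tolerance_metrics(np.array([5.0, 6.0, 7.0]), np.array([5, 5, 9]))
        assert out["accuracies"]["within_1"] == pytest.approx(2 / 3)
        assert out["error_buckets"] == {"le_1": 2, "1_to_2": 1, "gt_2": 0}

    def test_perfect(self):
        out = tolerance_metrics(np.array([3.0, 4.0]), np.array([3, 4]),
                                pred_discrete=np.array([3, 4]))
        assert out["accuracies"] == {"within_0.5": 1.0, "within_1": 1.0}
        assert np.trace(out["confusion"]) == 2

    def test_boundary_inclusive(self):
        out = tolerance_metrics(np.array([4.0, 6.0]), np.array([5, 5]))
        assert out["accuracies"]["within_0.5"] == 0.0
        assert out["accuracies"]["within_1"] == 1.0

    def test_confusion_uses_discrete(self):
        out = tolerance_metrics(
            np.array([4.7, 5.2]), np.array([5, 5]), pred_discrete=np.array([5, 5])
        )
        assert out["exact_accuracy"] == 1.0


class TestBlandAltman:
    def test_zero_diffs(self):
        out = bland_altman(np.ones(4), np.ones(4))
        assert out["mean_diff"] == 0.0
        assert out["loa_low"] == 0.0 and out["loa_high"] == 0.0

    def test_two_point_arithmetic(self):
        out = bland_altman(np.array([1.0, -1.0]), np.zeros(2))
        assert out["mean_diff"] == 0.0
        assert out["sd_diff"] == pytest.approx(math.sqrt(2))
        assert out["loa_high"] == pytest.approx(1.96 * math.sqrt(2))

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        pred = rng.normal(size=20)
        true = rng.normal(size=20)
        a = bland_altman(pred, true)
        b = bland_altman(pred + 3.0, true)
        assert b["mean_diff"] == pytest.approx(a["mean_diff"] + 3.0)
        assert b["sd_diff"] == pytest.approx(a["sd_diff"])

    def test_small_group_flagged(self):
        pred = np.array([1.0, 2.0, 3.0])
        true = np.zeros(3)
        out = bland_altman(pred, true, groups=np.array(["a", "a", "b"]))
        assert out["per_group"]["b"] is None
        assert out["per_group"]["a"]["n"] == 2


class TestCrossValidate:
    def test_every_row_predicted_once(self, small_table):
        res = cross_validate(small_table, FAST_RF, CVScheme("groupkfold", 3, 0))
        assert np.all(np.isfinite(res.pred_continuous))
        assert np.all(res.fold_id >= 0)

    def test_group_rows_share_fold(self, small_table):
        res = cross_validate(small_table, FAST_RF, CVScheme("groupkfold", 3, 0))
        df = pd.DataFrame({"g": res.groups, "f": res.fold_id})
        assert (df.groupby("g")["f"].nunique() == 1).all()

    def test_deterministic(self, small_table):
        r1 = cross_validate(small_table, FAST_RF, CVScheme("groupkfold", 3, 0))
        r2 = cross_validate(small_table, FAST_RF, CVScheme("groupkfold", 3, 0))
        np.testing.assert_array_equal(r1.pred_continuous, r2.pred_continuous)
        np.testing.assert_array_equal(r1.pred_discrete, r2.pred_discrete)

    def test_leaky_variant_runs(self, small_table):
        res = cross_validate(
            small_table, FAST_RF, CVScheme("kfold5", 5, 0), leak_free=False
        )
        assert np.all(np.isfinite(res.pred_continuous))


class TestEvalReport:
    def test_accuracy_ordering_invariant(self, small_table):
        res = cross_validate(small_table, FAST_RF, CVScheme("groupkfold", 3, 0))
        rep = evaluate_predictions(res)
        assert rep.acc_within_10 >= rep.acc_within_05 >= rep.exact_accuracy

    def test_buckets_sum_to_n(self, small_table):
        res = cross_validate(small_table, FAST_RF, CVScheme("groupkfold", 3, 0))
        rep = evaluate_predictions(res)
        assert sum(rep.error_buckets.values()) == len(small_table)

    def test_loa_identity(self, small_table):
        res = cross_validate(small_table, FAST_RF, CVScheme("groupkfold", 3, 0))
        rep = evaluate_predictions(res)
        ba = rep.bland_altman
        assert ba["loa_low"] == pytest.approx(ba["mean_diff"] - 1.96 * ba["sd_diff"])

    def test_mean_diff_near_zero_on_well_specified_data(self):
        table = cohort_table(seed=2, n_subjects=10)
        res = cross_validate(table, FAST_RF, CVScheme("groupkfold", 5, 0))
        rep = evaluate_predictions(res)
        se = rep.bland_altman["sd_diff"] / math.sqrt(len(table))
        assert abs(rep.bland_altman["mean_diff"]) < 3 * se + 0.15

    def test_json_serializable(self, small_table):
        import json

        res = cross_validate(small_table, FAST_RF, CVScheme("groupkfold", 3, 0))
        rep = evaluate_predictions(res)
        json.dumps(rep.to_dict())


class TestCompareModels:
    def test_identical_specs_identical_reports(self, small_table):
        out = compare_models(
            small_table, [FAST_RF, FAST_RF], CVScheme("groupkfold", 3, 0)
        )
        reps = list(out["reports"].values())
        assert reps[0].r2 == reps[1].r2

    def test_all_three_kinds_report(self, small_table):
        specs = [
            ModelSpec("rf", hyperparams={"n_estimators": 40}, seed=0),
            ModelSpec("histgbr", hyperparams={"max_iter": 60}, seed=0),
            ModelSpec("ridge", seed=0),
        ]
        out = compare_models(small_table, specs, CVScheme("groupkfold", 3, 0))
        assert set(out["reports"]) == {"rf", "histgbr", "ridge"}
        assert len(out["ranking"]) == 3
        tbl = report_table(out["reports"])
        assert set(tbl.index) == {"rf", "histgbr", "ridge"}

    def test_ridge_competitive_on_linear_labels(self):
        # labels exactly linear in one feature: the linear baseline should be
        # within noise of the tree models
        rng = np.random.default_rng(0)
        n = 300
        x = rng.uniform(0, 10, size=n)
        table = pd.DataFrame(
            {
                "subject_id": [f"S{i % 20:02d}" for i in range(n)],
                "limb": "L",
                "feat": x,
                "noise": rng.normal(size=n),
                "rpe": np.clip(np.rint(x), 0, 10).astype(int),
            }
        )
        out = compare_models(
            table,
            [
                ModelSpec("rf", hyperparams={"n_estimators": 60}, seed=0),
                ModelSpec("histgbr", hyperparams={"max_iter": 80}, seed=0),
                ModelSpec("ridge", seed=0),
            ],
            CVScheme("groupkfold", 5, 0),
            selection_threshold=0.3,
        )
        r2 = {k: v.r2 for k, v in out["reports"].items()}
        assert r2["ridge"] >= max(r2["rf"], r2["histgbr"]) - 0.05

    def test_requires_two_specs(self, small_table):
        with pytest.raises(InputError):
            compare_models(small_table, [FAST_RF], CVScheme("kfold5", 5, 0))
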