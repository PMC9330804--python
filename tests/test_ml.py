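"""Grouped CV splitting, hyperparameter tuning, learner adapters, importances."""

import warnings

import numpy as np
import pandas as pd
import pytest

from rifpk.ml import (
    HyperparamSpace,
    LeakageError,
    feature_importance,
    fit,
    make_grouped_folds,
    predict,
    run_benchmark,
    tune,
)


def linear_table(n_ids=20, rows_per_id=4, seed=0, noise=0.0):
    """Noiseless (or noisy) linear data: TARGET = 2*x1 - 3*x2 + 5."""
    rng = np.random.default_rng(seed)
    n = n_ids * rows_per_id
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    return pd.DataFrame({
        "ID": np.repeat(np.arange(1, n_ids + 1), rows_per_id),
        "x1": x1, "x2": x2,
        "TARGET": 2 * x1 - 3 * x2 + 5 + noise * rng.normal(size=n)})


class TestGroupedFolds:
    def test_exact_division(self):
        plan = make_grouped_folds(np.arange(10), k=5, seed=1)
        sizes = [len(f) for f in plan.folds]
        assert sizes == [2] * 5
        assert set(np.concatenate(plan.folds)) == set(range(10))

    def test_83_ids_balanced_partition(self):
        plan = make_grouped_folds(np.arange(1, 84), k=5, seed=2)
        assert sorted(len(f) for f in plan.folds) == [16, 16, 17, 17, 17]

    def test_determinism(self):
        a = make_grouped_folds(np.arange(30), k=5, seed=3)
        b = make_grouped_folds(np.arange(30), k=5, seed=3)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa, fb)

    def test_k_larger_than_ids_rejected(self):
        with pytest.raises(ValueError):
            make_grouped_folds(np.arange(3), k=5, seed=0)


class TestTune:
    def test_single_combination_returned_without_evaluation(self):
        space = HyperparamSpace(strategy="grid", grid={"alpha": [0.5]})
        table = linear_table()
        plan = make_grouped_folds(table["ID"], k=2, seed=0)
        assert tune("LASSO", space, table, plan) == {"alpha": 0.5}

    def test_perfect_lambda_selected_on_noiseless_linear_data(self):
        table = linear_table(seed=1)
        plan = make_grouped_folds(table["ID"], k=3, seed=1)
        space = HyperparamSpace(strategy="grid", grid={"alpha": [100.0, 1e-9]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chosen = tune("LASSO", space, table, plan)
        assert chosen == {"alpha": 1e-9}

    def test_sequential_single_stage_equals_grid(self):
        table = linear_table(seed=2, noise=0.5)
        plan = make_grouped_folds(table["ID"], k=3, seed=2)
        grid = {"n_estimators": [20, 50], "max_depth": [2, 3]}
        g = tune("GBM", HyperparamSpace(strategy="grid", grid=grid),
                 table, plan, seed=0)
        s = tune("GBM", HyperparamSpace(strategy="sequential", stages=(grid,),
                                        base={"learning_rate": 0.1}),
                 table, plan, seed=0)
        assert {k: s[k] for k in grid} == g

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            HyperparamSpace(strategy="grid", grid={}).validate()

    def test_inner_folds_must_stay_inside_outer_train(self):
        table = linear_table()
        outer_train = table[table["ID"] <= 15]
        bad_plan = make_grouped_folds(table["ID"], k=3, seed=0)  # includes 16..20
        space = HyperparamSpace(strategy="grid", grid={"alpha": [0.1, 1.0]})
        with pytest.raises(LeakageError):
            tune("LASSO", space, outer_train, bad_plan)


class TestFitPredict:
    def test_constant_target_predicted_by_all_algorithms(self):
        table = linear_table(n_ids=10)
        table["TARGET"] = 7.0
        for algo, hp in [("LASSO", {"alpha": 0.1}),
                         ("GBM", {"n_estimators": 20}),
                         ("RF", {"n_estimators": 20}),
                         ("XGB", {"n_estimators": 20})]:
            model = fit(algo, hp, table, seed=0)
            preds = predict(model, table)
            np.testing.assert_allclose(preds["y_pred"], 7.0, atol=1e-6)

    def test_lasso_infinite_penalty_predicts_training_mean(self):
        table = linear_table(seed=3)
        model = fit("LASSO", {"alpha": 1e6}, table)
        preds = predict(model, table)
        np.testing.assert_allclose(preds["y_pred"], table["TARGET"].mean(),
                                   rtol=1e-9)

    def test_lasso_zero_penalty_recovers_generating_coefficients(self):
        table = linear_table(seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit("LASSO", {"alpha": 0.0}, table)
        pipe = model.estimator
        beta = pipe.named_steps["lasso"].coef_ / pipe.named_steps["scale"].scale_
        X = np.column_stack([np.ones(len(table)), table["x1"], table["x2"]])
        ols = np.linalg.lstsq(X, table["TARGET"], rcond=None)[0]  # oracle
        np.testing.assert_allclose(beta, ols[1:], atol=1e-6)
        np.testing.assert_allclose(beta, [2.0, -3.0], atol=1e-6)

    def test_memorizing_forest_reproduces_training_targets(self):
        table = linear_table(seed=5, noise=1.0)
        model = fit("RF", {"n_estimators": 1, "bootstrap": False,
                           "min_samples_leaf": 1}, table)
        preds = predict(model, table)
        np.testing.assert_allclose(preds["y_pred"], preds["y_obs"], rtol=1e-9)

    def test_empty_test_table_gives_empty_predictions(self):
        table = linear_table()
        model = fit("GBM", {"n_estimators": 10}, table)
        preds = predict(model, table.iloc[0:0])
        assert preds.empty

    def test_schema_mismatch_lists_offending_columns(self):
        table = linear_table()
        model = fit("GBM", {"n_estimators": 10}, table)
        bad = table.assign(x3=1.0)
        with pytest.raises(ValueError, match="x3"):
            predict(model, bad)

    def test_negative_predictions_not_clipped_by_default(self):
        table = linear_table(seed=6)  # targets span negative values
        model = fit("LASSO", {"alpha": 1e-4}, table)
        preds = predict(model, table)
        assert (preds["y_pred"] < 0).any()
        clipped = predict(model, table, clip_negative=True)
        assert (clipped["y_pred"] >= 0).all()

    def test_missing_values_rejected(self):
        table = linear_table()
        table.loc[0, "x1"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit("GBM", {"n_estimators": 10}, table)


class TestImportance:
    def _tad_table(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 400
        tad = rng.uniform(0, 24, size=n)
        return pd.DataFrame({
            "ID": np.repeat(np.arange(1, 41), 10),
            "TAD": tad,
            "AGE": rng.uniform(20, 60, size=n),
            "WT": rng.uniform(40, 90, size=n),
            "TARGET": np.sin(tad / 4) * 10 + 20 * np.exp(-0.3 * tad)})

    @pytest.mark.parametrize("algo", ["GBM", "RF", "XGB"])
    def test_single_informative_feature_ranked_first(self, algo):
        model = fit(algo, {"n_estimators": 50}, self._tad_table(), seed=0)
        ranked = feature_importance(model)
        assert ranked[0][0] == "TAD"
        assert ranked[0][1] > 0.9
        assert sum(s for _, s in ranked) == pytest.approx(1.0)

    def test_lasso_importance_refused_without_override(self):
        table = linear_table()
        model = fit("LASSO", {"alpha": 0.1}, table)
        with pytest.raises(ValueError, match="LASSO"):
            feature_importance(model)
        ranked = feature_importance(model, allow_lasso=True)
        assert {f for f, _ in ranked} == {"x1", "x2"}

    @pytest.mark.parametrize("algo", ["GBM", "RF"])
    def test_permutation_equivariance(self, algo):
        table = self._tad_table(seed=1)
        permuted = table[["ID", "WT", "TAD", "AGE", "TARGET"]]
        a = dict(feature_importance(fit(algo, {"n_estimators": 30}, table, seed=0)))
        b = dict(feature_importance(fit(algo, {"n_estimators": 30}, permuted, seed=0)))
        # tree builders scan candidate features in column order, so exact ties
        # in split gain can break differently; scores agree up to that effect
        for name in a:
            assert a[name] == pytest.approx(b[name], abs=1e-3)


class TestRunBenchmark:
    def test_fold_coverage_and_determinism(self):
        table = linear_table(n_ids=15, noise=0.5)
        plan = make_grouped_folds(table["ID"], k=5, seed=4)
        space = {"LASSO": HyperparamSpace(strategy="grid",
                                          grid={"alpha": [0.01, 0.1]})}
        cells = run_benchmark({1: table}, plan, algorithms=("LASSO",),
                              spaces=space, seed=9, inner_k=3)
        assert len(cells) == 5
        covered = pd.concat([c.predictions for c in cells])["ID"].unique()
        assert set(covered) == set(table["ID"])
        cells2 = run_benchmark({1: table}, plan, algorithms=("LASSO",),
                               spaces=space, seed=9, inner_k=3)
        for c1, c2 in zip(cells, cells2):
            assert c1.hyperparams == c2.hyperparams
            pd.testing.assert_frame_equal(c1.predictions, c2.predictions)

    def test_id_universe_mismatch_rejected(self):
        table = linear_table(n_ids=15)
        plan = make_grouped_folds(np.arange(1, 11), k=5, seed=0)
        with pytest.raises(ValueError, match="IDs"):
            run_benchmark({1: table}, plan, algorithms=("LASSO",), seed=0)
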