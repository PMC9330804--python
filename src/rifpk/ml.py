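"""Grouped-CV benchmark of four supervised learners for PK prediction.

Protocol: outer 5-fold cross-validation grouped by subject ID (every subject
left out exactly once; test folds never inform training or tuning), with
hyperparameter tuning on inner grouped 5-fold splits of each outer-training
set. LASSO, GBM and Random Forest are tuned by exhaustive grid search; XGBoost
by a sequential stage-wise heuristic search (each stage's best values frozen
before the next). The tuning loss is mean inner-validation RMSE; ties keep
the earlier combination in grid order, and default grids are ordered from
more to less regularized so ties resolve toward regularization.

Learner adapters delegate to scikit-learn (L1-penalized linear regression on
standardized features, gradient-boosted trees, random forest with impurity
importances) and xgboost; the protocol around them is authored here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBRegressor

__all__ = [
    "ALGORITHMS", "SplitPlan", "HyperparamSpace", "TrainedModel", "CellResult",
    "default_spaces", "make_grouped_folds", "tune", "fit", "predict",
    "feature_importance", "run_benchmark", "LeakageError",
]

ALGORITHMS = ("LASSO", "GBM", "RF", "XGB")

META_COLUMNS = ("ID", "TARGET")  # never used as features


class LeakageError(RuntimeError):
    """Subject appears on both sides of a train/test split."""


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint subject-ID test folds covering every ID exactly once."""

    folds: tuple  # tuple of np.ndarray of IDs
    seed: int

    def validate(self) -> None:
        all_ids = np.concatenate(self.folds)
        if len(all_ids) != len(np.unique(all_ids)):
            raise LeakageError("a subject ID appears in more than one test fold")


def make_grouped_folds(ids, k: int = 5, seed: int = 0) -> SplitPlan:
    """Partition distinct subject IDs into k shuffled folds (sizes differ <= 1)."""
    unique_ids = np.unique(np.asarray(ids))
    if k > len(unique_ids):
        raise ValueError(f"k={k} exceeds the number of distinct IDs ({len(unique_ids)})")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(unique_ids)
    plan = SplitPlan(folds=tuple(np.sort(f) for f in np.array_split(shuffled, k)),
                     seed=seed)
    plan.validate()
    return plan


@dataclass(frozen=True)
class HyperparamSpace:
    """Search space: exhaustive ``grid`` or ordered ``sequential`` stages.

    Grid-value lists are ordered from more to less regularized, so tie-breaks
    (strict improvement required to switch) favor the regularized setting.
    """

    strategy: str  # "grid" | "sequential"
    grid: dict = field(default_factory=dict)
    stages: tuple = ()       # sequential: tuple of per-stage grids
    base: dict = field(default_factory=dict)  # sequential: starting values

    def validate(self) -> None:
        if self.strategy == "grid":
            if not self.grid or any(len(v) == 0 for v in self.grid.values()):
                raise ValueError("empty hyperparameter grid")
        elif self.strategy == "sequential":
            if not self.stages or any(not s for s in self.stages):
                raise ValueError("sequential search requires non-empty stages")
        else:
            raise ValueError(f"unknown search strategy {self.strategy!r}")


def default_spaces() -> dict[str, HyperparamSpace]:
    return {
        "LASSO": HyperparamSpace(
            strategy="grid",
            grid={"alpha": [float(a) for a in np.logspace(1, -4, 13)]}),
        "GBM": HyperparamSpace(
            strategy="grid",
            grid={"n_estimators": [300],
                  "max_depth": [3, 5],
                  "learning_rate": [0.05, 0.1]}),
        "RF": HyperparamSpace(
            strategy="grid",
            grid={"n_estimators": [200],
                  "max_features": ["sqrt", 0.33],
                  "min_samples_leaf": [5, 1]}),
        "XGB": HyperparamSpace(
            strategy="sequential",
            base={"learning_rate": 0.1, "n_estimators": 300, "max_depth": 3,
                  "min_child_weight": 1, "subsample": 1.0, "reg_lambda": 1.0},
            stages=(
                {"learning_rate": [0.05, 0.1], "n_estimators": [300, 500]},
                {"max_depth": [3, 5], "min_child_weight": [5, 1]},
                {"subsample": [0.8, 1.0], "reg_lambda": [2.0, 1.0]},
            )),
    }


def _build_estimator(algorithm: str, hyperparams: dict, seed: int):
    hp = dict(hyperparams)
    if algorithm == "LASSO":
        # L1 penalties are scale-sensitive: standardize on training rows only
        return Pipeline([("scale", StandardScaler()),
                         ("lasso", Lasso(max_iter=100_000, **hp))])
    if algorithm == "GBM":
        return GradientBoostingRegressor(random_state=seed, **hp)
    if algorithm == "RF":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **hp)
    if algorithm == "XGB":
        # total-gain share matches the gain-based ranking convention of the
        # other boosting implementations (average gain per split would dilute
        # features that contribute through many modest splits)
        return XGBRegressor(objective="reg:squarederror", tree_method="hist",
                            importance_type="total_gain", n_jobs=1,
                            verbosity=0, random_state=seed, **hp)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _split_xy(table: pd.DataFrame):
    features = [c for c in table.columns if c not in META_COLUMNS]
    return table[features], table["TARGET"].to_numpy(), features


@dataclass
class TrainedModel:
    algorithm: str
    hyperparams: dict
    estimator: object
    feature_names: list


def fit(algorithm: str, hyperparams: dict, train: pd.DataFrame,
        seed: int = 0) -> TrainedModel:
    """Fit one learner on a feature table (all columns but ID/TARGET are features)."""
    if train.empty:
        raise ValueError("training table is empty")
    if train.isna().any().any():
        raise ValueError("training table contains missing values")
    X, y, features = _split_xy(train)
    est = _build_estimator(algorithm, hyperparams, seed)
    try:
        est.fit(X, y)
    except Exception as err:  # surface the failing cell's coordinates
        raise RuntimeError(
            f"{algorithm} fit failed with hyperparams {hyperparams}: {err}") from err
    return TrainedModel(algorithm=algorithm, hyperparams=dict(hyperparams),
                        estimator=est, feature_names=features)


def predict(model: TrainedModel, test: pd.DataFrame,
            clip_negative: bool = False) -> pd.DataFrame:
    """Predict the target for every test row.

    Predictions may be negative by default (the learners are unconstrained
    regressors); ``clip_negative`` floors them at 0 as an opt-in.
    Returns ID/OCC (and TAD where present) with observed and predicted target.
    """
    keep = [c for c in ("ID", "OCC", "TAD") if c in test.columns]
    if test.empty:
        return pd.DataFrame(columns=keep + ["y_obs", "y_pred"])
    test_features = [c for c in test.columns if c not in META_COLUMNS]
    if test_features != model.feature_names:
        extra = sorted(set(test_features) - set(model.feature_names))
        missing = sorted(set(model.feature_names) - set(test_features))
        raise ValueError(
            f"feature schema mismatch: extra={extra}, missing={missing}")
    y_pred = np.asarray(model.estimator.predict(test[model.feature_names]),
                        dtype=float)
    if clip_negative:
        y_pred = np.maximum(y_pred, 0.0)
    out = test[keep].copy()
    out["y_obs"] = test["TARGET"].to_numpy()
    out["y_pred"] = y_pred
    return out.reset_index(drop=True)


def _inner_rmse(algorithm: str, hyperparams: dict, outer_train: pd.DataFrame,
                inner_plan: SplitPlan, seed: int) -> float:
    losses = []
    for val_ids in inner_plan.folds:
        mask = outer_train["ID"].isin(val_ids)
        model = fit(algorithm, hyperparams, outer_train[~mask], seed=seed)
        preds = predict(model, outer_train[mask])
        losses.append(float(np.sqrt(np.mean((preds["y_obs"] - preds["y_pred"]) ** 2))))
    return float(np.mean(losses))


def tune(algorithm: str, space: HyperparamSpace, outer_train: pd.DataFrame,
         inner_plan: SplitPlan, seed: int = 0) -> dict:
    """Select hyperparameters by mean inner-validation RMSE.

    Exhaustive grids evaluate every combination; single-combination grids are
    returned without evaluation. Sequential search optimizes each stage in
    order, freezing earlier choices. Strict improvement is required to move
    off an earlier (more regularized) candidate.
    """
    space.validate()
    train_ids = set(outer_train["ID"])
    for val_ids in inner_plan.folds:
        if not train_ids.issuperset(val_ids):
            raise LeakageError("inner validation IDs outside the outer-training set")

    def grid_search(grid: dict, frozen: dict) -> dict:
        names = list(grid)
        combos = [dict(zip(names, values))
                  for values in itertools.product(*(grid[n] for n in names))]
        if len(combos) == 1 and not frozen:
            return combos[0]
        best, best_loss = None, np.inf
        for combo in combos:
            loss = _inner_rmse(algorithm, {**frozen, **combo}, outer_train,
                               inner_plan, seed)
            if loss < best_loss:
                best, best_loss = combo, loss
        return best

    if space.strategy == "grid":
        return grid_search(space.grid, {})
    current = dict(space.base)
    for stage in space.stages:
        frozen = {k: v for k, v in current.items() if k not in stage}
        current.update(grid_search(dict(stage), frozen))
    return current


def feature_importance(model: TrainedModel, allow_lasso: bool = False) -> list:
    """Ranked (feature, score) list; scores >= 0 and summing to 1.

    Tree learners report impurity/gain importances. LASSO importance is not
    evaluated by default (its linear ranking is unreliable here); pass
    ``allow_lasso=True`` to rank by absolute standardized coefficients anyway.
    """
    if model.algorithm == "LASSO":
        if not allow_lasso:
            raise ValueError("feature importance is not evaluated for LASSO "
                             "by default (pass allow_lasso=True to override)")
        scores = np.abs(model.estimator.named_steps["lasso"].coef_)
    else:
        scores = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = scores.sum()
    if total > 0:
        scores = scores / total
    ranked = sorted(zip(model.feature_names, scores),
                    key=lambda fs: (-fs[1], fs[0]))
    return [(name, float(score)) for name, score in ranked]


@dataclass
class CellResult:
    scenario: int
    algorithm: str
    fold: int
    hyperparams: dict
    predictions: pd.DataFrame
    importance: list | None


def run_benchmark(tables: dict[int, pd.DataFrame], plan: SplitPlan,
                  algorithms=ALGORITHMS, spaces: dict | None = None,
                  seed: int = 0, inner_k: int = 5,
                  clip_negative: bool = False) -> list[CellResult]:
    """Run every scenario x algorithm x outer-fold cell.

    All scenario tables must share the ID universe of the split plan. ID
    leakage is asserted at run time for every cell. Fully reproducible given
    the seed (which fans out per cell into tuning and learner substreams).
    """
    spaces = default_spaces() if spaces is None else spaces
    plan.validate()
    plan_ids = set(np.concatenate(plan.folds))
    results = []
    for scenario in sorted(tables):
        table = tables[scenario]
        if set(table["ID"]) != plan_ids:
            raise ValueError(f"scenario {scenario} IDs differ from the split plan")
        for algorithm in algorithms:
            for fold_idx, test_ids in enumerate(plan.folds):
                cell_seed = int(np.random.SeedSequence(
                    [seed, scenario, ALGORITHMS.index(algorithm), fold_idx]
                ).generate_state(1)[0] % (2**31))
                mask = table["ID"].isin(test_ids)
                outer_train, outer_test = table[~mask], table[mask]
                if set(outer_train["ID"]) & set(outer_test["ID"]):
                    raise LeakageError(
                        f"ID leakage in scenario {scenario}/{algorithm}/fold {fold_idx}")
                inner_plan = make_grouped_folds(outer_train["ID"], k=inner_k,
                                                seed=cell_seed)
                try:
                    hp = tune(algorithm, spaces[algorithm], outer_train,
                              inner_plan, seed=cell_seed)
                    model = fit(algorithm, hp, outer_train, seed=cell_seed)
                    preds = predict(model, outer_test, clip_negative=clip_negative)
                except Exception as err:
                    raise RuntimeError(
                        f"benchmark cell failed: scenario={scenario}, "
                        f"algorithm={algorithm}, fold={fold_idx}") from err
                imp = (feature_importance(model)
                       if algorithm != "LASSO" else None)
                results.append(CellResult(scenario=scenario, algorithm=algorithm,
                                          fold=fold_idx, hyperparams=hp,
                                          predictions=preds, importance=imp))
    return results
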