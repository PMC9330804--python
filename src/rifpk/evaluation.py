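"""Performance metrics, cross-fold aggregation and the prediction-interval VPC.

Metrics: coefficient of determination R^2 = 1 - SS_res/SS_tot, Pearson
correlation, RMSE (precision) and MAE (bias), all in target units. Fold-level
metrics are aggregated as fold-mean with (min-max) range for RMSE/MAE; R^2
and Pearson are stored both fold-averaged and pooled over all test
predictions (every subject is predicted exactly once under grouped CV), since
the two conventions differ and reports must not conflate them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetricSet", "r_squared", "pearson", "rmse", "mae", "metric_set",
    "aggregate_folds", "pi_vpc", "render_reports", "UndefinedMetricError",
    "summarize_benchmark", "mean_importance_ranking",
]


class UndefinedMetricError(ValueError):
    """Metric undefined for the given inputs (e.g. zero total variance)."""


def _check_pair(observed, predicted, min_n=1):
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError(f"length mismatch: observed {o.shape} vs predicted {p.shape}")
    if o.size < min_n:
        raise ValueError(f"need at least {min_n} pairs")
    return o, p


def r_squared(observed, predicted) -> float:
    """1 - SS_res/SS_tot; may be negative for fits worse than the mean."""
    o, p = _check_pair(observed, predicted, min_n=2)
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("R^2 undefined: observations have zero variance")
    return 1.0 - float(np.sum((o - p) ** 2)) / ss_tot


def pearson(observed, predicted) -> float:
    o, p = _check_pair(observed, predicted, min_n=2)
    if o.std() == 0 or p.std() == 0:
        raise UndefinedMetricError("Pearson undefined: zero variance")
    return float(np.corrcoef(o, p)[0, 1])


def rmse(observed, predicted) -> float:
    o, p = _check_pair(observed, predicted)
    return float(np.sqrt(np.mean((o - p) ** 2)))


def mae(observed, predicted) -> float:
    o, p = _check_pair(observed, predicted)
    return float(np.mean(np.abs(o - p)))


@dataclass(frozen=True)
class MetricSet:
    r2: float
    pearson_r: float
    rmse: float
    mae: float
    n: int


def metric_set(observed, predicted) -> MetricSet:
    return MetricSet(r2=r_squared(observed, predicted),
                     pearson_r=pearson(observed, predicted),
                     rmse=rmse(observed, predicted),
                     mae=mae(observed, predicted),
                     n=len(np.asarray(observed)))


def aggregate_folds(fold_metrics: list[MetricSet],
                    pooled_observed, pooled_predicted) -> dict:
    """Fold-mean (range) for RMSE/MAE; fold-mean and pooled R^2/Pearson."""
    if not fold_metrics:
        raise ValueError("need at least one fold")
    rmses = [m.rmse for m in fold_metrics]
    maes = [m.mae for m in fold_metrics]
    return {
        "rmse_mean": float(np.mean(rmses)),
        "rmse_min": float(np.min(rmses)),
        "rmse_max": float(np.max(rmses)),
        "mae_mean": float(np.mean(maes)),
        "mae_min": float(np.min(maes)),
        "mae_max": float(np.max(maes)),
        "r2_fold_mean": float(np.mean([m.r2 for m in fold_metrics])),
        "r2_pooled": r_squared(pooled_observed, pooled_predicted),
        "pearson_fold_mean": float(np.mean([m.pearson_r for m in fold_metrics])),
        "pearson_pooled": pearson(pooled_observed, pooled_predicted),
        "n_total": int(sum(m.n for m in fold_metrics)),
    }


def _percentiles(x) -> tuple[float, float, float]:
    lo, med, hi = np.percentile(np.asarray(x, dtype=float), [2.5, 50.0, 97.5])
    return float(lo), float(med), float(hi)


def pi_vpc(predictions: pd.DataFrame, observations: pd.DataFrame) -> dict:
    """Prediction-interval VPC bands.

    Both inputs need columns TAD and a value column (``y_pred`` for
    predictions, ``y_obs`` for observations). Returns per-nominal-TAD 2.5th /
    median / 97.5th percentile bands for predictions and observations plus
    TAD-pooled overall intervals.
    """
    if predictions.empty or observations.empty:
        raise ValueError("predictions and observations must be non-empty")
    pred_tads = set(predictions["TAD"].unique())
    obs_tads = set(observations["TAD"].unique())
    if pred_tads - obs_tads:
        raise ValueError(f"unknown TAD values in predictions: {sorted(pred_tads - obs_tads)}")
    rows = []
    for tad in sorted(pred_tads):
        plo, pmed, phi = _percentiles(predictions.loc[predictions["TAD"] == tad, "y_pred"])
        olo, omed, ohi = _percentiles(observations.loc[observations["TAD"] == tad, "y_obs"])
        rows.append({"TAD": tad, "pred_lo": plo, "pred_median": pmed, "pred_hi": phi,
                     "obs_lo": olo, "obs_median": omed, "obs_hi": ohi})
    plo, pmed, phi = _percentiles(predictions["y_pred"])
    olo, omed, ohi = _percentiles(observations["y_obs"])
    return {"bands": pd.DataFrame(rows),
            "overall": {"pred_lo": plo, "pred_median": pmed, "pred_hi": phi,
                        "obs_lo": olo, "obs_median": omed, "obs_hi": ohi}}


def summarize_benchmark(cells) -> dict:
    """Assemble fold-level and aggregated metric tables from benchmark cells.

    ``cells`` are per scenario x algorithm x fold results carrying a
    predictions frame (y_obs, y_pred) and an optional importance ranking.
    """
    fold_rows, agg_rows, imp_rows = [], [], []
    keys = sorted({(c.scenario, c.algorithm) for c in cells})
    for scenario, algorithm in keys:
        group = sorted((c for c in cells
                        if c.scenario == scenario and c.algorithm == algorithm),
                       key=lambda c: c.fold)
        fold_metrics = []
        pooled = pd.concat([c.predictions for c in group], ignore_index=True)
        for c in group:
            m = metric_set(c.predictions["y_obs"], c.predictions["y_pred"])
            fold_metrics.append(m)
            fold_rows.append({"scenario": scenario, "algorithm": algorithm,
                              "fold": c.fold, "r2": m.r2, "pearson": m.pearson_r,
                              "rmse": m.rmse, "mae": m.mae, "n": m.n})
        agg = aggregate_folds(fold_metrics, pooled["y_obs"], pooled["y_pred"])
        agg_rows.append({"scenario": scenario, "algorithm": algorithm, **agg})
        # fold-mean importance score per feature for the tree learners
        if group[0].importance is not None:
            per_feature: dict[str, list] = {}
            for c in group:
                for name, score in c.importance:
                    per_feature.setdefault(name, []).append(score)
            for name, scores in sorted(per_feature.items()):
                imp_rows.append({"scenario": scenario, "algorithm": algorithm,
                                 "feature": name,
                                 "importance_mean": float(np.mean(scores)),
                                 "importance_sd": float(np.std(scores))})
        else:
            imp_rows.append({"scenario": scenario, "algorithm": algorithm,
                             "feature": "not evaluated",
                             "importance_mean": np.nan, "importance_sd": np.nan})
    return {"fold_metrics": pd.DataFrame(fold_rows),
            "aggregated": pd.DataFrame(agg_rows),
            "importances": pd.DataFrame(imp_rows)}


def mean_importance_ranking(summary: dict, scenario: int, algorithm: str) -> list:
    imp = summary["importances"]
    sub = imp[(imp["scenario"] == scenario) & (imp["algorithm"] == algorithm)]
    sub = sub.sort_values(["importance_mean", "feature"],
                          ascending=[False, True])
    return list(sub["feature"])


def render_reports(aggregated: pd.DataFrame, fold_metrics: pd.DataFrame,
                   importances: pd.DataFrame, vpc_bands: pd.DataFrame | None,
                   out_dir) -> list[str]:
    """Write the benchmark report files (CSV plus a markdown summary)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        written.append(str(path))

    _write(fold_metrics, "metrics.csv")
    _write(aggregated, "aggregated.csv")
    _write(importances, "importances.csv")
    if vpc_bands is not None:
        _write(vpc_bands, "vpc_bands.csv")

    lines = ["# Benchmark summary", "",
             "Fold-mean metrics per scenario and algorithm "
             "(RMSE/MAE shown as mean (min-max) across outer folds).", ""]
    lines.append("| scenario | algorithm | R2 (fold-mean) | Pearson | RMSE | MAE |")
    lines.append("|---|---|---|---|---|---|")
    for _, r in aggregated.sort_values(["scenario", "algorithm"]).iterrows():
        lines.append(
            f"| {int(r['scenario'])} | {r['algorithm']} | {r['r2_fold_mean']:.2f} "
            f"| {r['pearson_fold_mean']:.2f} "
            f"| {r['rmse_mean']:.1f} ({r['rmse_min']:.1f}-{r['rmse_max']:.1f}) "
            f"| {r['mae_mean']:.1f} ({r['mae_min']:.1f}-{r['mae_max']:.1f}) |")
    lines += ["", "Feature importances: see importances.csv "
              "(LASSO rendered as 'not evaluated').", ""]
    path = out / "summary.md"
    path.write_text("\n".join(lines))
    written.append(str(path))
    return written
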