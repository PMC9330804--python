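#!/usr/bin/env python
"""Evaluate the benchmark: metric tables, feature importances, VPC bands.

Aggregates fold-level R^2 / Pearson / RMSE / MAE per scenario x algorithm
(fold-mean with min-max range; pooled variants stored alongside), summarizes
tree-learner importances, and builds the prediction-interval VPC of the best
series model (XGBoost, scenario 3) against the simulated observations.
"""

import argparse
import json
from pathlib import Path

from rifpk import evaluation, io


class _Cell:
    def __init__(self, scenario, algorithm, fold, predictions, importance=None):
        self.scenario, self.algorithm, self.fold = scenario, algorithm, fold
        self.predictions, self.importance = predictions, importance


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    preds = io.read_dataset(args.out / "predictions.csv")
    raw_imp = json.loads((args.out / "importances_raw.json").read_text())
    imp_map = {(r["scenario"], r["algorithm"], r["fold"]):
               [tuple(x) for x in r["importance"]] for r in raw_imp}
    cells = [
        _Cell(s, a, f, g.drop(columns=["scenario", "algorithm", "fold"]),
              imp_map.get((s, a, f)))
        for (s, a, f), g in preds.groupby(["scenario", "algorithm", "fold"])]
    summary = evaluation.summarize_benchmark(cells)

    obs = io.read_dataset(args.out / "observations.csv",
                          schema=io.OBSERVATION_SCHEMA)
    vpc_preds = preds.query("scenario == 3 and algorithm == 'XGB'")
    vpc = evaluation.pi_vpc(vpc_preds[["TAD", "y_pred"]],
                            obs[["TAD", "DV"]].rename(columns={"DV": "y_obs"}))
    evaluation.render_reports(summary["aggregated"], summary["fold_metrics"],
                              summary["importances"], vpc["bands"], args.out)

    agg = summary["aggregated"]
    print(agg[["scenario", "algorithm", "r2_fold_mean", "rmse_mean",
               "mae_mean"]].round(2).to_string(index=False))
    o = vpc["overall"]
    print(f"VPC (XGB, scenario 3): prediction 95% PI "
          f"{o['pred_lo']:.1f}-{o['pred_hi']:.1f} mg/L "
          f"(median {o['pred_median']:.1f}); observed "
          f"{o['obs_lo']:.1f}-{o['obs_hi']:.1f} mg/L "
          f"(median {o['obs_median']:.1f})")
    for algo in ("GBM", "RF", "XGB"):
        top = evaluation.mean_importance_ranking(summary, 1, algo)[:4]
        print(f"scenario-1 importance ranking ({algo}): {', '.join(top)}")


if __name__ == "__main__":
    main()
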