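"""End-to-end pipeline: simulate -> NCA -> scenarios -> benchmark -> evaluate.

Each stage draws from its own named substream of the master seed, so a run is
reproducible end-to-end and stage-by-stage. A run manifest (config hash,
seeds, row counts) is written alongside the outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import evaluation, io, ml, nca, scenarios, trial_design
from ._seeds import stage_int_seed
from .config import RunConfig
from .pk_model import SimulationResult, simulate_trial

__all__ = ["simulate_stage", "PipelineResult", "run_pipeline", "write_outputs"]

VPC_SCENARIO = 3  # richest series scenario, shown for the best tree learner
VPC_ALGORITHM = "XGB"


def simulate_stage(cfg: RunConfig) -> tuple[trial_design.TrialDesign, SimulationResult]:
    """Population sampling, dose allocation and trial simulation."""
    master = cfg.seeds.master
    d = cfg.design
    subjects = trial_design.sample_covariates(
        d.covariates.build(), d.n_subjects, seed=stage_int_seed(master, "design"))
    subjects = trial_design.assign_doses(
        subjects, dose_groups=d.dose_groups, mode=d.allocation_mode,
        seed=stage_int_seed(master, "design") + 1, rounding=d.dose_rounding)
    design = trial_design.build_design(
        subjects, occasion_days=d.occasion_days,
        nominal_times_h=d.nominal_times_h, n_days=d.n_days)
    sim = simulate_trial(
        design, cfg.model.build_structural(), cfg.model.build_variability(),
        seed=stage_int_seed(master, "trial"),
        rich_times_h=cfg.model.rich_times_h,
        solver_opts=cfg.model.solver or None)
    return design, sim


@dataclass
class PipelineResult:
    design: trial_design.TrialDesign
    sim: SimulationResult
    aucs: pd.DataFrame
    tables: dict
    plan: ml.SplitPlan
    cells: list
    summary: dict
    vpc: dict


def run_pipeline(cfg: RunConfig,
                 scenarios_subset: list[int] | None = None) -> PipelineResult:
    master = cfg.seeds.master
    design, sim = simulate_stage(cfg)
    aucs = nca.derive_aucs(sim, use_true=cfg.nca.use_true, method=cfg.nca.method)
    tables = scenarios.build_all_tables(sim, aucs)
    if scenarios_subset is not None:
        tables = {k: v for k, v in tables.items() if k in scenarios_subset}
    plan = ml.make_grouped_folds(design.subjects["ID"], k=cfg.ml.k_folds,
                                 seed=stage_int_seed(master, "folds"))
    cells = ml.run_benchmark(tables, plan,
                             algorithms=tuple(cfg.ml.algorithms),
                             spaces=cfg.ml.build_spaces(),
                             seed=stage_int_seed(master, "learners"),
                             inner_k=cfg.ml.inner_k_folds,
                             clip_negative=cfg.ml.clip_negative)
    summary = evaluation.summarize_benchmark(cells)
    vpc = _vpc_for(cells, sim)
    return PipelineResult(design=design, sim=sim, aucs=aucs, tables=tables,
                          plan=plan, cells=cells, summary=summary, vpc=vpc)


def _vpc_for(cells, sim: SimulationResult, scenario: int = VPC_SCENARIO,
             algorithm: str = VPC_ALGORITHM) -> dict | None:
    sel = [c for c in cells
           if c.scenario == scenario and c.algorithm == algorithm]
    if not sel:
        return None
    preds = pd.concat([c.predictions for c in sel], ignore_index=True)
    obs = sim.observations[["TAD", "DV"]].rename(columns={"DV": "y_obs"})
    return evaluation.pi_vpc(preds, obs)


def write_outputs(result: PipelineResult, cfg: RunConfig, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "master_seed": cfg.seeds.master,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "row_counts": {},
    }
    io.write_dataset(result.design.subjects, out / "subjects.csv")
    io.write_dataset(result.sim.observations, out / "observations.csv")
    io.write_dataset(result.sim.rich, out / "rich.csv")
    io.write_dataset(result.aucs, out / "aucs.csv")
    for k, table in result.tables.items():
        io.write_dataset(table, out / f"scenario_{k}.csv")
        (out / f"scenario_{k}.columns.json").write_text(
            json.dumps({"features": scenarios.feature_columns(k),
                        "target": "TARGET", "group": "ID"}, indent=2))
    preds = pd.concat(
        [c.predictions.assign(scenario=c.scenario, algorithm=c.algorithm,
                              fold=c.fold) for c in result.cells],
        ignore_index=True)
    io.write_dataset(preds, out / "predictions.csv")
    vpc_bands = result.vpc["bands"] if result.vpc else None
    evaluation.render_reports(result.summary["aggregated"],
                              result.summary["fold_metrics"],
                              result.summary["importances"], vpc_bands, out)
    hp = [{"scenario": c.scenario, "algorithm": c.algorithm, "fold": c.fold,
           "hyperparams": c.hyperparams} for c in result.cells]
    (out / "hyperparams.json").write_text(json.dumps(hp, indent=2))
    manifest["row_counts"] = {
        "subjects": len(result.design.subjects),
        "observations": len(result.sim.observations),
        "rich": len(result.sim.rich),
        "auc_records": len(result.aucs),
        "predictions": len(preds),
    }
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
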