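"""Scenario-specific feature/target tables for the ML benchmark.

Six input-richness scenarios: targets are either the full concentration-time
series (scenarios 1-3) or AUC_0-24h (scenarios 4-6), with 0, 2 (TAD 2 and
4 h) or 6 (TAD 0.5, 1, 2, 4, 8, 24 h) of the subject's own observed
concentrations per occasion added to the demographic/design features.
Concentration features always come from the same occasion as the target row;
the predicted series deliberately includes the input time-points (predicting
a full profile from a limited sample).
"""

from __future__ import annotations

import pandas as pd

from .nca import DataError
from .pk_model import SimulationResult

__all__ = [
    "SCENARIOS",
    "BASE_FEATURES",
    "conc_feature_name",
    "feature_columns",
    "build_series_table",
    "build_auc_table",
    "build_all_tables",
]

BASE_FEATURES = ["DOSE", "OCC", "BMI", "AGE", "SEX", "RACE", "WT", "HT",
                 "HIV", "FFM"]

SPARSE_TIMES = (2.0, 4.0)
RICH_INPUT_TIMES = (0.5, 1.0, 2.0, 4.0, 8.0, 24.0)

#: scenario id -> (target kind, input concentration TADs per occasion)
SCENARIOS = {
    1: ("series", ()),
    2: ("series", SPARSE_TIMES),
    3: ("series", RICH_INPUT_TIMES),
    4: ("auc", ()),
    5: ("auc", SPARSE_TIMES),
    6: ("auc", RICH_INPUT_TIMES),
}


def conc_feature_name(tad: float) -> str:
    return "C" + f"{tad:g}".replace(".", "_") + "H"


def feature_columns(scenario: int) -> list[str]:
    kind, times = SCENARIOS[scenario]
    cols = (["TAD"] if kind == "series" else []) + list(BASE_FEATURES)
    return cols + [conc_feature_name(t) for t in times]


def _observations(sim) -> pd.DataFrame:
    return sim.observations if isinstance(sim, SimulationResult) else sim


def _conc_features(obs: pd.DataFrame, times) -> pd.DataFrame | None:
    if not times:
        return None
    sub = obs[obs["TAD"].isin(times)][["ID", "OCC", "TAD", "DV"]]
    wide = sub.pivot_table(index=["ID", "OCC"], columns="TAD", values="DV")
    wide.columns = [conc_feature_name(t) for t in wide.columns]
    return wide.reset_index()


def _finalize(table: pd.DataFrame, scenario: int) -> pd.DataFrame:
    cols = ["ID", "OCC"] + [c for c in feature_columns(scenario)
                            if c != "OCC"] + ["TARGET"]
    table = table[cols]
    if table.isna().any().any():
        missing = table.columns[table.isna().any()].tolist()
        raise DataError(f"missing values in scenario {scenario} table: {missing}")
    return table.reset_index(drop=True)


def build_series_table(sim, scenario: int) -> pd.DataFrame:
    """Feature table targeting the observed concentration series (one row per
    (ID, OCC, nominal TAD); target = residual-error-perturbed DV).

    Accepts a simulation result or an observation table directly."""
    kind, times = SCENARIOS[scenario]
    if kind != "series":
        raise ValueError(f"scenario {scenario} does not target the series")
    obs = _observations(sim)
    table = obs.copy()
    table["TARGET"] = table["DV"]
    wide = _conc_features(obs, times)
    if wide is not None:
        table = table.merge(wide, on=["ID", "OCC"], how="left")
    return _finalize(table, scenario)


def build_auc_table(sim, aucs: pd.DataFrame,
                    scenario: int) -> pd.DataFrame:
    """Feature table targeting AUC_0-24h (one row per (ID, OCC); no TAD)."""
    kind, times = SCENARIOS[scenario]
    if kind != "auc":
        raise ValueError(f"scenario {scenario} does not target AUC")
    obs = _observations(sim)
    base = (obs[["ID", "OCC", "DOSE"] +
                             [c for c in BASE_FEATURES if c not in ("DOSE", "OCC")]]
            .drop_duplicates(subset=["ID", "OCC"]))
    table = base.merge(aucs.rename(columns={"AUC0_24": "TARGET"}),
                       on=["ID", "OCC"], how="left")
    if table["TARGET"].isna().any():
        bad = table.loc[table["TARGET"].isna(), ["ID", "OCC"]].to_records(index=False)
        raise DataError(f"missing AUC record for subject-occasions: {list(bad)}")
    wide = _conc_features(obs, times)
    if wide is not None:
        table = table.merge(wide, on=["ID", "OCC"], how="left")
    return _finalize(table, scenario)


def build_all_tables(sim: SimulationResult, aucs: pd.DataFrame) -> dict[int, pd.DataFrame]:
    return {k: (build_series_table(sim, k) if kind == "series"
                else build_auc_table(sim, aucs, k))
            for k, (kind, _) in SCENARIOS.items()}
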