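"""Run configuration: YAML-backed, schema-validated, master-seed mandatory.

The configuration owns every tunable of the pipeline — population
distributions, structural and variability parameters, NCA options, ML grids
and fold counts — so that no scientific constant is hard-coded in the
pipeline stages. Unknown keys are rejected; validation errors name the
offending fields.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from . import pk_model, trial_design
from .ml import ALGORITHMS, HyperparamSpace, default_spaces

__all__ = ["RunConfig", "load_config", "default_config", "ConfigError"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TruncNormBlock(_Strict):
    mean: float
    sd: float
    lower: float
    upper: float

    def build(self) -> trial_design.TruncatedNormal:
        return trial_design.TruncatedNormal(self.mean, self.sd, self.lower, self.upper)


class BodyBlock(_Strict):
    wt: TruncNormBlock
    ffm: TruncNormBlock
    corr: float

    def build(self) -> trial_design.SexConditionalBody:
        return trial_design.SexConditionalBody(self.wt.build(), self.ffm.build(),
                                               self.corr)


class CovariateBlock(_Strict):
    ht: TruncNormBlock | None = None
    age: TruncNormBlock | None = None
    p_male: float | None = None
    p_hiv: float | None = None
    p_race_other: float | None = None
    body_male: BodyBlock | None = None
    body_female: BodyBlock | None = None

    def build(self) -> trial_design.CovariateDistribution:
        defaults = trial_design.CovariateDistribution()
        kwargs = {}
        for name in ("ht", "age", "body_male", "body_female"):
            block = getattr(self, name)
            if block is not None:
                kwargs[name] = block.build()
        for name in ("p_male", "p_hiv", "p_race_other"):
            val = getattr(self, name)
            if val is not None:
                kwargs[name] = val
        dist = replace(defaults, **kwargs)
        dist.validate()
        return dist


class DesignBlock(_Strict):
    n_subjects: int = 83
    dose_groups: list[float] = list(trial_design.DOSE_GROUPS_MG_KG)
    allocation_mode: str = "random"  # random | fixed_printed
    dose_rounding: str = "nearest"   # nearest | up
    nominal_times_h: list[float] = list(trial_design.NOMINAL_TIMES_H)
    occasion_days: dict[int, int] = dict(trial_design.OCCASION_DAYS)
    n_days: int = 14
    covariates: CovariateBlock = CovariateBlock()

    @field_validator("allocation_mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("random", "fixed_printed"):
            raise ValueError("allocation_mode must be 'random' or 'fixed_printed'")
        return v


class ModelBlock(_Strict):
    structural: dict = {}
    iiv: dict | None = None
    iov: dict | None = None
    ruv_prop_sd: float = 0.10
    ruv_add_sd: float = 0.05
    solver: dict = {}
    rich_times_h: list[float] = list(pk_model.RICH_TIMES_H)

    def build_structural(self) -> pk_model.StructuralParams:
        try:
            pop = pk_model.StructuralParams(**self.structural)
        except TypeError as err:
            raise ConfigError(f"unknown structural parameter: {err}") from err
        pop.validate()
        return pop

    def build_variability(self) -> pk_model.VariabilityParams:
        kwargs = {"ruv_prop_sd": self.ruv_prop_sd, "ruv_add_sd": self.ruv_add_sd}
        if self.iiv is not None:
            kwargs["iiv"] = dict(self.iiv)
        if self.iov is not None:
            kwargs["iov"] = dict(self.iov)
        var = pk_model.VariabilityParams(**kwargs)
        var.validate()
        return var


class NcaBlock(_Strict):
    method: str = "linear"  # linear | linlog
    use_true: bool = True


class MlBlock(_Strict):
    algorithms: list[str] = list(ALGORITHMS)
    k_folds: int = 5
    inner_k_folds: int = 5
    clip_negative: bool = False
    grids: dict = {}  # per-algorithm overrides of the default spaces

    @field_validator("algorithms")
    @classmethod
    def _algos(cls, v):
        bad = [a for a in v if a not in ALGORITHMS]
        if bad:
            raise ValueError(f"unknown algorithms: {bad}")
        return v

    def build_spaces(self) -> dict[str, HyperparamSpace]:
        spaces = default_spaces()
        for name, override in self.grids.items():
            if name not in ALGORITHMS:
                raise ConfigError(f"grid override for unknown algorithm {name!r}")
            spaces[name] = HyperparamSpace(**override)
            spaces[name].validate()
        return spaces


class SeedsBlock(_Strict):
    master: int


class RunConfig(_Strict):
    design: DesignBlock = DesignBlock()
    model: ModelBlock = ModelBlock()
    nca: NcaBlock = NcaBlock()
    ml: MlBlock = MlBlock()
    seeds: SeedsBlock
    output_dir: str = "results"


def default_config(master_seed: int = 1) -> RunConfig:
    return RunConfig(seeds=SeedsBlock(master=master_seed))


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        cfg = RunConfig(**raw)
    except ValidationError as err:
        offenders = "; ".join(
            ".".join(str(loc) for loc in e["loc"]) + f": {e['msg']}"
            for e in err.errors())
        raise ConfigError(f"invalid configuration: {offenders}") from err
    # materialize the scientific blocks so domain-level violations (negative
    # variances, bad bounds) surface at load time with the field named
    cfg.design.covariates.build()
    cfg.model.build_structural()
    cfg.model.build_variability()
    cfg.ml.build_spaces()
    return cfg
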