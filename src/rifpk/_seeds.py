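"""Master-seed fan-out into named per-stage substreams.

Each pipeline stage (population sampling, trial simulation, residual error,
fold assignment, learner seeding) draws from its own substream so a stage can
be re-run in isolation and still reproduce the full-pipeline realization.
"""

from __future__ import annotations

import numpy as np

_STAGES = ("design", "trial", "ruv", "folds", "learners", "tuning")


def stage_seed_sequence(master_seed: int, stage: str) -> np.random.SeedSequence:
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return children[_STAGES.index(stage)]


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed_sequence(master_seed, stage))


def stage_int_seed(master_seed: int, stage: str) -> int:
    """31-bit integer seed for libraries that take plain ints."""
    return int(stage_seed_sequence(master_seed, stage).generate_state(1)[0] % (2**31))
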