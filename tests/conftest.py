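import pytest

from rifpk.config import default_config
from rifpk.pipeline import run_pipeline, simulate_stage


@pytest.fixture(scope="session")
def small_cfg():
    cfg = default_config(7).model_copy(deep=True)
    cfg.design.n_subjects = 12
    return cfg


@pytest.fixture(scope="session")
def small_run(small_cfg):
    """12-subject design + simulation used by fast structural tests."""
    return simulate_stage(small_cfg)


@pytest.fixture(scope="session")
def benchmark_run():
    """Full default-conditions pipeline (83 subjects, 6 scenarios, 4 learners).

    Computed once per session; the grouped-CV benchmark dominates the suite's
    runtime.
    """
    return run_pipeline(default_config(7))
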