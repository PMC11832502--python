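import numpy as np
import pytest

from qeeg.pipeline import PipelineConfig, run_pipeline
from qeeg.simulate import CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full default pipeline run (39 + 49 participants, 19 channels, 43 s,
    seed 0) shared by every test that inspects cohort-level results."""
    out = tmp_path_factory.mktemp("default_run")
    return run_pipeline(PipelineConfig(cohort=CohortConfig(seed=0)), out)


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """A cohort small enough for fast structural tests."""
    return CohortConfig(n_td=3, n_asd=3, n_channels=4, duration_s=5.0, seed=11)
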