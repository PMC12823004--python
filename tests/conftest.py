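import numpy as np
import pytest

from aquadiag import ParameterBox
from aquadiag.isma import ScheduleConfig
from aquadiag.pipeline import PipelineConfig
from aquadiag.simulate import SyntheticConfig, generate


def sphere(x):
    return float(np.sum(np.asarray(x, dtype=float) ** 2))


@pytest.fixture
def box2d():
    return ParameterBox(["x", "y"], [-5.0, -5.0], [5.0, 5.0])


@pytest.fixture(scope="session")
def small_dataset():
    """A short synthetic run shared by pipeline-level tests."""
    return generate(SyntheticConfig(n_samples=220, seed=7))


@pytest.fixture
def fast_pipeline_config():
    """Reduced optimizer budgets so end-to-end tests stay quick."""
    return PipelineConfig(isma_pop_size=8,
                          isma_schedule=ScheduleConfig(T=6))
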