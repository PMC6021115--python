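import numpy as np
import pytest

from rbcshape import PipelineConfig, RenderParams, run_pipeline


@pytest.fixture(scope="session")
def noiseless_params() -> RenderParams:
    """Rendering with all stochastic photometric effects off."""
    return RenderParams().noiseless()


@pytest.fixture(scope="session")
def pipeline_result():
    """One scaled-down end-to-end run (2,000 cells, default training),
    shared by every test that needs a trained model or its artifacts."""
    return run_pipeline(PipelineConfig().with_seed(1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
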