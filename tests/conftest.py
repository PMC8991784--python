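import numpy as np
import pytest

from physnet import PipelineConfig, SimConfig, generate_bundle, run_pipeline


@pytest.fixture(scope="session")
def default_bundle():
    """Default-scale synthetic bundle (120 physicians, 4 planted
    communities, 4000 patients) with its ground truth."""
    return generate_bundle(SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def pipeline_result(default_bundle, default_config):
    bundle, _ = default_bundle
    return run_pipeline(bundle, default_config, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160401)
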