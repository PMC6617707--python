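import numpy as np
import pytest

from alpinecast import RunConfig
from alpinecast.pipeline import Pipeline


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full end-to-end run of the default synthetic study, shared by all
    tests that need fitted models and ensemble projections."""
    out = tmp_path_factory.mktemp("default_run")
    pipeline = Pipeline(RunConfig(seed=1), output_dir=out)
    pipeline.run()
    return pipeline


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
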