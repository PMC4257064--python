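import numpy as np
import pytest
from hypothesis import settings

from forestrisk.pipeline import run_pipeline

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pipeline_result():
    """One full synthetic run (default 200x200 study conditions), shared
    across tests that only inspect it."""
    return run_pipeline(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
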