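import pytest

from longvdj import PipelineParams, make_synthetic_germline


@pytest.fixture(scope="session")
def reference():
    """Default synthetic germline reference shared across the suite."""
    return make_synthetic_germline(seed=1)


@pytest.fixture(scope="session")
def params():
    return PipelineParams()
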