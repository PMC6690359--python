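import pytest
from hypothesis import settings

from gvtsig.synthetic_data import SimConfig, generate_experiments

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundle42():
    """The default synthetic paired-experiment bundle at seed 42."""
    return generate_experiments(SimConfig(seed=42))


@pytest.fixture(scope="session")
def bundle42_nodropout():
    return generate_experiments(SimConfig(seed=42, dropout_prob=0.0))
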