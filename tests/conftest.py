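import io

import pytest
from hypothesis import settings

from affectmc import GeneratorConfig, simulate_scale_responses, simulate_sequences

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def tiny_log():
    """Single participant, states neutral->negative->positive."""
    return io.StringIO(
        "participant_id,turn_index,state,quality\n"
        "p1,0,U,low\n"
        "p1,1,N,high\n"
        "p1,2,P,\n"
    )


@pytest.fixture(scope="session")
def study_corpus():
    """Study-scale synthetic corpus: 23 participants per stability group."""
    cfg = GeneratorConfig(seed=11)
    return cfg, simulate_sequences(cfg)


@pytest.fixture(scope="session")
def study_scales():
    cfg = GeneratorConfig(seed=11)
    return cfg, simulate_scale_responses(cfg)
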