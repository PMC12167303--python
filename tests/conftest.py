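import numpy as np
import pytest

from sprbench import (
    CHOLEC80_DURATIONS,
    CHOLEC80_SCHEMA,
    CohortConfig,
    PhaseSchema,
    RAPN_DURATIONS,
    RAPN_SCHEMA,
    SamplerConfig,
    simulate_timeline,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def rapn_schema():
    return RAPN_SCHEMA


@pytest.fixture(scope="session")
def cholec_schema():
    return CHOLEC80_SCHEMA


@pytest.fixture(scope="session")
def toy_schema():
    return PhaseSchema(name="toy", labels=("A", "B", "C"))


@pytest.fixture(scope="session")
def rapn_mean_timeline():
    """RAPN timeline with every phase at exactly its published mean duration."""
    cfg = CohortConfig(
        schema=RAPN_SCHEMA, durations=RAPN_DURATIONS, family="degenerate"
    )
    return simulate_timeline(cfg, np.random.default_rng(0), procedure_id="mean-rapn")


@pytest.fixture
def default_sampler_config():
    return SamplerConfig()
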