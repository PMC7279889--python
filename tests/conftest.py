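import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_simulation():
    """A small transcriptome + counts with planted truth, shared by tests."""
    from quadloc import synthio

    cfg = synthio.SimulationConfig(n_genes=300, seed=42)
    utr3, truth = synthio.make_transcriptome(cfg)
    counts, meta = synthio.simulate_counts(truth, cfg)
    return cfg, utr3, truth, counts, meta
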