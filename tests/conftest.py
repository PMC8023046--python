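import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 8000


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_corpus():
    """15 in-memory recordings (5 per class) at the default operating point."""
    from lungsound.pipeline import PipelineConfig, simulate_in_memory

    cfg = PipelineConfig(n_per_class=5, snr_db=20.0, seed=11)
    recs, labels, truth = simulate_in_memory(cfg)
    return cfg, recs, labels, truth
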