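import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from myoknn import SyntheticConfig, generate_envelope_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_world():
    """A small, well-separated synthetic world: rest + 3 gestures,
    2 repetitions of 30 samples -- fast enough for per-test refits."""
    cfg = SyntheticConfig(classes=("rs", "pw", "fl", "ex"), noise_sd=0.05,
                          repetitions=2, samples_per_rep=30, seed=42)
    return cfg, generate_envelope_dataset(cfg)


@pytest.fixture(scope="session")
def world6000():
    """The stated capture world: 5 classes x 3 repetitions x 400 samples
    (2 s at 200 Hz) at full intensity = 6000 training vectors."""
    cfg = SyntheticConfig(seed=2024)
    return cfg, generate_envelope_dataset(cfg)
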