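import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """Three-view planted dataset small enough for per-test fits."""
    from spidnmf import generate_multiview

    dataset, truth = generate_multiview(
        n=24, p=(12, 16, 20), k=3, n_stages=3, noise_sigma=0.02, seed=7
    )
    return dataset, truth
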