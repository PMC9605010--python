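import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trichoscan.simulate import SimConfig, generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_sim():
    """Six small synthetic images with exact ground truth (shared, read-only)."""
    cfg = SimConfig(seed=11, follicles_per_image=(8, 16))
    images, ann_set, manifest = generate_dataset(6, cfg)
    return images, ann_set, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
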