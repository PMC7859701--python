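import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tzpheno import SceneGroundTruth, simulate_phasmid_scene

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_widefield_scene():
    """One noiseless, background-free wide-field scene (shared; read-only)."""
    truth = SceneGroundTruth.widefield(
        seed=0, shot_noise=False, read_noise_sd=0.0, background_level=0.0
    )
    return simulate_phasmid_scene(truth)


@pytest.fixture(scope="session")
def noiseless_superres_scene():
    """One noiseless, background-free super-res shell stack (shared)."""
    truth = SceneGroundTruth.superres(
        seed=0, shot_noise=False, read_noise_sd=0.0, background_level=0.0
    )
    return simulate_phasmid_scene(truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
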