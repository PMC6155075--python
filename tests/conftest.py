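import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fociquant import SceneParams, VoxelSize, make_spot_scene

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_voxel():
    return VoxelSize()


@pytest.fixture(scope="session")
def noise_free_pair_scene():
    """One noise-free 500 nm pair with unjittered seeds (a clean oracle)."""
    params = SceneParams(
        n_loci=1,
        separation_nm=500.0,
        seed=3,
        background_mean=0.0,
        background_sd=0.0,
        shot_noise=False,
        seed_jitter_vox=0,
    )
    return make_spot_scene(params)


@pytest.fixture(scope="session")
def noisy_scene_factory():
    """Factory for default-noise single-pair scenes keyed by seed."""

    def make(seed, **overrides):
        kwargs = dict(n_loci=1, separation_nm=(300.0, 1000.0), seed=seed)
        kwargs.update(overrides)
        return make_spot_scene(SceneParams(**kwargs))

    return make
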