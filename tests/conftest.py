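import numpy as np
import pytest

from nanofoci import SceneParams, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_scene():
    """The default two-focus scene used across modules (seed fixed)."""
    return generate_scene(SceneParams(seed=42))


@pytest.fixture
def small_scene_params():
    """A light-weight scene for fast tests."""
    return SceneParams(
        nucleus_radius_nm=1500.0,
        n_foci=1,
        events_per_focus_ch1=80,
        events_per_focus_ch2=80,
        background_density_ch1=10.0,
        background_density_ch2=10.0,
        seed=7,
    )
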