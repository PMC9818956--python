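import numpy as np
import pytest

from penreg.simulate import SceneConfig, generate_view_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_pair():
    """One 64x64 ground-truth pair with defaults (residual 6 px)."""
    return generate_view_pair(SceneConfig(seed=42))


@pytest.fixture(scope="session")
def small_scene():
    from penreg.simulate import generate_scene

    return generate_scene(SceneConfig(seed=7))
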