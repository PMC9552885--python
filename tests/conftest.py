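import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small simulated scene bundle shared across pipeline tests."""
    from cabinlight import simulate_bundle

    out = tmp_path_factory.mktemp("bundle")
    index = simulate_bundle(
        out,
        seed=7,
        scenes=("sun_city", "countryside", "forest", "night"),
        settings=("L1", "L7"),
        levels=(1, 5),
        height=128,
        block=16,
        view_size=(256, 128),
    )
    return out, index
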