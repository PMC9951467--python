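import numpy as np
import pytest

from pamvasc.phantom import PhantomSpec, generate_surface, place_vessels, render_volume


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec.small(seed=7)


@pytest.fixture(scope="session")
def small_scene(small_spec):
    """One rendered small phantom volume with its generating scene."""
    surface = generate_surface(small_spec)
    vessels = place_vessels(small_spec)
    volume = render_volume(vessels, surface, small_spec, 0.0)
    return {"spec": small_spec, "surface": surface, "vessels": vessels, "volume": volume}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
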