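import numpy as np
import pytest

from melanoscene import apply_illuminant, equal_energy_spd, generate_scene
from melanoscene.synthetic import SceneGeneratorSpec


@pytest.fixture(scope="session")
def natural_reflectance():
    """Small natural-like reflectance scene (fixed seed)."""
    return generate_scene(
        SceneGeneratorSpec(environment="natural", height=96, width=96, seed=7)
    )


@pytest.fixture(scope="session")
def radiance_scene(natural_reflectance):
    """The same scene rendered under an equal-energy illuminant."""
    return apply_illuminant(natural_reflectance, equal_energy_spd())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
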