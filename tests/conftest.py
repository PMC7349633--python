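import numpy as np
import pytest

from spadmap import SceneSpec, SpectralCube, generate_scene, reference_profile


@pytest.fixture(scope="session")
def profile():
    return reference_profile()


@pytest.fixture(scope="session")
def noiseless_scene():
    """Small noise-free scene with full ground truth (96 x 160)."""
    return generate_scene(SceneSpec(seed=1, shape=(96, 160)))


@pytest.fixture()
def tiny_cube(profile):
    """4 x 5 cube whose band b is constant b + 1 (band-identification aid)."""
    data = np.zeros((4, 5, profile.n_bands))
    for b in range(profile.n_bands):
        data[:, :, b] = b + 1
    return SpectralCube(data=data, wavelengths=profile.wavelengths,
                        value_kind="reflectance")
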