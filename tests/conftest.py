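import numpy as np
import pytest

from holoquant import simulate as sim


MIX = np.array([[0.90, 0.07, 0.03], [0.05, 0.90, 0.05], [0.03, 0.08, 0.89]])


@pytest.fixture(scope="session")
def identity_camera() -> sim.CameraSimConfig:
    """Gamma 1, no vignetting, no mixing, no noise: image equals the scene."""
    return sim.CameraSimConfig(gamma_rgb=(1, 1, 1), vignette_strength=0.0, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def phone_camera() -> sim.CameraSimConfig:
    """A realistic phone-like camera: per-channel gamma, cross-talk, vignetting, noise."""
    return sim.CameraSimConfig(
        gamma_rgb=(2.1, 2.0, 1.9), vignette_strength=0.25, mix_matrix=MIX, noise_sd=0.003, seed=7
    )


@pytest.fixture(scope="session")
def phone_chart(phone_camera):
    return sim.render_chart(phone_camera)


@pytest.fixture(scope="session")
def phone_grey_card(phone_camera):
    return sim.render_grey_card(phone_camera)


@pytest.fixture(scope="session")
def template():
    return sim.render_template()


@pytest.fixture(scope="session")
def phone_scene(phone_camera):
    """One cluttered scene at mid-range pH through the phone-like camera."""
    return sim.render_scene(phone_camera, ph=5.0, clutter_level=0.3)
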