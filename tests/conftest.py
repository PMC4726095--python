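import numpy as np
import pytest

from xpiv import SceneConfig


def fourier_shift(img: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Sub-pixel periodic shift via the Fourier shift theorem (test oracle)."""
    ky = np.fft.fftfreq(img.shape[0])[:, None]
    kx = np.fft.fftfreq(img.shape[1])[None, :]
    return np.fft.ifft2(
        np.fft.fft2(img) * np.exp(-2j * np.pi * (ky * dy + kx * dx))
    ).real


@pytest.fixture(scope="session")
def test_scene_cfg():
    """Canonical small synthetic scene: 256 px frames, R = 200 um vessel."""
    return SceneConfig(
        frame_shape=(256, 256),
        vessel_radius=200.0,
        vessel_center_row=128,
        v_max=5.0,
        bluntness_k=3.31,
        bubble_count=2000,
        seed=7,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
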