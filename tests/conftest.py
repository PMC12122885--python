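import numpy as np
import pytest

from steerflow.ballistic import BallisticCorrection, CorrectionSet, Signal
from steerflow.synthetic import CameraModel, build_track


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def track():
    return build_track()


@pytest.fixture(scope="session")
def small_camera():
    # Quarter-ish scale raster keeps per-frame rendering cheap in tests.
    return CameraModel(image_width=120, image_height=108, focal_length=52.0)


@pytest.fixture()
def single_correction():
    return BallisticCorrection(a=1.0, mu=1.0, sigma=0.12)


def make_grid(t0: float, t1: float, dt: float = 1.0 / 90.0) -> Signal:
    n = int(round((t1 - t0) / dt)) + 1
    return Signal(t0, dt, np.zeros(n))


def gaussian_sum_signal(corrections, t0, t1, dt=1.0 / 90.0,
                        noise_sd=0.0, seed=0) -> Signal:
    """Independent construction of a sum-of-Gaussians trace (the oracle
    generator used across decomposition tests)."""
    t = t0 + dt * np.arange(int(round((t1 - t0) / dt)) + 1)
    z = np.zeros_like(t)
    for c in corrections:
        z += c.a * np.exp(-0.5 * ((t - c.mu) / c.sigma) ** 2)
    if noise_sd:
        z = z + noise_sd * np.random.default_rng(seed).standard_normal(t.size)
    return Signal(t0, dt, z)


@pytest.fixture()
def grid_factory():
    return make_grid


@pytest.fixture()
def gaussian_signal_factory():
    return gaussian_sum_signal
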