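import numpy as np
import pytest

from denoisem.io_formats import ImagePlane, MovieStack
from denoisem.pairgen import NoisePair, split_even_odd
from denoisem.synthetic_data import NoiseModel, make_scene_2d, noise_sigma_for_snr, render_movie


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_stack():
    """5-frame 32x32 stack with distinct frame values."""
    rng = np.random.default_rng(42)
    frames = rng.normal(size=(5, 32, 32)).astype(np.float32)
    return MovieStack(frames, pixel_size=1.2, dose_per_frame=1.5, origin_name="small")


@pytest.fixture
def synthetic_pair():
    """One low-SNR even/odd pair from a rendered 40-frame movie."""
    scene = make_scene_2d(64, 64, 4, 4.0, 1.0, seed=5)
    sigma = noise_sigma_for_snr(scene, 40, 0.2)
    stack = render_movie(scene, 40, NoiseModel(kind="gaussian", read_std=sigma, seed=6))
    return split_even_odd(stack)


def make_training_pairs(n, size=64, frames=20, snr_full=0.2, seed0=100):
    """Small rendered training set shared by training tests."""
    pairs = []
    for i in range(n):
        scene = make_scene_2d(size, size, 4, 3.0, 1.0, seed=seed0 + i)
        sigma = noise_sigma_for_snr(scene, frames, snr_full)
        stack = render_movie(scene, frames, NoiseModel(kind="gaussian", read_std=sigma, seed=seed0 + 1000 + i))
        pairs.append(split_even_odd(stack))
    return pairs


def gaussian_noise_pairs(n, size, signal_sigma=2.0, signal_amp=8.0, seed=7):
    """Stationary-Gaussian pairs: shared smooth signal + white noise halves."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        y = ndimage.gaussian_filter(rng.standard_normal((size, size)), signal_sigma) * signal_amp
        a = y + rng.standard_normal((size, size))
        b = y + rng.standard_normal((size, size))
        pairs.append(NoisePair(even=ImagePlane(a), odd=ImagePlane(b), source=f"g{i}"))
    return pairs
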