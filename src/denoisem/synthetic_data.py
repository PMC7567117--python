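"""Synthetic scenes, movies and volumes with known ground truth and SNR.

The generator mimics the statistics the training framework assumes: a
smooth particle-like signal, F detector frames that are independent noisy
observations of that same signal (per-frame shot noise plus additive
readout noise), and even/odd half sums as the paired observations. Because
signal and noise variances are known analytically, the split-frame SNR
estimator can be validated against a closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from denoisem.io_formats import ImagePlane, MovieStack, Volume

__all__ = [
    "Scene",
    "NoiseModel",
    "make_scene_2d",
    "make_scene_3d",
    "render_movie",
    "expected_pair_snr",
    "noise_sigma_for_snr",
]

NEG_INF = float("-inf")
POS_INF = float("inf")


@dataclass
class Scene:
    """Ground-truth signal with the particle layout that produced it."""

    signal: np.ndarray  # 2D (H, W) or 3D (D, H, W)
    centers: np.ndarray  # (n, ndim) float
    radius: float
    contrast: float
    background: float

    @property
    def ndim(self) -> int:
        return self.signal.ndim


@dataclass
class NoiseModel:
    """Per-frame noise process applied independently to every frame.

    ``gaussian``: frame = signal + N(0, read_std^2).
    ``poisson_gaussian``: frame = Poisson(counts_per_frame * signal) /
    counts_per_frame + N(0, read_std^2); the signal must be positive.
    """

    kind: str = "gaussian"
    read_std: float = 1.0
    counts_per_frame: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "poisson_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.read_std < 0:
            raise ValueError("read_std must be >= 0")
        if self.counts_per_frame <= 0:
            raise ValueError("counts_per_frame must be > 0")


def _gaussian_blob(grids, center, radius: float) -> np.ndarray:
    # radius is the Gaussian sigma of the blob profile
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.exp(-r2 / (2.0 * radius**2))


def _make_scene(shape, n_particles, radius_px, contrast, seed, sign) -> Scene:
    if n_particles < 0:
        raise ValueError("n_particles must be >= 0")
    # 4 sigma keeps blob tails inside the frame, so the discrete signal mass
    # matches the analytic box integral to ~1e-7 relative
    margin = 4.0 * radius_px
    if n_particles > 0 and any(s <= 2 * margin for s in shape):
        raise ValueError(f"particles of radius {radius_px} do not fit in shape {shape}")
    rng = np.random.default_rng(seed)
    background = 10.0
    signal = np.full(shape, background, dtype=np.float64)
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    centers = []
    min_sep = 2.5 * radius_px
    for _ in range(n_particles):
        placed = None
        for _attempt in range(50):
            c = np.array([rng.uniform(margin, s - margin) for s in shape])
            if all(np.linalg.norm(c - p) >= min_sep for p in centers):
                placed = c
                break
        if placed is None:
            import warnings

            warnings.warn("could not separate particles after 50 retries; placing anyway", stacklevel=2)
            placed = np.array([rng.uniform(margin, s - margin) for s in shape])
        centers.append(placed)
        signal += sign * contrast * _gaussian_blob(grids, placed, radius_px)
    centers = np.array(centers).reshape(n_particles, len(shape))
    return Scene(signal=signal, centers=centers, radius=radius_px, contrast=contrast, background=background)


def make_scene_2d(
    h: int,
    w: int,
    n_particles: int = 8,
    radius_px: float = 6.0,
    contrast: float = 1.0,
    seed: int = 0,
    darker: bool = True,
) -> Scene:
    """Gaussian blobs on a constant background (particles darker by default)."""
    return _make_scene((h, w), n_particles, radius_px, contrast, seed, -1.0 if darker else 1.0)


def make_scene_3d(
    d: int,
    h: int,
    w: int,
    n_particles: int = 8,
    radius_px: float = 4.0,
    contrast: float = 1.0,
    seed: int = 0,
    darker: bool = True,
) -> Scene:
    """3D analogue of :func:`make_scene_2d` with spherical blobs."""
    return _make_scene((d, h, w), n_particles, radius_px, contrast, seed, -1.0 if darker else 1.0)


def render_movie(scene: Scene, n_frames: int, noise: NoiseModel, seed: Optional[int] = None) -> MovieStack:
    """Draw ``n_frames`` independent noisy observations of the scene signal."""
    if scene.ndim != 2:
        raise ValueError("render_movie needs a 2D scene")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    sig = scene.signal
    frames = np.empty((n_frames,) + sig.shape, dtype=np.float64)
    for f in range(n_frames):
        if noise.kind == "gaussian":
            frame = sig + rng.normal(0.0, noise.read_std, size=sig.shape)
        else:
            scaled = noise.counts_per_frame * sig
            if np.any(scaled < 0):
                raise ValueError(
                    "negative scaled signal under the Poisson model; add a background offset"
                )
            frame = rng.poisson(scaled).astype(np.float64) / noise.counts_per_frame
            if noise.read_std > 0:
                frame += rng.normal(0.0, noise.read_std, size=sig.shape)
        frames[f] = frame
    return MovieStack(frames.astype(np.float32), origin_name="synthetic")


def _half_noise_var(noise: NoiseModel, scene: Scene, n_half: int) -> float:
    if noise.kind == "gaussian":
        return n_half * noise.read_std**2
    # Poisson variance approximated by its mean; averaged over the scene
    shot = float(np.mean(scene.signal)) / noise.counts_per_frame
    return n_half * (shot + noise.read_std**2)


def expected_pair_snr(scene: Scene, noise: NoiseModel, n_frames: int) -> float:
    """Analytic split-half SNR in dB for movies rendered from this scene.

    Each half sums ``n_frames // 2`` frames (the even half gets the extra
    frame of an odd-length movie; the odd half count is used, matching the
    denoised-odd vs raw-even convention). Signal variance scales with the
    square of the frame count, noise variance linearly, so
    ``SNR = (n/2)^2 Var(signal) / ((n/2) Var(noise_frame))``.
    """
    n_half = n_frames // 2
    if n_half < 1:
        raise ValueError("need at least 2 frames for a pair")
    var_signal = float(np.var(scene.signal))
    if var_signal == 0:
        return NEG_INF
    noise_var = _half_noise_var(noise, scene, n_half)
    if noise_var == 0:
        return POS_INF
    snr = (n_half**2 * var_signal) / noise_var
    return 10.0 * math.log10(snr)


def noise_sigma_for_snr(scene: Scene, n_frames: int, snr_full: float) -> float:
    """Per-frame gaussian sigma so the full-dose micrograph has the given SNR.

    The full sum of F frames has signal variance ``F^2 Var(s)`` and noise
    variance ``F sigma^2``; solving ``snr_full = F Var(s) / sigma^2``.
    """
    if snr_full <= 0:
        raise ValueError("snr_full must be > 0")
    var_signal = float(np.var(scene.signal))
    return math.sqrt(n_frames * var_signal / snr_full)
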