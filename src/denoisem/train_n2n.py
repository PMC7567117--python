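"""Noise2Noise training: normalization, patch sampling, augmentation, losses.

The training objective never sees clean images. Each movie yields two
independent same-signal observations (even/odd frame sums); the model is
fit to map each observation to the other, in both directions, so the loss
per minibatch is ``0.5 * [loss(f(a), b) + loss(f(b), a)]``. Under an L2
loss the optimum is the posterior mean of the signal; under L1, the
median; the smoothed-L0 variant is mode-seeking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from denoisem.io_formats import ImagePlane, Volume
from denoisem.models import Denoiser, ModelSpec, build_model
from denoisem.nn import Adagrad
from denoisem.pairgen import NoisePair

__all__ = [
    "NormStats",
    "TrainConfig",
    "TrainHistory",
    "normalize_image",
    "denormalize_image",
    "sample_patch_pairs",
    "augment_pair",
    "pair_loss",
    "pair_loss_grad",
    "train",
]

logger = logging.getLogger(__name__)

LOSS_MODES = ("l1", "l2", "l0")


@dataclass(frozen=True)
class NormStats:
    """Whole-image mean/std (population convention) enabling exact inversion."""

    mean: float
    std: float

    def __post_init__(self) -> None:
        if not self.std > 0:
            raise ValueError("std must be > 0")


@dataclass
class TrainConfig:
    """Hyper-parameters of the training loop (defaults follow the method)."""

    loss_mode: str = "l2"
    lr: float = 0.001
    epochs: int = 100
    batch: int = 4
    patch: int = 800
    augment: bool = True
    seed: int = 0
    l0_gamma_start: float = 2.0
    l0_gamma_end: float = 0.01
    l0_eps: float = 1e-8
    holdout: Optional[Sequence[NoisePair]] = None

    def __post_init__(self) -> None:
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"loss_mode must be one of {LOSS_MODES}, got {self.loss_mode!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch < 1 or self.patch < 1:
            raise ValueError("batch and patch must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch mean training loss (and optional held-out loss)."""

    train_loss: List[float] = field(default_factory=list)
    holdout_loss: List[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


def normalize_image(image: Union[ImagePlane, Volume, np.ndarray]) -> Tuple[np.ndarray, NormStats]:
    """Subtract the whole-image mean and divide by the (population) std.

    Returns the normalized array together with the stats needed to invert
    the transform exactly. Raises on a constant image.
    """
    data = image.data if isinstance(image, (ImagePlane, Volume)) else np.asarray(image)
    data = data.astype(np.float64, copy=False)
    mean = float(data.mean())
    std = float(data.std())
    if std == 0:
        raise ValueError("degenerate micrograph: constant intensity (std = 0)")
    return (data - mean) / std, NormStats(mean=mean, std=std)


def denormalize_image(data: np.ndarray, stats: NormStats) -> np.ndarray:
    """Restore original intensity scale: multiply by std, add back mean."""
    return data * stats.std + stats.mean


def sample_patch_pairs(
    pair: NoisePair,
    patch: int,
    n: int,
    rng: np.random.Generator,
    even_data: Optional[np.ndarray] = None,
    odd_data: Optional[np.ndarray] = None,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Cut ``n`` aligned square patches at uniform random positions.

    The same top-left coordinate is used in the even and odd planes so the
    two patches observe the identical signal. ``even_data``/``odd_data``
    may substitute pre-normalized planes for the pair's raw data.
    """
    a = pair.even.data if even_data is None else even_data
    b = pair.odd.data if odd_data is None else odd_data
    h, w = a.shape
    patch = _shrink_patch(patch, h, w)
    out = []
    for _ in range(n):
        i = int(rng.integers(0, h - patch + 1))
        j = int(rng.integers(0, w - patch + 1))
        out.append((a[i : i + patch, j : j + patch], b[i : i + patch, j : j + patch]))
    return out


def _shrink_patch(patch: int, *extents: int) -> int:
    smallest = min(extents)
    if patch > smallest:
        warnings.warn(
            f"patch {patch} exceeds image extent {smallest}; shrinking to {smallest}",
            stacklevel=3,
        )
        return smallest
    return patch


def augment_pair(
    pa: np.ndarray, pb: np.ndarray, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Apply one random element of the dihedral group (rot90 x mirror) to both.

    Only right-angle rotations are used, so pixels are permuted, never
    interpolated. Non-square patches cannot be rotated by 90/270.
    """
    k = int(rng.integers(0, 4))
    mirror = bool(rng.integers(0, 2))
    if k % 2 == 1 and pa.shape[0] != pa.shape[1]:
        raise ValueError("cannot rotate a non-square patch by 90/270 degrees")
    if k:
        pa, pb = np.rot90(pa, k), np.rot90(pb, k)
    if mirror:
        pa, pb = pa[:, ::-1], pb[:, ::-1]
    return np.ascontiguousarray(pa), np.ascontiguousarray(pb)


def _l0_weight(gamma: float, d: np.ndarray, eps: float) -> np.ndarray:
    return (np.abs(d) + eps) ** gamma


def pair_loss(pred: np.ndarray, target: np.ndarray, mode: str = "l2", gamma: float = 2.0, eps: float = 1e-8) -> float:
    """Mean per-pixel discrepancy between prediction and the paired observation.

    l2: mean squared difference; l1: mean absolute difference; l0: mean of
    ``(|d| + eps)**gamma`` with gamma from the annealing schedule.
    """
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    d = pred.astype(np.float64) - target.astype(np.float64)
    if mode == "l2":
        return float(np.mean(d * d))
    if mode == "l1":
        return float(np.mean(np.abs(d)))
    if mode == "l0":
        return float(np.mean(_l0_weight(gamma, d, eps)))
    raise ValueError(f"loss mode must be one of {LOSS_MODES}, got {mode!r}")


def pair_loss_grad(pred: np.ndarray, target: np.ndarray, mode: str, gamma: float = 2.0, eps: float = 1e-8) -> np.ndarray:
    """d(loss)/d(pred) for :func:`pair_loss` (mean convention)."""
    d = pred.astype(np.float64) - target.astype(np.float64)
    n = d.size
    if mode == "l2":
        return 2.0 * d / n
    if mode == "l1":
        return np.sign(d) / n
    if mode == "l0":
        return gamma * (np.abs(d) + eps) ** (gamma - 1.0) * np.sign(d) / n
    raise ValueError(mode)


def _normalized_pairs(pairs: Sequence[NoisePair]) -> List[Tuple[np.ndarray, np.ndarray]]:
    out = []
    for pair in pairs:
        a, _ = normalize_image(pair.even)
        b, _ = normalize_image(pair.odd)
        out.append((a, b))
    return out


def _round_patch(patch: int, granularity: int, extents: Tuple[int, int]) -> int:
    patch = _shrink_patch(patch, *extents)
    if granularity > 1:
        rounded = (patch // granularity) * granularity
        if rounded < granularity:
            raise ValueError(
                f"patch {patch} too small for model pooling granularity {granularity}"
            )
        if rounded != patch:
            warnings.warn(
                f"patch {patch} rounded down to {rounded} (multiple of {granularity})",
                stacklevel=3,
            )
        patch = rounded
    return patch


def _epoch_gamma(cfg: TrainConfig, epoch: int) -> float:
    if cfg.epochs == 1:
        return cfg.l0_gamma_end
    t = epoch / (cfg.epochs - 1)
    return cfg.l0_gamma_start + t * (cfg.l0_gamma_end - cfg.l0_gamma_start)


def _holdout_loss(model: Denoiser, norm_pairs, patch: int, mode: str, gamma: float, eps: float) -> float:
    losses = []
    for a, b in norm_pairs:
        pa = a[:patch, :patch][None, None]
        pb = b[:patch, :patch][None, None]
        fa = model.forward_batch(pa.astype(np.dtype(model.spec.dtype)))
        fb = model.forward_batch(pb.astype(np.dtype(model.spec.dtype)))
        losses.append(0.5 * (pair_loss(fa, pb, mode, gamma, eps) + pair_loss(fb, pa, mode, gamma, eps)))
    return float(np.mean(losses))


def train(
    pairs: Sequence[NoisePair],
    spec: ModelSpec,
    cfg: TrainConfig,
    model: Optional[Denoiser] = None,
) -> Tuple[Denoiser, TrainHistory]:
    """Fit a denoiser to paired observations with the symmetric objective.

    Each epoch samples one patch per training pair (resampled every epoch,
    shuffled, optionally augmented); minibatches run both loss directions
    through the model in a single batched pass. Optimization is Adagrad at
    ``cfg.lr``. Fully deterministic given ``cfg.seed``.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one training pair")
    if model is None:
        model = build_model(spec)
    if model.ndim != 2:
        raise ValueError("train() operates on 2D pairs; 3D training uses the same loop on volume slabs")
    dtype = np.dtype(model.spec.dtype)
    rng = np.random.default_rng(cfg.seed)
    norm = _normalized_pairs(pairs)
    extents = norm[0][0].shape
    patch = _round_patch(cfg.patch, model.granularity, extents)

    bias_only = spec.arch == "constant"
    params = model.params()
    if bias_only:
        params = [model.net.layers[0].bias]
    opt = Adagrad(params, lr=cfg.lr)
    norm_holdout = _normalized_pairs(cfg.holdout) if cfg.holdout else None

    history = TrainHistory()
    for epoch in range(cfg.epochs):
        gamma = _epoch_gamma(cfg, epoch)
        order = rng.permutation(len(norm))
        samples = []
        for idx in order:
            a, b = norm[idx]
            (pa, pb), = sample_patch_pairs(pairs[idx], patch, 1, rng, even_data=a, odd_data=b)
            if cfg.augment:
                pa, pb = augment_pair(pa, pb, rng)
            samples.append((pa, pb))
        epoch_losses = []
        for start in range(0, len(samples), cfg.batch):
            chunk = samples[start : start + cfg.batch]
            a_stack = np.stack([c[0] for c in chunk]).astype(dtype)[:, None]
            b_stack = np.stack([c[1] for c in chunk]).astype(dtype)[:, None]
            # both directions in one pass: f([a; b]) vs [b; a]
            x = np.concatenate([a_stack, b_stack], axis=0)
            t = np.concatenate([b_stack, a_stack], axis=0)
            pred = model.forward_batch(x)
            loss = 0.5 * (
                pair_loss(pred[: len(chunk)], t[: len(chunk)], cfg.loss_mode, gamma, cfg.l0_eps)
                + pair_loss(pred[len(chunk) :], t[len(chunk) :], cfg.loss_mode, gamma, cfg.l0_eps)
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, minibatch {start // cfg.batch}"
                )
            g = np.empty_like(pred)
            g[: len(chunk)] = 0.5 * pair_loss_grad(
                pred[: len(chunk)], t[: len(chunk)], cfg.loss_mode, gamma, cfg.l0_eps
            )
            g[len(chunk) :] = 0.5 * pair_loss_grad(
                pred[len(chunk) :], t[len(chunk) :], cfg.loss_mode, gamma, cfg.l0_eps
            )
            opt.zero_grad()
            model.backward_batch(g.astype(dtype))
            opt.step()
            epoch_losses.append(loss)
        history.train_loss.append(float(np.mean(epoch_losses)))
        if norm_holdout is not None:
            hpatch = _round_patch(patch, model.granularity, norm_holdout[0][0].shape)
            history.holdout_loss.append(
                _holdout_loss(model, norm_holdout, hpatch, cfg.loss_mode, gamma, cfg.l0_eps)
            )
        logger.info("epoch %d/%d loss %.6f", epoch + 1, cfg.epochs, history.train_loss[-1])
    return model, history
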