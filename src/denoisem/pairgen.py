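"""Build paired independent observations from movie stacks.

Splitting a movie into even-index and odd-index frame sums yields two
images of the identical specimen signal with independent noise — the
training pair for the self-supervised denoising objective. Frames are
assumed gain-corrected; frame alignment is out of scope (a hook accepts
externally pre-aligned per-half stacks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from denoisem.io_formats import ImagePlane, MovieStack

__all__ = [
    "NoisePair",
    "split_even_odd",
    "fractionate_frames",
    "sum_frames",
    "pair_from_half_stacks",
    "cap_per_dataset",
]


@dataclass
class NoisePair:
    """Two independent observations of the same signal (even/odd frame sums)."""

    even: ImagePlane
    odd: ImagePlane
    source: str = ""
    dose_even: Optional[float] = None
    dose_odd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.even.shape != self.odd.shape:
            raise ValueError(
                f"even/odd shapes differ: {self.even.shape} vs {self.odd.shape}"
            )


def _half_sum(frames: np.ndarray, start: int) -> np.ndarray:
    # accumulate in float64; numpy's pairwise reduction keeps this stable
    return np.add.reduce(frames[start::2].astype(np.float64, copy=False), axis=0)


def split_even_odd(stack: MovieStack) -> NoisePair:
    """Sum frames at even (0, 2, 4, ...) and odd (1, 3, 5, ...) indices.

    "Even" means 0-based indices, so an odd-length stack gives the extra
    frame to the even half. ``even + odd`` reproduces :func:`sum_frames`
    exactly.
    """
    if stack.n_frames < 2:
        raise ValueError("cannot form independent pair: stack has a single frame")
    even = _half_sum(stack.frames, 0)
    odd = _half_sum(stack.frames, 1)
    dose = stack.dose_per_frame
    n_even = (stack.n_frames + 1) // 2
    n_odd = stack.n_frames // 2
    return NoisePair(
        even=ImagePlane(even, pixel_size=stack.pixel_size, origin_name=f"{stack.origin_name}_even"),
        odd=ImagePlane(odd, pixel_size=stack.pixel_size, origin_name=f"{stack.origin_name}_odd"),
        source=stack.origin_name,
        dose_even=None if dose is None else dose * n_even,
        dose_odd=None if dose is None else dose * n_odd,
    )


def fractionate_frames(stack: MovieStack, fraction: float) -> MovieStack:
    """Keep the first ``floor(fraction * n_frames)`` frames (a prefix).

    Dose fractions are rounded down to the nearest whole frame;
    ``dose_per_frame`` is unchanged.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    # guard against float artifacts like 0.175 * 40 = 6.999999...
    k = math.floor(fraction * stack.n_frames + 1e-9)
    if k < 1:
        raise ValueError(
            f"fraction {fraction} of {stack.n_frames} frames rounds down to zero frames"
        )
    return MovieStack(
        stack.frames[:k],
        pixel_size=stack.pixel_size,
        dose_per_frame=stack.dose_per_frame,
        origin_name=f"{stack.origin_name}_f{fraction:g}",
    )


def sum_frames(stack: MovieStack) -> ImagePlane:
    """Elementwise sum over all frames.

    Computed as even-half + odd-half so that conservation against
    :func:`split_even_odd` is exact, not merely up to accumulation order.
    """
    if stack.n_frames == 1:
        return ImagePlane(
            stack.frames[0].astype(np.float64),
            pixel_size=stack.pixel_size,
            origin_name=f"{stack.origin_name}_sum",
        )
    total = _half_sum(stack.frames, 0) + _half_sum(stack.frames, 1)
    return ImagePlane(total, pixel_size=stack.pixel_size, origin_name=f"{stack.origin_name}_sum")


def pair_from_half_stacks(even_stack: MovieStack, odd_stack: MovieStack, source: str = "") -> NoisePair:
    """Build a NoisePair from externally pre-aligned even/odd half stacks."""
    even = sum_frames(even_stack)
    odd = sum_frames(odd_stack)
    if even.shape != odd.shape:
        raise ValueError("pre-aligned half stacks disagree in shape")
    return NoisePair(even=even, odd=odd, source=source or even_stack.origin_name)


def cap_per_dataset(paths: Sequence, max_per_dataset: Optional[int] = 200, seed: int = 0):
    """Randomly select up to ``max_per_dataset`` movie paths per source dataset.

    The dataset of a path is its parent directory. Selection is a seeded
    permutation so the balanced subset is reproducible. ``None`` disables
    the cap.
    """
    paths = [Path(p) for p in paths]
    if max_per_dataset is None:
        return list(paths)
    if max_per_dataset < 1:
        raise ValueError("max_per_dataset must be >= 1 or None")
    by_dataset: dict = {}
    for p in paths:
        by_dataset.setdefault(str(p.parent), []).append(p)
    rng = np.random.default_rng(seed)
    chosen = []
    for key in sorted(by_dataset):
        group = sorted(by_dataset[key])
        if len(group) > max_per_dataset:
            idx = rng.permutation(len(group))[:max_per_dataset]
            group = [group[i] for i in sorted(idx)]
        chosen.extend(group)
    return chosen
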