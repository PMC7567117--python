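"""SNR estimation, low-pass baselines, dose-titration curves, display scaling.

Two estimators are provided:

* region-based: from N paired signal/background rectangles, signal power is
  the squared difference of region means and noise power the background
  variance; the report is the mean over pairs of
  ``10 * (log10(s_i) - log10(v_i))`` in dB.
* split-frame: from two independent observations of the same signal, SNR
  follows from the Pearson correlation p via ``SNR = p / (1 - p)``,
  reported as ``10 * log10(p / (1 - p))`` dB.

Low-pass baselines are a Fourier crop-and-pad "binning" filter and a
Gaussian filter with half-amplitude attenuation at the cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from denoisem.io_formats import ImagePlane, MovieStack
from denoisem.pairgen import fractionate_frames, split_even_odd, sum_frames

__all__ = [
    "RegionPair",
    "RegionPairSet",
    "SNRReport",
    "ccc",
    "snr_split",
    "snr_regions",
    "lowpass_bin",
    "lowpass_gaussian",
    "dose_titration",
    "scale_display",
    "read_region_tsv",
]

NEG_INF = float("-inf")
POS_INF = float("inf")


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, 0-based, half-open: rows [y0, y1), cols [x0, x1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"empty rectangle {self}")
        if (self.x1 - self.x0) * (self.y1 - self.y0) < 4:
            raise ValueError(f"region {self} has fewer than 4 pixels")

    def extract(self, data: np.ndarray) -> np.ndarray:
        h, w = data.shape
        if self.y1 > h or self.x1 > w or self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"region {self} outside image bounds {(h, w)}")
        return data[self.y0 : self.y1, self.x0 : self.x1]


@dataclass(frozen=True)
class RegionPair:
    """A signal rectangle and its paired background rectangle on one image."""

    image_name: str
    pair_id: str
    signal: Rect
    background: Rect


@dataclass
class RegionPairSet:
    items: List[RegionPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class SNRReport:
    """Per-item dB values for one method, with their mean (and p when split-frame)."""

    method: str
    items_db: List[float]
    p: Optional[float] = None

    @property
    def mean_db(self) -> float:
        return float(np.mean(self.items_db))


def ccc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson cross-correlation coefficient over all pixels."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("cannot correlate a constant image")
    r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return min(1.0, max(-1.0, r))


def snr_split(x: np.ndarray, y: np.ndarray) -> float:
    """Split-frame SNR in dB: ``10 log10(p / (1 - p))`` with p = ccc(x, y)."""
    p = ccc(x, y)
    if p <= 0:
        warnings.warn(f"non-positive correlation p={p:.4g}; SNR is -inf", stacklevel=2)
        return NEG_INF
    if p >= 1.0 - 1e-12:  # numerically perfect correlation
        return POS_INF
    return 10.0 * np.log10(p / (1.0 - p))


def snr_regions(images: Mapping[str, ImagePlane], regions: RegionPairSet, method: str = "") -> SNRReport:
    """Region-pair SNR: mean over pairs of ``10(log10 s_i - log10 v_i)`` dB.

    ``s_i`` is the squared difference between signal and background region
    means, ``v_i`` the population variance of the background region.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    items = []
    for rp in regions.items:
        if rp.image_name not in images:
            raise KeyError(f"region pair {rp.pair_id}: image {rp.image_name!r} not provided")
        data = np.asarray(images[rp.image_name].data, dtype=np.float64)
        mu_s = float(rp.signal.extract(data).mean())
        bg = rp.background.extract(data)
        mu_b = float(bg.mean())
        v_b = float(bg.var())
        if v_b == 0:
            raise ValueError(f"zero background variance in region pair {rp.pair_id!r}")
        s = (mu_s - mu_b) ** 2
        if s == 0:
            warnings.warn(f"signal mean equals background mean in pair {rp.pair_id!r}", stacklevel=2)
            items.append(NEG_INF)
        else:
            items.append(10.0 * (np.log10(s) - np.log10(v_b)))
    return SNRReport(method=method, items_db=items)


def _bin_mask(n: int, factor: int) -> np.ndarray:
    """Fourier-crop band along one axis: frequencies surviving a crop to n//factor."""
    keep = n // factor
    freqs = np.fft.fftfreq(n) * n  # integer frequency indices
    lo, hi = -(keep // 2), (keep - 1) // 2
    return (freqs >= lo) & (freqs <= hi)


def lowpass_bin(image: np.ndarray, factor: int) -> np.ndarray:
    """Band-limit at 1/factor Nyquist via Fourier crop-and-pad; same shape.

    Equivalent to cropping the spectrum to ``shape // factor`` and zero
    padding back, so the output can be compared to the input pixelwise.
    """
    image = np.asarray(image, dtype=np.float64)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return image.copy()
    if min(image.shape) < factor:
        raise ValueError(f"factor {factor} exceeds smallest extent {min(image.shape)}")
    spec = np.fft.fftn(image)
    for ax, n in enumerate(image.shape):
        mask = _bin_mask(n, factor)
        shape = [1] * image.ndim
        shape[ax] = n
        spec = spec * mask.reshape(shape)
    return np.real(np.fft.ifftn(spec))


def lowpass_gaussian(image: np.ndarray, cutoff: float) -> np.ndarray:
    """Gaussian low-pass with half-amplitude at ``cutoff`` x Nyquist."""
    image = np.asarray(image, dtype=np.float64)
    if not cutoff > 0:
        raise ValueError("cutoff must be > 0")
    fc = 0.5 * cutoff  # cycles/pixel at the cutoff
    grids = np.meshgrid(*[np.fft.fftfreq(n) for n in image.shape], indexing="ij")
    r2 = sum(g * g for g in grids)
    filt = np.exp(-np.log(2.0) * r2 / fc**2)  # 0.5 at |f| == fc
    spec = np.fft.fftn(image) * filt
    return np.real(np.fft.ifftn(spec))


def dose_titration(
    stack: MovieStack,
    fractions: Sequence[float],
    methods: Mapping[str, Callable[[np.ndarray], np.ndarray]],
) -> pd.DataFrame:
    """SNR (dB) of each method at each dose fraction of the odd half.

    The stack is split even/odd; the odd half is truncated to the first
    ``floor(fraction * n_odd_frames)`` frames (fractions are of the *total*
    dose, so only (0, 0.5] makes sense), summed, processed by each method,
    and correlated against the full even sum via :func:`snr_split`.
    Rows are fractions, columns methods.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    pair = split_even_odd(stack)
    even_full = pair.even.data
    odd_frames = stack.frames[1::2]
    n_odd = odd_frames.shape[0]
    rows = {}
    for frac in fractions:
        if not 0 < frac <= 0.5:
            warnings.warn(
                f"fraction {frac} outside (0, 0.5]: the odd half holds at most half "
                "the total dose; skipping",
                stacklevel=2,
            )
            continue
        # fraction of the *total* dose, taken as a frame prefix of the odd half
        k = min(int(np.floor(frac * stack.n_frames + 1e-9)), n_odd)
        if k < 1:
            warnings.warn(f"fraction {frac} rounds down to zero frames; skipping", stacklevel=2)
            continue
        odd_sum = np.add.reduce(odd_frames[:k].astype(np.float64), axis=0)
        row = {}
        for name, fn in methods.items():
            row[name] = snr_split(fn(odd_sum), even_full)
        rows[frac] = row
    if not rows:
        raise ValueError("no usable fractions")
    return pd.DataFrame.from_dict(rows, orient="index")


def scale_display(image: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Quantize intensities for display relative to a low-passed reference.

    ``z = (image - mean(ref)) / std(ref)`` clamped to [-4, 4] and floored
    into 256 uniform buckets (z = 0 lands in bucket 128). Returns uint8.
    """
    reference = np.asarray(reference, dtype=np.float64)
    std = reference.std()
    if std == 0:
        raise ValueError("constant reference image")
    z = (np.asarray(image, dtype=np.float64) - reference.mean()) / std
    z = np.clip(z, -4.0, 4.0)
    buckets = np.floor((z + 4.0) / 8.0 * 256.0)
    return np.clip(buckets, 0, 255).astype(np.uint8)


def read_region_tsv(path) -> RegionPairSet:
    """Parse region annotations from a TSV file.

    Columns: image_name, role (signal|background), pair_id, x0, y0, x1, y1
    (0-based, half-open). Each pair_id must appear exactly once per role.
    """
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str})
    required = {"image_name", "role", "pair_id", "x0", "y0", "x1", "y1"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    items = []
    for pair_id, group in df.groupby("pair_id", sort=True):
        roles = dict(zip(group["role"], group.index))
        if set(roles) != {"signal", "background"}:
            raise ValueError(f"{path}: pair {pair_id!r} needs exactly one signal and one background row")
        sig = group.loc[roles["signal"]]
        bg = group.loc[roles["background"]]
        if sig["image_name"] != bg["image_name"]:
            raise ValueError(f"{path}: pair {pair_id!r} spans two images")
        items.append(
            RegionPair(
                image_name=str(sig["image_name"]),
                pair_id=str(pair_id),
                signal=Rect(int(sig.x0), int(sig.y0), int(sig.x1), int(sig.y1)),
                background=Rect(int(bg.x0), int(bg.y0), int(bg.x1), int(bg.y1)),
            )
        )
    return RegionPairSet(items=items)
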