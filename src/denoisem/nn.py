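"""Minimal N-dimensional convolutional network engine (NumPy + FFT).

Implements exactly the operators the denoising architectures need --
same-shape zero-padded convolutions (odd kernels), leaky rectifiers,
2x max pooling, 2x nearest-neighbour upsampling -- with hand-written
backward passes and an Adagrad optimizer. Convolutions run in the Fourier
domain, which is exact for linear convolution when the transform size is
``S + k - 1`` and fast enough on a single CPU for the patch sizes used
here. Works identically for 2D (images) and 3D (volumes); batches are
leading axes ``(N, C, *spatial)``.

Everything is deterministic given the seeds handed to the initializers.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import fft as sp_fft

__all__ = [
    "Param",
    "ConvND",
    "LeakyReLU",
    "MaxPoolND",
    "UpsampleND",
    "Adagrad",
]


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0


def _spatial_axes(nd: int) -> Tuple[int, ...]:
    return tuple(range(-nd, 0))


from functools import lru_cache


@lru_cache(maxsize=64)
def _dft_twiddle(length: int, taps: int, rfft_axis: bool) -> np.ndarray:
    """(frequencies, taps) matrix evaluating a zero-padded DFT at few taps."""
    if rfft_axis:
        m = np.arange(length // 2 + 1)
    else:
        m = np.fft.fftfreq(length) * length
    t = np.arange(taps)
    return np.exp(-2j * np.pi * np.outer(m, t) / length)


def _kernel_spectrum(w: np.ndarray, fshape: Tuple[int, ...], flipped: bool, complex_dtype) -> np.ndarray:
    """rfftn of a small zero-padded kernel via separable direct DFT.

    Far cheaper than a full FFT when the kernel has few taps: each axis is
    a (taps x frequencies) tensordot shared across all channel pairs.
    """
    nd = w.ndim - 2
    if flipped:
        w = w[(Ellipsis,) + (slice(None, None, -1),) * nd]
    arr = w.astype(complex_dtype)
    for j in range(nd):
        tw = _dft_twiddle(fshape[j], w.shape[2 + j], rfft_axis=(j == nd - 1))
        arr = np.tensordot(arr, tw.astype(complex_dtype), axes=([2], [1]))
    return arr


@lru_cache(maxsize=64)
def _idft_twiddle(length: int, taps: int, centre: int, rfft_axis: bool) -> np.ndarray:
    """(taps, frequencies) matrix evaluating an inverse DFT at few lags.

    Lags are ``(t - centre) mod length`` for ``t`` in [0, taps). For the
    half-spectrum axis the interior bins carry weight 2 (their conjugate
    partners are not stored); the result is exact once the real part is
    taken over the full contraction.
    """
    lags = (np.arange(taps) - centre) % length
    if rfft_axis:
        m = np.arange(length // 2 + 1)
        weights = np.full(m.shape, 2.0)
        weights[0] = 1.0
        if length % 2 == 0:
            weights[-1] = 1.0
    else:
        m = np.fft.fftfreq(length) * length
        weights = np.ones(m.shape)
    tw = np.exp(2j * np.pi * np.outer(lags, m) / length) * weights
    return tw / length


def _spectrum_to_kernel_grad(cf: np.ndarray, fshape: Tuple[int, ...], kernel: Tuple[int, ...]) -> np.ndarray:
    """Evaluate the (real) correlation spectrum at the k**nd kernel lags."""
    nd = len(kernel)
    arr = cf
    for j in range(nd):
        tw = _idft_twiddle(fshape[j], kernel[j], kernel[j] // 2, rfft_axis=(j == nd - 1))
        arr = np.tensordot(arr, tw.astype(cf.dtype), axes=([2], [1]))
    return np.real(arr)


def _freq_contract(a: np.ndarray, b: np.ndarray, pattern: str) -> np.ndarray:
    """Per-frequency channel contraction as a batched GEMM.

    ``a``: (N, Ci, *F) spectra, ``b``: (Co, Ci, *F) kernel spectra (or the
    analogous shapes for the gradient contractions). ``pattern`` selects
    the contraction; batched matmul over the flattened frequency axis is
    far faster than the equivalent einsum.
    """
    fshape = a.shape[2:]
    nf = int(np.prod(fshape))
    a2 = a.reshape(a.shape[0], a.shape[1], nf)
    b2 = b.reshape(b.shape[0], b.shape[1], nf)
    batched = a2.shape[0] >= 4  # batched GEMM wins for minibatches, the
    # channel loop for single-image inference (memory-traffic bound)
    if pattern == "ni,oi->no":
        # out[n,o] = sum_i a[n,i] * b[o,i]
        if batched:
            out = (a2.transpose(2, 0, 1) @ b2.transpose(2, 1, 0)).transpose(1, 2, 0)
            return np.ascontiguousarray(out).reshape(a.shape[0], b.shape[0], *fshape)
        out = np.empty((a2.shape[0], b2.shape[0], nf), dtype=np.result_type(a2, b2))
        for o in range(b2.shape[0]):
            np.sum(a2 * b2[o][None], axis=1, out=out[:, o])
        return out.reshape(a.shape[0], b.shape[0], *fshape)
    if pattern == "ni,no->oi":
        # out[o,i] = sum_n a[n,i] * b[n,o]
        if batched:
            out = (b2.transpose(2, 1, 0) @ a2.transpose(2, 0, 1)).transpose(1, 2, 0)
            return np.ascontiguousarray(out).reshape(b.shape[1], a.shape[1], *fshape)
        out = np.empty((b2.shape[1], a2.shape[1], nf), dtype=np.result_type(a2, b2))
        for o in range(b2.shape[1]):
            np.sum(a2 * b2[:, o][:, None], axis=0, out=out[o])
        return out.reshape(b.shape[1], a.shape[1], *fshape)
    raise ValueError(pattern)


class ConvND:
    """Same-shape convolution with zero padding; odd kernel sizes only.

    ``y[n,o] = bias[o] + sum_i corr(x[n,i], W[o,i])`` where ``corr`` is the
    cross-correlation convention used by ML frameworks.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: Sequence[int],
        rng: Optional[np.random.Generator] = None,
        init: str = "fan_in_uniform",
        dtype=np.float32,
    ):
        kernel = tuple(int(k) for k in kernel)
        if any(k % 2 == 0 or k < 1 for k in kernel):
            raise ValueError(f"kernel sizes must be odd and positive, got {kernel}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.nd = len(kernel)
        self.dtype = np.dtype(dtype)
        wshape = (out_channels, in_channels) + kernel
        if init == "zero":
            w = np.zeros(wshape)
            b = np.zeros(out_channels)
        elif init == "fan_in_uniform":
            if rng is None:
                raise ValueError("fan_in_uniform init needs an rng")
            fan_in = in_channels * int(np.prod(kernel))
            bound = 1.0 / np.sqrt(fan_in)
            w = rng.uniform(-bound, bound, size=wshape)
            b = rng.uniform(-bound, bound, size=out_channels)
        else:
            raise ValueError(f"unknown init {init!r}")
        self.weight = Param(w.astype(self.dtype))
        self.bias = Param(b.astype(self.dtype))
        self._cache = None
        # kernel spectra keyed by (fshape, flipped); revalidated against a
        # stored weight copy so direct weight edits can never go stale
        self._kf_cache: dict = {}

    def _kernel_fft(self, fshape: Tuple[int, ...], flipped: bool) -> np.ndarray:
        w = self.weight.value
        key = (fshape, flipped)
        hit = self._kf_cache.get(key)
        if hit is not None and np.array_equal(hit[0], w):
            return hit[1]
        cdtype = np.complex128 if self.dtype == np.float64 else np.complex64
        kf = _kernel_spectrum(w, fshape, flipped, cdtype)
        if len(self._kf_cache) > 8:
            self._kf_cache.clear()
        self._kf_cache[key] = (w.copy(), kf)
        return kf

    def params(self) -> List[Param]:
        return [self.weight, self.bias]

    def _fshape(self, spatial: Tuple[int, ...]) -> Tuple[int, ...]:
        # any size >= S + k - 1 keeps the linear convolution exact; rounding
        # up to even FFT-friendly lengths is much faster for awkward sizes
        out = []
        for s, k in zip(spatial, self.kernel):
            n = sp_fft.next_fast_len(s + k - 1, real=True)
            while n % 2:
                n = sp_fft.next_fast_len(n + 1, real=True)
            out.append(n)
        return tuple(out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        nd = self.nd
        axes = _spatial_axes(nd)
        spatial = x.shape[-nd:]
        fshape = self._fshape(spatial)
        xf = sp_fft.rfftn(x, s=fshape, axes=axes, workers=1)
        kf = self._kernel_fft(fshape, flipped=True)
        yf = _freq_contract(xf, kf, "ni,oi->no")
        y_full = sp_fft.irfftn(yf, s=fshape, axes=axes, workers=1)
        centre = (Ellipsis,) + tuple(slice(k // 2, k // 2 + s) for k, s in zip(self.kernel, spatial))
        y = y_full[centre].astype(self.dtype, copy=True)
        y += self.bias.value.reshape((-1,) + (1,) * nd)
        self._cache = (xf, spatial, fshape)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        nd = self.nd
        axes = _spatial_axes(nd)
        xf, spatial, fshape = self._cache
        gf = sp_fft.rfftn(gy, s=fshape, axes=axes, workers=1)

        # bias gradient
        self.bias.grad += gy.sum(axis=(0,) + axes).astype(self.dtype)

        # weight gradient: circular correlation of input with output grad,
        # evaluated only at the k**nd kernel lags (no wrap-around
        # contamination because fshape >= S + k - 1)
        cf = _freq_contract(xf, np.conj(gf), "ni,no->oi")
        gw = _spectrum_to_kernel_grad(cf, fshape, self.kernel)
        self.weight.grad += gw.astype(self.dtype)

        # input gradient: true convolution of gy with the (unflipped) kernel
        kf2 = self._kernel_fft(fshape, flipped=False)
        kf2_t = kf2.transpose((1, 0) + tuple(range(2, kf2.ndim)))
        gxf = _freq_contract(gf, kf2_t, "ni,oi->no")
        gx_full = sp_fft.irfftn(gxf, s=fshape, axes=axes, workers=1)
        centre = (Ellipsis,) + tuple(slice(k // 2, k // 2 + s) for k, s in zip(self.kernel, spatial))
        self._cache = None
        return gx_full[centre].astype(self.dtype, copy=True)


class LeakyReLU:
    def __init__(self, slope: float = 0.1):
        self.slope = float(slope)
        self._mask = None

    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = np.where(self._mask, gy, np.asarray(self.slope, dtype=gy.dtype) * gy)
        self._mask = None
        return gx


class MaxPoolND:
    """2x max pooling; spatial extents must be even."""

    def __init__(self, nd: int):
        self.nd = nd
        self._cache = None

    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        nd = self.nd
        spatial = x.shape[-nd:]
        if any(s % 2 for s in spatial):
            raise ValueError(f"max pool needs even spatial extents, got {spatial}")
        lead = x.shape[:-nd]
        shape = list(lead)
        for s in spatial:
            shape.extend([s // 2, 2])
        xr = x.reshape(shape)
        # move the window axes (every second spatial axis) to the end
        nlead = len(lead)
        win_axes = [nlead + 2 * j + 1 for j in range(nd)]
        keep_axes = [a for a in range(xr.ndim) if a not in win_axes]
        xt = np.transpose(xr, keep_axes + win_axes)
        flat = xt.reshape(xt.shape[: nlead + nd] + (2**nd,))
        arg = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, x.shape)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        nd = self.nd
        arg, xshape = self._cache
        lead = xshape[:-nd]
        nlead = len(lead)
        half = tuple(s // 2 for s in xshape[-nd:])
        flat = np.zeros(lead + half + (2**nd,), dtype=gy.dtype)
        np.put_along_axis(flat, arg[..., None], gy[..., None], axis=-1)
        # invert the transpose/reshape of forward
        xt_shape = lead + half + (2,) * nd
        xt = flat.reshape(xt_shape)
        keep_axes = list(range(nlead)) + [nlead + 2 * j for j in range(nd)]
        win_axes = [nlead + 2 * j + 1 for j in range(nd)]
        src = list(range(xt.ndim))
        # forward did transpose(keep + win); build the inverse permutation
        fwd_perm = keep_axes + win_axes
        inv_perm = np.argsort(fwd_perm)
        gx = np.transpose(xt, inv_perm).reshape(xshape)
        self._cache = None
        return gx


class UpsampleND:
    """2x nearest-neighbour upsampling."""

    def __init__(self, nd: int):
        self.nd = nd

    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        for ax in _spatial_axes(self.nd):
            x = np.repeat(x, 2, axis=ax)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        nd = self.nd
        lead = gy.shape[:-nd]
        spatial = gy.shape[-nd:]
        shape = list(lead)
        for s in spatial:
            shape.extend([s // 2, 2])
        gr = gy.reshape(shape)
        nlead = len(lead)
        for j in range(nd - 1, -1, -1):
            gr = gr.sum(axis=nlead + 2 * j + 1)
        return gr


class Adagrad:
    """Adagrad with per-parameter accumulated squared gradients."""

    def __init__(self, params: Sequence[Param], lr: float = 0.001, eps: float = 1e-10):
        self.params = list(params)
        self.lr = float(lr)
        self.eps = float(eps)
        self.state = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        for p, s in zip(self.params, self.state):
            g = p.grad
            s += g * g
            p.value -= (self.lr * g / (np.sqrt(s) + self.eps)).astype(p.value.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
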