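"""Denoising model architectures and receptive-field accounting.

Four 2D architectures and one 3D architecture are provided:

* ``affine`` -- a single 31x31 convolution (weights start at zero). Trained
  with the L2 objective this is exactly the linear least-squares (Wiener)
  filter problem.
* ``fcnn`` -- three 11x11 convolutions with 64 filters and leaky
  rectifiers between them.
* ``unet_small`` / ``unet`` -- encoder/decoder with 3 / 5 max-pooling and
  nearest-neighbour upsampling stages, skip connections at every
  resolution, and a width-11 first convolution.
* ``unet3d`` -- the same topology with 3D operators and a width-7 first
  convolution (default depth 3 so a 96-voxel patch survives pooling;
  ``depth`` is configurable).
* ``constant`` -- a bias-only predictor (diagnostic; its L1/L2 optima are
  the target median/mean).

Every model preserves spatial shape exactly: inputs whose sides are not
divisible by ``2**depth`` are padded at the trailing edges (mirror when
possible) and cropped back after the forward pass.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional

import numpy as np

from denoisem.nn import Adagrad, ConvND, LeakyReLU, MaxPoolND, Param, UpsampleND

__all__ = [
    "ARCHITECTURES",
    "ModelSpec",
    "Denoiser",
    "build_model",
    "receptive_field",
    "save_checkpoint",
    "load_checkpoint",
]

ARCHITECTURES = ("affine", "fcnn", "unet_small", "unet", "unet3d", "constant")

_DEFAULT_DEPTH = {"unet_small": 3, "unet": 5, "unet3d": 3}


@dataclass
class ModelSpec:
    """Architecture description; fully determines a freshly built model."""

    arch: str
    in_channels: int = 1
    base_width: int = 48
    activation_slope: float = 0.1
    seed: int = 0
    depth: Optional[int] = None  # unet family only; None -> architecture default
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.arch not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.arch!r}; valid names: {', '.join(ARCHITECTURES)}"
            )
        if self.base_width < 1:
            raise ValueError("base_width must be >= 1")
        if self.depth is None:
            self.depth = _DEFAULT_DEPTH.get(self.arch, 0)

    @property
    def ndim(self) -> int:
        return 3 if self.arch == "unet3d" else 2


class _Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self) -> List[Param]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class _UNet:
    """Encoder/decoder with skip connections (2D or 3D by ``nd``)."""

    def __init__(self, nd, depth, width, k_first, slope, rng, dtype):
        self.nd = nd
        self.depth = depth
        kf = (k_first,) * nd
        k3 = (3,) * nd
        act = lambda: LeakyReLU(slope)  # noqa: E731
        self.enc_first = ConvND(1, width, kf, rng=rng, dtype=dtype)
        self.enc_first_act = act()
        self.enc_convs = []
        self.pools = []
        for _ in range(depth):
            self.pools.append(MaxPoolND(nd))
            self.enc_convs.append((ConvND(width, width, k3, rng=rng, dtype=dtype), act()))
        self.ups = []
        self.dec_convs = []
        for _ in range(depth):
            self.ups.append(UpsampleND(nd))
            self.dec_convs.append(
                (
                    ConvND(2 * width, width, k3, rng=rng, dtype=dtype),
                    act(),
                    ConvND(width, width, k3, rng=rng, dtype=dtype),
                    act(),
                )
            )
        self.final = ConvND(width, 1, k3, rng=rng, dtype=dtype)
        self.width = width

    def params(self) -> List[Param]:
        out = self.enc_first.params()
        for conv, _ in self.enc_convs:
            out.extend(conv.params())
        for c1, _, c2, _ in self.dec_convs:
            out.extend(c1.params())
            out.extend(c2.params())
        out.extend(self.final.params())
        return out

    def forward(self, x):
        feats = [self.enc_first_act.forward(self.enc_first.forward(x))]
        h = feats[0]
        for pool, (conv, act) in zip(self.pools, self.enc_convs):
            h = act.forward(conv.forward(pool.forward(h)))
            feats.append(h)
        for i in range(self.depth):
            skip = feats[self.depth - 1 - i]
            u = self.ups[i].forward(h)
            c1, a1, c2, a2 = self.dec_convs[i]
            h = np.concatenate([u, skip], axis=1)
            h = a2.forward(c2.forward(a1.forward(c1.forward(h))))
        return self.final.forward(h)

    def backward(self, gy):
        # forward: feats[j+1] = act(conv(pool(feats[j]))); decoder stage i
        # consumes feats[depth-1-i] as its skip. Skip gradients are
        # accumulated and folded in while walking back up the encoder.
        w = self.width
        g = self.final.backward(gy)
        gskips = [None] * self.depth  # gradient wrt feats[0..depth-1] via skips
        for i in range(self.depth - 1, -1, -1):
            c1, a1, c2, a2 = self.dec_convs[i]
            g = c1.backward(a1.backward(c2.backward(a2.backward(g))))
            gu, gskip = g[:, :w], g[:, w:]
            gskips[self.depth - 1 - i] = gskip
            g = self.ups[i].backward(gu)
        # g is now the gradient wrt feats[depth]
        for j in range(self.depth - 1, -1, -1):
            conv, act = self.enc_convs[j]
            g = self.pools[j].backward(conv.backward(act.backward(g)))
            g = g + gskips[j]
        return self.enc_first.backward(self.enc_first_act.backward(g))


class Denoiser:
    """A trained (or trainable) image -> image mapping.

    ``forward`` maps an unbatched ``(H, W)`` plane or ``(D, H, W)`` volume
    to an identically shaped output. ``forward_batch`` / ``backward_batch``
    expose the training interface on ``(N, 1, *spatial)`` arrays whose
    spatial extents must be divisible by :attr:`granularity`.
    """

    def __init__(self, spec: ModelSpec, net, receptive_field: int, granularity: int):
        self.spec = spec
        self.net = net
        self.receptive_field = int(receptive_field)
        self.granularity = int(granularity)

    @property
    def ndim(self) -> int:
        return self.spec.ndim

    def params(self) -> List[Param]:
        return self.net.params()

    def forward_batch(self, x: np.ndarray) -> np.ndarray:
        nd = self.ndim
        if x.ndim != nd + 2:
            raise ValueError(f"expected (N, 1, {'D, ' if nd == 3 else ''}H, W) input")
        if any(s % self.granularity for s in x.shape[2:]):
            raise ValueError(
                f"batched spatial extents {x.shape[2:]} must be divisible by {self.granularity}"
            )
        return self.net.forward(x)

    def backward_batch(self, gy: np.ndarray) -> np.ndarray:
        return self.net.backward(gy)

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Shape-preserving forward on a single unbatched image or volume."""
        nd = self.ndim
        image = np.asarray(image)
        if image.ndim != nd:
            raise ValueError(
                f"model {self.spec.arch!r} expects {nd}D input, got {image.ndim}D"
            )
        if min(image.shape) < 1:
            raise ValueError("zero-extent input")
        m = self.granularity
        pads = tuple((-s) % m for s in image.shape)
        x = image.astype(np.dtype(self.spec.dtype), copy=False)
        if any(pads):
            pad_spec = []
            for s, p in zip(image.shape, pads):
                pad_spec.append((0, p))
            mode = "reflect" if all(p <= s - 1 for s, p in zip(image.shape, pads)) else "edge"
            x = np.pad(x, pad_spec, mode=mode)
        y = self.net.forward(x[None, None])
        out = y[0, 0]
        if any(pads):
            out = out[tuple(slice(0, s) for s in image.shape)]
        return np.ascontiguousarray(out)


def _op_chain(spec: ModelSpec):
    """1D op sequence of the widest path (through the bottleneck)."""
    if spec.arch in ("affine",):
        return [("conv", 31)]
    if spec.arch == "constant":
        return [("conv", 1)]
    if spec.arch == "fcnn":
        return [("conv", 11)] * 3
    k_first = 7 if spec.arch == "unet3d" else 11
    ops = [("conv", k_first)]
    for _ in range(spec.depth):
        ops += [("pool",), ("conv", 3)]
    for _ in range(spec.depth):
        ops += [("up",), ("conv", 3), ("conv", 3)]
    ops.append(("conv", 3))
    return ops


def _influence_width(ops, q: int) -> int:
    """How many output pixels one input pixel at phase ``q`` can reach."""
    lo = hi = q
    for op in ops:
        if op[0] == "conv":
            r = op[1] // 2
            lo, hi = lo - r, hi + r
        elif op[0] == "pool":
            lo, hi = lo // 2, hi // 2
        else:  # up
            lo, hi = 2 * lo, 2 * hi + 1
    return hi - lo + 1


def _dependency_width(ops, p: int) -> int:
    """How many input pixels one output pixel at phase ``p`` can see."""
    lo = hi = p
    for op in reversed(ops):
        if op[0] == "conv":
            r = op[1] // 2
            lo, hi = lo - r, hi + r
        elif op[0] == "pool":
            lo, hi = 2 * lo, 2 * hi + 1
        else:  # up
            lo, hi = lo // 2, hi // 2
    return hi - lo + 1


def receptive_field(spec: ModelSpec) -> int:
    """Side length bounding the input/output interaction of one pixel.

    Exact integer interval propagation through the widest path, maximized
    over pooling phases and over both directions (which inputs an output
    depends on; which outputs an input influences — these differ for
    strided architectures). Rounded up to odd.
    """
    ops = _op_chain(spec)
    period = 2 ** max(
        sum(1 for op in ops if op[0] == "pool"), 1
    )
    rf = 1
    for phase in range(period):
        rf = max(rf, _influence_width(ops, phase), _dependency_width(ops, phase))
    return rf if rf % 2 else rf + 1


def build_model(spec: ModelSpec) -> Denoiser:
    """Instantiate a Denoiser from its spec (deterministic given spec.seed)."""
    rng = np.random.default_rng(spec.seed)
    dtype = np.dtype(spec.dtype)
    slope = spec.activation_slope
    if spec.arch == "affine":
        net = _Sequential([ConvND(1, 1, (31, 31), init="zero", dtype=dtype)])
        gran = 1
    elif spec.arch == "constant":
        net = _Sequential([ConvND(1, 1, (1, 1), init="zero", dtype=dtype)])
        net.layers[0].weight.value[...] = 0  # bias-only: freeze handled by trainer
        gran = 1
    elif spec.arch == "fcnn":
        w = 64
        net = _Sequential(
            [
                ConvND(1, w, (11, 11), rng=rng, dtype=dtype),
                LeakyReLU(slope),
                ConvND(w, w, (11, 11), rng=rng, dtype=dtype),
                LeakyReLU(slope),
                ConvND(w, 1, (11, 11), rng=rng, dtype=dtype),
            ]
        )
        gran = 1
    elif spec.arch in ("unet_small", "unet"):
        net = _UNet(2, spec.depth, spec.base_width, 11, slope, rng, dtype)
        gran = 2**spec.depth
    elif spec.arch == "unet3d":
        net = _UNet(3, spec.depth, spec.base_width, 7, slope, rng, dtype)
        gran = 2**spec.depth
    else:
        raise ValueError(
            f"unknown architecture {spec.arch!r}; valid names: {', '.join(ARCHITECTURES)}"
        )
    return Denoiser(spec, net, receptive_field(spec), gran)


def save_checkpoint(model: Denoiser, path) -> None:
    """Write spec + parameters to a single-file NPZ archive (version 1)."""
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    meta = dict(asdict(model.spec))
    header = json.dumps({"format_version": 1, "spec": meta})
    meta_arr = np.frombuffer(header.encode(), dtype=np.uint8)
    if hasattr(path, "write"):
        np.savez(path, __meta__=meta_arr, **arrays)
    else:
        # np.savez appends ".npz" to plain paths; an open handle keeps the name
        with open(path, "wb") as fh:
            np.savez(fh, __meta__=meta_arr, **arrays)


def load_checkpoint(path) -> Denoiser:
    """Rebuild a Denoiser from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta.get("format_version") != 1:
            raise ValueError(f"unsupported checkpoint version: {meta.get('format_version')}")
        spec = ModelSpec(**meta["spec"])
        model = build_model(spec)
        params = model.params()
        for i, p in enumerate(params):
            stored = archive[f"param_{i}"]
            if stored.shape != p.value.shape:
                raise ValueError(f"checkpoint parameter {i} shape mismatch")
            p.value[...] = stored
    return model
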