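"""Reading and writing MRC2014 images, stacks and volumes (plus TIFF convenience).

Conventions
-----------
* Arrays are indexed ``(Z,) Y, X`` with 0-based coordinates; all intervals
  are half-open ``[start, end)``.
* Files are always written as MRC mode 2 (float32). Modes 0/1/2/6 are
  accepted on read and promoted to float32.
* A 3D MRC is only interpreted as a movie stack when the caller asks for it
  (``as_stack=True``) or the header's image-stack flag is set; otherwise it
  is a :class:`Volume`. MRC headers do not distinguish the two reliably.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import mrcfile
import numpy as np
import tifffile

__all__ = [
    "FormatError",
    "ImagePlane",
    "Volume",
    "MovieStack",
    "read_image",
    "write_image",
]


class FormatError(ValueError):
    """Raised when a file cannot be interpreted as a supported image format."""


def _check_finite(data: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(data)):
        bad = int(np.count_nonzero(~np.isfinite(data)))
        raise ValueError(f"{what} contains {bad} non-finite value(s); refusing")


@dataclass
class ImagePlane:
    """A single 2D real-valued image (rows = Y, cols = X)."""

    data: np.ndarray
    pixel_size: Optional[float] = None
    origin_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or min(self.data.shape) < 1:
            raise ValueError(f"ImagePlane needs a 2D array, got shape {self.data.shape}")
        _check_finite(self.data, "ImagePlane data")
        if self.pixel_size is not None and not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class Volume:
    """A 3D real-valued grid indexed (Z, Y, X)."""

    data: np.ndarray
    voxel_size: Optional[float] = None
    origin_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"Volume needs a 3D array, got shape {self.data.shape}")
        _check_finite(self.data, "Volume data")
        if self.voxel_size is not None and not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class MovieStack:
    """Ordered raw detector frames of one exposure.

    ``frames`` is a (F, H, W) array; every frame is an independent noisy
    observation of the same underlying signal. ``dose_per_frame`` is in
    electrons per square Angstrom.
    """

    frames: np.ndarray
    pixel_size: Optional[float] = None
    dose_per_frame: Optional[float] = None
    origin_name: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError(f"MovieStack needs a (F, H, W) array, got shape {self.frames.shape}")
        _check_finite(self.frames, "MovieStack frames")
        if self.dose_per_frame is not None and self.dose_per_frame < 0:
            raise ValueError("dose_per_frame must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:]

    @property
    def total_dose(self) -> Optional[float]:
        if self.dose_per_frame is None:
            return None
        return self.dose_per_frame * self.n_frames

    def frame(self, i: int) -> ImagePlane:
        return ImagePlane(self.frames[i], pixel_size=self.pixel_size, origin_name=f"{self.origin_name}[{i}]")


ImageLike = Union[ImagePlane, Volume, MovieStack]

_SUPPORTED_MODES = {0, 1, 2, 6}


def _read_mrc(path: Path, as_stack: Optional[bool]) -> ImageLike:
    size = os.path.getsize(path)
    if size < 1024:
        raise FormatError(
            f"{path}: file is {size} bytes, smaller than the 1024-byte MRC2014 header"
        )
    try:
        with mrcfile.open(path, mode="r", permissive=False) as mrc:
            mode = int(mrc.header.mode)
            if mode not in _SUPPORTED_MODES:
                raise FormatError(
                    f"{path}: MRC mode {mode} unsupported (accepted: {sorted(_SUPPORTED_MODES)})"
                )
            data = np.asarray(mrc.data, dtype=np.float32).copy()
            px = float(mrc.voxel_size.x)
            pixel_size = px if px > 0 else None
            header_stack = bool(mrc.is_image_stack())
    except FormatError:
        raise
    except Exception as exc:  # mrcfile raises ValueError on truncated payloads
        raise FormatError(f"{path}: unreadable MRC (file size {size} bytes): {exc}") from exc

    name = path.name
    if data.ndim == 2:
        return ImagePlane(data, pixel_size=pixel_size, origin_name=name)
    if data.ndim == 3:
        stack = header_stack if as_stack is None else as_stack
        if stack:
            return MovieStack(data, pixel_size=pixel_size, origin_name=name)
        return Volume(data, voxel_size=pixel_size, origin_name=name)
    raise FormatError(f"{path}: unsupported dimensionality {data.ndim}")


def _read_tiff(path: Path, as_stack: Optional[bool]) -> ImageLike:
    try:
        data = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable TIFF: {exc}") from exc
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        return ImagePlane(data, origin_name=path.name)
    if data.ndim == 3:
        if as_stack is False:
            return Volume(data, origin_name=path.name)
        # multipage TIFF defaults to a stack of planes
        return MovieStack(data, origin_name=path.name)
    raise FormatError(f"{path}: unsupported TIFF dimensionality {data.ndim}")


def read_image(path, as_stack: Optional[bool] = None) -> ImageLike:
    """Read an MRC2014 (or TIFF) file into the matching domain type.

    Parameters
    ----------
    path : path-like
        File to read. ``.tif``/``.tiff`` suffixes go through the TIFF
        reader; everything else is treated as MRC.
    as_stack : bool, optional
        Force 3D data to be a :class:`MovieStack` (True) or :class:`Volume`
        (False). Default: trust the MRC image-stack header flag.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_tiff(path, as_stack)
    return _read_mrc(path, as_stack)


def write_image(obj: ImageLike, path) -> None:
    """Write an ImagePlane / Volume / MovieStack as MRC2014 mode 2 (float32).

    ``read_image(write_image(x))`` round-trips bitwise for float32 payloads.
    Non-finite values are refused.
    """
    path = Path(path)
    if isinstance(obj, ImagePlane):
        data, px, stack = obj.data, obj.pixel_size, False
    elif isinstance(obj, Volume):
        data, px, stack = obj.data, obj.voxel_size, False
    elif isinstance(obj, MovieStack):
        data, px, stack = obj.frames, obj.pixel_size, True
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    _check_finite(data, "data to write")
    data = np.ascontiguousarray(data, dtype=np.float32)
    with mrcfile.new(path, overwrite=True) as mrc:
        mrc.set_data(data)
        if stack and data.ndim == 3:
            mrc.set_image_stack()
        if px is not None:
            mrc.voxel_size = px
        mrc.update_header_from_data()
        mrc.update_header_stats()
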