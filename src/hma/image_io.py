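"""Raster I/O for the pipeline.

All images are held in memory as 2-D float arrays on a canonical ``[0, 1]``
intensity scale, regardless of the bit depth of the source file; every
threshold elsewhere in the package is expressed on this scale.  Label maps
round-trip bit-exactly through 16-bit single-channel TIFF, binary masks
through ``{0, 255}`` 8-bit PNG.

Coordinates are (row, col), 0-based, origin at the top-left corner.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

from .errors import CapacityError, FormatError

#: ITU-R BT.601 luminance weights used to collapse stray RGB inputs.
_BT601 = np.array([0.299, 0.587, 0.114])

MIN_SIDE = 8


@dataclass
class IntensityImage:
    """A single-channel image rescaled to the canonical [0, 1] float scale.

    Parameters
    ----------
    pixels
        2-D float array with values in ``[0, 1]``.
    bit_depth_origin
        Bit depth of the source raster (8 or 16); informational only --
        all processing happens on the float scale.
    """

    pixels: np.ndarray
    bit_depth_origin: int = 8
    path: str | None = field(default=None, compare=False)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


def as_float_image(image) -> np.ndarray:
    """Coerce an :class:`IntensityImage` or bare array to a float64 2-D array."""
    pixels = image.pixels if isinstance(image, IntensityImage) else np.asarray(image)
    if pixels.ndim != 2:
        raise FormatError(f"expected a 2-D image, got shape {pixels.shape}")
    return np.asarray(pixels, dtype=np.float64)


def _rescale(raw: np.ndarray) -> tuple[np.ndarray, int]:
    if raw.dtype == np.uint8:
        return raw.astype(np.float64) / 255.0, 8
    if raw.dtype == np.uint16:
        return raw.astype(np.float64) / 65535.0, 16
    if np.issubdtype(raw.dtype, np.floating):
        # Float rasters are assumed to already be on [0, 1].
        return np.clip(raw.astype(np.float64), 0.0, 1.0), 16
    if np.issubdtype(raw.dtype, np.integer):
        bits = 8 if raw.max(initial=0) <= 255 else 16
        return raw.astype(np.float64) / (2**bits - 1), bits
    raise FormatError(f"unsupported raster dtype {raw.dtype}")


def read_grayscale(path: str | os.PathLike) -> IntensityImage:
    """Read a TIFF/PNG raster as a grayscale :class:`IntensityImage`.

    RGB inputs are converted by BT.601 luminance; 8- and 16-bit integer
    rasters are rescaled by ``2**depth - 1``.  Images smaller than
    8 x 8 pixels are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            raw = tifffile.imread(path)
        else:
            raw = iio.imread(path)
    except (ValueError, OSError, RuntimeError) as exc:  # zero-size / non-raster
        raise FormatError(f"cannot read {path} as a raster: {exc}") from exc
    raw = np.asarray(raw)
    if raw.ndim == 3:
        if raw.shape[2] == 4:
            raw = raw[..., :3]
        if raw.shape[2] != 3:
            raise FormatError(f"unsupported channel count {raw.shape[2]} in {path}")
        pixels, depth = _rescale(raw)
        pixels = pixels @ _BT601
    elif raw.ndim == 2:
        pixels, depth = _rescale(raw)
    else:
        raise FormatError(f"{path} is not a 2-D raster (shape {raw.shape})")
    if pixels.shape[0] < MIN_SIDE or pixels.shape[1] < MIN_SIDE:
        raise FormatError(
            f"image {path} is {pixels.shape[0]}x{pixels.shape[1]}; "
            f"minimum supported size is {MIN_SIDE}x{MIN_SIDE}"
        )
    return IntensityImage(pixels=pixels, bit_depth_origin=depth, path=str(path))


def write_grayscale(image, path: str | os.PathLike, bit_depth: int = 16) -> None:
    """Write a [0, 1] image to disk, quantized to the requested bit depth."""
    pixels = as_float_image(image)
    scale = 2**bit_depth - 1
    quant = np.clip(np.rint(pixels * scale), 0, scale)
    path = Path(path)
    if bit_depth == 16:
        tifffile.imwrite(path, quant.astype(np.uint16))
    elif bit_depth == 8:
        if path.suffix.lower() in {".tif", ".tiff"}:
            tifffile.imwrite(path, quant.astype(np.uint8))
        else:
            iio.imwrite(path, quant.astype(np.uint8))
    else:
        raise FormatError(f"unsupported output bit depth {bit_depth}")


def write_label_map(labels: np.ndarray, path: str | os.PathLike) -> None:
    """Persist a nonnegative-integer label map as 16-bit single-channel TIFF.

    Raises :class:`CapacityError` when any label exceeds 65535 (the 16-bit
    capacity); round-trip reads return bit-identical label values.
    """
    arr = np.asarray(labels)
    if arr.ndim != 2 or not np.issubdtype(arr.dtype, np.integer):
        raise FormatError("label map must be a 2-D integer array")
    if arr.min(initial=0) < 0:
        raise FormatError("label map must be nonnegative")
    if arr.max(initial=0) > 65535:
        raise CapacityError(
            f"label map holds labels up to {int(arr.max())}, above the 16-bit "
            "TIFF capacity of 65535"
        )
    tifffile.imwrite(Path(path), arr.astype(np.uint16))


def read_label_map(path: str | os.PathLike) -> np.ndarray:
    """Read a label map written by :func:`write_label_map`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such label map: {path}")
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path} is not a single-channel label map")
    return arr.astype(np.int32)


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a boolean mask as an 8-bit {0, 255} PNG (or TIFF)."""
    arr = np.asarray(mask, dtype=bool)
    out = np.where(arr, 255, 0).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a {0, 255} mask file back to a boolean array."""
    img = read_grayscale(path)
    return img.pixels > 0.5
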