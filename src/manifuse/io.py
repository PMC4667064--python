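"""Grayscale raster I/O with lossless bit-depth round-tripping.

Images are read from 8- or 16-bit PNG/TIFF into normalized [0, 1] float
fields; the original bit depth is kept alongside so that writing back is an
exact inverse of the read normalization (fused pixels are verbatim copies
of source pixels, so the round trip is lossless).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from ._validate import check_image
from .errors import InvalidImageError

__all__ = ["GrayImage", "read_gray", "write_gray"]

logger = logging.getLogger(__name__)

_DTYPES = {8: np.uint8, 16: np.uint16}


@dataclass(frozen=True)
class GrayImage:
    """A normalized 2-D intensity field plus its source bit depth."""

    values: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        check_image(self.values)
        if self.bit_depth not in _DTYPES:
            raise InvalidImageError(
                f"bit_depth must be 8 or 16, got {self.bit_depth}")


def read_gray(path) -> GrayImage:
    """Read a single-channel PNG/TIFF into a normalized GrayImage.

    Multi-channel files are accepted only if all channels are identical
    (gray stored as RGB); anything else raises rather than silently
    converting to luminance.
    """
    raw = iio.imread(Path(path))
    if raw.ndim == 3:
        if raw.shape[2] > 1 and np.all(raw == raw[:, :, :1]):
            raw = raw[:, :, 0]
        else:
            raise InvalidImageError(
                f"{path}: multi-channel image with non-identical channels; "
                "convert to single-channel grayscale first")
    if raw.dtype == np.uint8:
        depth = 8
    elif raw.dtype == np.uint16:
        depth = 16
    else:
        raise InvalidImageError(
            f"{path}: unsupported dtype {raw.dtype}; expected uint8/uint16")
    values = raw.astype(np.float64) / float(2 ** depth - 1)
    return GrayImage(values=values, bit_depth=depth)


def write_gray(image, path, bit_depth: int | None = None) -> None:
    """Write a normalized image to PNG/TIFF at the requested bit depth.

    Values outside [0, 1] are clipped with a logged warning.  For values
    that originated from the same bit depth the write is the exact inverse
    of :func:`read_gray`'s normalization.
    """
    if isinstance(image, GrayImage):
        values = image.values
        depth = bit_depth if bit_depth is not None else image.bit_depth
    else:
        values = np.asarray(image, dtype=np.float64)
        depth = bit_depth if bit_depth is not None else 8
    if depth not in _DTYPES:
        raise InvalidImageError(f"bit_depth must be 8 or 16, got {depth}")
    if values.min() < 0.0 or values.max() > 1.0:
        logger.warning("write_gray: clipping out-of-range values into [0, 1]")
        values = np.clip(values, 0.0, 1.0)
    scale = float(2 ** depth - 1)
    raster = np.rint(values * scale).astype(_DTYPES[depth])
    iio.imwrite(Path(path), raster)
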