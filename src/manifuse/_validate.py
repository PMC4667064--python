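"""Shared input validation helpers (internal)."""

from __future__ import annotations

import numpy as np

from .errors import InvalidImageError, ShapeMismatchError


def check_image(values, *, name: str = "image", min_size: int = 2,
                unit_range: bool = True) -> np.ndarray:
    """Validate a 2-D grayscale intensity field and return it as float64.

    Parameters
    ----------
    values : array-like
        Candidate image.
    name : str
        Name used in error messages.
    min_size : int
        Minimum extent required along each axis.
    unit_range : bool
        If True, require all values inside [0, 1].
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidImageError(
            f"{name} must be 2-D grayscale, got ndim={arr.ndim}")
    if arr.shape[0] < min_size or arr.shape[1] < min_size:
        raise InvalidImageError(
            f"{name} must be at least {min_size}x{min_size}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidImageError(f"{name} contains non-finite values")
    if unit_range and (arr.min() < 0.0 or arr.max() > 1.0):
        raise InvalidImageError(
            f"{name} values must lie in [0, 1], got "
            f"[{arr.min():.6g}, {arr.max():.6g}]")
    return arr


def check_same_shape(a: np.ndarray, b: np.ndarray, *,
                     names: tuple[str, str] = ("first", "second")) -> None:
    if a.shape != b.shape:
        raise ShapeMismatchError(
            f"{names[0]} has shape {a.shape} but {names[1]} has shape "
            f"{b.shape}; inputs must be co-registered and equal-size")
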