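"""Modified spatial frequency and modified local contrast saliency maps.

The fusion rule needs a per-pixel measure of local detail.  Spatial
frequency (SF) is the RMS of first differences along rows and columns;
adding the two diagonal difference directions gives the *modified* spatial
frequency (MSF), which also responds to oblique edges:

    SF  = sqrt(RF^2 + CF^2)
    MSF = sqrt(SF^2 + DF^2)

where, for an M x N window I,

    RF^2 = (1/MN) * sum_{i, j>=2} (I(i,j) - I(i,j-1))^2
    CF^2 = (1/MN) * sum_{i>=2, j} (I(i,j) - I(i-1,j))^2
    DF^2 = (1/MN) * sum_{i>=2, j>=2} [(I(i,j) - I(i-1,j-1))^2
                                      + (I(i-1,j) - I(i,j-1))^2]

The MSF *map* evaluates these statistics on a sliding (2r+1) x (2r+1)
window centered at every pixel (reflect padding), with M, N the window
dimensions.  The modified local contrast (MLC) divides this high-frequency
activity by the local background brightness, taken as the adaptive-manifold
filter response:

    MLC = MSF / AMF   where AMF != 0,   MLC = MSF   where AMF == 0.

Human vision responds to contrast rather than absolute intensity, so the
ratio, not raw MSF, drives pixel selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._validate import check_image, check_same_shape
from .errors import InvalidImageError, InvalidParameterError

__all__ = [
    "SaliencyMaps",
    "spatial_frequency",
    "diagonal_frequency",
    "modified_spatial_frequency_map",
    "modified_local_contrast",
]


@dataclass(frozen=True)
class SaliencyMaps:
    """Per-pixel saliency fields of one source image.

    Attributes
    ----------
    msf : ndarray
        Modified spatial frequency map (>= 0), the high-frequency term.
    amf : ndarray
        Adaptive-manifold filter response, the low-frequency term.
    mlc : ndarray
        Modified local contrast map (>= 0) driving the decision map.
    """

    msf: np.ndarray
    amf: np.ndarray
    mlc: np.ndarray

    def __post_init__(self) -> None:
        check_same_shape(self.msf, self.amf, names=("msf", "amf"))
        check_same_shape(self.msf, self.mlc, names=("msf", "mlc"))
        if np.any(self.msf < 0) or np.any(self.mlc < 0):
            raise InvalidImageError("msf and mlc maps must be nonnegative")


def spatial_frequency(window: np.ndarray) -> float:
    """Row/column spatial frequency of a window, sqrt(RF^2 + CF^2)."""
    w = check_image(window, name="window", unit_range=False)
    m, n = w.shape
    rf2 = np.sum((w[:, 1:] - w[:, :-1]) ** 2) / (m * n)
    cf2 = np.sum((w[1:, :] - w[:-1, :]) ** 2) / (m * n)
    return float(np.sqrt(rf2 + cf2))


def diagonal_frequency(window: np.ndarray) -> float:
    """Diagonal spatial frequency of a window (both diagonal directions)."""
    w = check_image(window, name="window", unit_range=False)
    m, n = w.shape
    d_main = w[1:, 1:] - w[:-1, :-1]
    d_anti = w[:-1, 1:] - w[1:, :-1]
    return float(np.sqrt((np.sum(d_main ** 2) + np.sum(d_anti ** 2)) / (m * n)))


def modified_spatial_frequency_map(image: np.ndarray,
                                   window_radius: int = 1) -> np.ndarray:
    """Per-pixel MSF evaluated on sliding windows with reflect padding.

    Equivalent to extracting the (2r+1) x (2r+1) neighborhood of every pixel
    and computing ``sqrt(SF^2 + DF^2)`` on it, but vectorized.
    """
    f = check_image(image, unit_range=False)
    r = int(window_radius)
    if r < 1:
        raise InvalidParameterError(f"window_radius must be >= 1, got {window_radius}")
    side = 2 * r + 1
    padded = np.pad(f, r, mode="symmetric")
    win = sliding_window_view(padded, (side, side))  # (M, N, side, side)
    mn = side * side

    def _winsum(diff: np.ndarray) -> np.ndarray:
        # Flatten the window axes before reducing so the summation order is
        # plain C order, identical to summing one extracted window.
        sq = np.ascontiguousarray(diff) ** 2
        return np.sum(sq.reshape(*sq.shape[:2], -1), axis=2)

    rf2 = _winsum(win[..., :, 1:] - win[..., :, :-1]) / mn
    cf2 = _winsum(win[..., 1:, :] - win[..., :-1, :]) / mn
    d_main = _winsum(win[..., 1:, 1:] - win[..., :-1, :-1])
    d_anti = _winsum(win[..., :-1, 1:] - win[..., 1:, :-1])
    sf = np.sqrt(rf2 + cf2)
    df = np.sqrt((d_main + d_anti) / mn)
    return np.sqrt(sf * sf + df * df)


def modified_local_contrast(msf_map: np.ndarray,
                            amf_map: np.ndarray) -> np.ndarray:
    """Elementwise MLC: MSF / AMF, with MSF passed through where AMF == 0.

    The zero branch uses exact floating-point equality: on normalized
    images a true zero background only arises in identically black regions.
    """
    msf = np.asarray(msf_map, dtype=np.float64)
    amf = np.asarray(amf_map, dtype=np.float64)
    check_same_shape(msf, amf, names=("msf", "amf"))
    if np.any(msf < 0):
        raise InvalidImageError("msf map must be nonnegative")
    nonzero = amf != 0.0
    return np.where(nonzero, msf / np.where(nonzero, amf, 1.0), msf)
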