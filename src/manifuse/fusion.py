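"""Pixel-selection fusion of two co-registered grayscale images.

Pipeline (sources x and y, assumed registered upstream):

1. filter both sources with the adaptive manifold filter -> low-frequency
   background maps AMF_x, AMF_y;
2. compute the modified-spatial-frequency maps MSF_x, MSF_y;
3. form modified local contrast MLC = MSF / AMF for each source;
4. decision map D = 1 where MLC_x >= MLC_y, else 0 (ties go to x);
5. merge: F = Ix * D + Iy * (1 - D).

Every fused pixel is a verbatim copy of one source pixel; there is no
blending, so source intensities (and their quantization) survive exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._validate import check_image, check_same_shape
from .amfilter import FilterParams, amf_filter
from .errors import InvalidImageError
from .saliency import (SaliencyMaps, modified_local_contrast,
                       modified_spatial_frequency_map)

__all__ = ["DecisionMap", "FusionResult", "decision_map", "merge", "fuse",
           "average_fusion"]


@dataclass(frozen=True)
class DecisionMap:
    """Binary per-pixel selector: 1 takes source x, 0 takes source y."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or not np.all((v == 0) | (v == 1)):
            raise InvalidImageError("decision map must be 2-D and binary (0/1)")
        object.__setattr__(self, "values", v.astype(np.uint8))


@dataclass(frozen=True)
class FusionResult:
    """Fused image plus all intermediates of the pipeline."""

    fused: np.ndarray
    decision: DecisionMap
    saliency_x: SaliencyMaps
    saliency_y: SaliencyMaps


def decision_map(mlc_x: np.ndarray, mlc_y: np.ndarray) -> DecisionMap:
    """Binary decision map; ties (equal contrast) select the first source."""
    a = np.asarray(mlc_x, dtype=np.float64)
    b = np.asarray(mlc_y, dtype=np.float64)
    check_same_shape(a, b, names=("mlc_x", "mlc_y"))
    return DecisionMap(values=(a >= b))


def merge(ix: np.ndarray, iy: np.ndarray, d: DecisionMap) -> np.ndarray:
    """Select per pixel: F = Ix where D == 1, Iy where D == 0."""
    x = check_image(ix, name="ix", unit_range=False)
    y = check_image(iy, name="iy", unit_range=False)
    check_same_shape(x, y, names=("ix", "iy"))
    check_same_shape(x, d.values, names=("ix", "decision map"))
    return np.where(d.values == 1, x, y)


def _majority_vote(d: np.ndarray, radius: int) -> np.ndarray:
    """Optional small-window majority smoothing of a binary decision map."""
    size = 2 * radius + 1
    votes = ndimage.uniform_filter(d.astype(np.float64), size=size,
                                   mode="reflect")
    return (votes >= 0.5).astype(np.uint8)


def fuse(ix: np.ndarray, iy: np.ndarray,
         filter_params: FilterParams | None = None,
         window_radius: int = 1,
         decision_smoothing_radius: int = 0) -> FusionResult:
    """Fuse two co-registered grayscale images by modified local contrast.

    Parameters
    ----------
    ix, iy : ndarray
        Equal-shape grayscale images with values in [0, 1].
    filter_params : FilterParams, optional
        Adaptive-manifold filter settings (default sigma_s=14, sigma_r=0.10).
    window_radius : int
        Sliding-window radius of the MSF saliency (default 1, i.e. 3x3).
    decision_smoothing_radius : int
        Off by default (0).  If > 0, applies a majority vote of that radius
        to the decision map before merging; an extension, not part of the
        raw per-pixel rule.

    Returns
    -------
    FusionResult
        Fused image, binary decision map and both saliency map sets.
    """
    x = check_image(ix, name="ix")
    y = check_image(iy, name="iy")
    check_same_shape(x, y, names=("ix", "iy"))
    params = filter_params if filter_params is not None else FilterParams()

    amf_x = amf_filter(x, params)
    amf_y = amf_filter(y, params)
    msf_x = modified_spatial_frequency_map(x, window_radius)
    msf_y = modified_spatial_frequency_map(y, window_radius)
    mlc_x = modified_local_contrast(msf_x, amf_x)
    mlc_y = modified_local_contrast(msf_y, amf_y)

    d = decision_map(mlc_x, mlc_y)
    if decision_smoothing_radius > 0:
        d = DecisionMap(_majority_vote(d.values, decision_smoothing_radius))
    fused = merge(x, y, d)
    return FusionResult(
        fused=fused,
        decision=d,
        saliency_x=SaliencyMaps(msf=msf_x, amf=amf_x, mlc=mlc_x),
        saliency_y=SaliencyMaps(msf=msf_y, amf=amf_y, mlc=mlc_y),
    )


def average_fusion(ix: np.ndarray, iy: np.ndarray) -> np.ndarray:
    """Trivial pixel-averaging baseline used for metric comparisons."""
    x = check_image(ix, name="ix")
    y = check_image(iy, name="iy")
    check_same_shape(x, y, names=("ix", "iy"))
    return 0.5 * (x + y)
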