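"""Edge-preserving adaptive-manifold filtering of grayscale images.

The adaptive-manifold filter approximates high-dimensional (bilateral-type)
Gaussian filtering of an image ``f`` over the joint space-range domain by
three steps repeated for a small set of nonlinear manifolds eta_k:

1. **projection** -- each pixel value is weighted by its Gaussian range
   distance to the manifold, ``w_ki = phi(eta_ki - f_i)``;
2. **blurring** -- the weighted values ``w*f`` and the weights ``w`` are
   low-pass filtered along the manifold with spatial standard deviation
   ``sigma_s``;
3. **gathering** -- the per-manifold blurred responses are combined into the
   final output as a weighted ratio, which makes the result a convex
   combination of input values and therefore range-bounded.

For a grayscale image the spatial domain is 2-D and the range is 1-D.  The
first manifold is a plain spatial low-pass of the image; further manifolds
are built recursively by splitting pixels on the sign of the residual
``f - eta`` and low-pass filtering each side's residual (the standard
adaptive-manifolds tree construction).

All Gaussian range kernels use the unnormalized form
``phi_sigma(x) = exp(-x**2 / (2 * sigma**2))``; the normalization constant
cancels in the gathering ratio.  The projection kernel uses half the range
variance (``sigma_r**2 / 2``), i.e. ``exp(-x**2 / sigma_r**2)``, because the
blur along the manifold contributes the other half of the range smoothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from ._validate import check_image, check_same_shape
from .errors import DegenerateWeightError, InvalidParameterError

__all__ = [
    "FilterParams",
    "Manifold",
    "ProjectedSignal",
    "compute_num_manifolds",
    "build_first_manifold",
    "project_onto_manifold",
    "blur_on_manifold",
    "gather",
    "segment_pixels",
    "amf_filter",
]

# Smallest admissible projection weight.  exp() underflows to exact zero for
# very distant manifolds; flooring keeps the gather denominator positive
# without measurably changing well-conditioned pixels.
_WEIGHT_FLOOR = np.finfo(np.float64).tiny


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the adaptive manifold filter.

    Attributes
    ----------
    sigma_s : float
        Spatial standard deviation in pixels.  Default 14.
    sigma_r : float
        Range standard deviation in normalized [0, 1] intensity units.
        Default 0.10.
    num_manifolds : int or "auto"
        Number of manifolds K; ``"auto"`` derives it from the two sigmas
        (always >= 4).
    """

    sigma_s: float = 14.0
    sigma_r: float = 0.10
    num_manifolds: Union[int, str] = "auto"

    def __post_init__(self) -> None:
        if not (self.sigma_s > 0):
            raise InvalidParameterError(f"sigma_s must be > 0, got {self.sigma_s}")
        if not (self.sigma_r > 0):
            raise InvalidParameterError(f"sigma_r must be > 0, got {self.sigma_r}")
        if self.num_manifolds != "auto":
            k = self.num_manifolds
            if not (isinstance(k, (int, np.integer)) and k >= 1):
                raise InvalidParameterError(
                    f"num_manifolds must be 'auto' or a positive integer, got {k!r}")


@dataclass(frozen=True)
class Manifold:
    """One adaptive manifold: a per-pixel range value eta_k plus tree depth."""

    eta: np.ndarray
    depth: int = 1

    def __post_init__(self) -> None:
        eta = np.asarray(self.eta, dtype=np.float64)
        if eta.ndim != 2 or not np.all(np.isfinite(eta)):
            raise InvalidParameterError("manifold eta must be a finite 2-D field")
        object.__setattr__(self, "eta", eta)


@dataclass(frozen=True)
class ProjectedSignal:
    """Gaussian range-weighted projection of an image onto a manifold.

    ``weighted_values`` is ``w * f`` and ``weights`` is ``w``; after
    :func:`blur_on_manifold` both fields hold the low-pass filtered versions.
    """

    weighted_values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        check_same_shape(self.weighted_values, self.weights,
                         names=("weighted_values", "weights"))
        if np.any(self.weights <= 0):
            raise InvalidParameterError("projection weights must be strictly positive")


def _lowpass(values: np.ndarray, sigma_s: float) -> np.ndarray:
    """Separable Gaussian low-pass with reflect (mirror) boundary, DC gain 1."""
    return ndimage.gaussian_filter(values, sigma=sigma_s, mode="reflect")


def _phi(x: np.ndarray, sigma: float) -> np.ndarray:
    """Unnormalized Gaussian kernel exp(-x^2 / (2 sigma^2))."""
    return np.exp(-(x * x) / (2.0 * sigma * sigma))


def compute_num_manifolds(params: FilterParams) -> int:
    """Number of manifolds K implied by the filter scales.

    ``K = 2 + max(2, ceil(H_S * L_R))`` with tree height
    ``H_S = max(1, ceil(log2(sigma_s)) - 1)`` and range correction
    ``L_R = 1 - sigma_r``.  K does not depend on the image dimensionality
    and is always at least 4.
    """
    if not (params.sigma_s > 0):
        raise InvalidParameterError("sigma_s must be > 0")
    if not (0 < params.sigma_r <= 1):
        raise InvalidParameterError(
            f"sigma_r must be in (0, 1] for manifold counting, got {params.sigma_r}")
    h_s = max(1, math.ceil(math.log2(params.sigma_s)) - 1)
    l_r = 1.0 - params.sigma_r
    return 2 + max(2, math.ceil(h_s * l_r))


def build_first_manifold(image: np.ndarray, sigma_s: float) -> Manifold:
    """First manifold eta_1: spatial low-pass of the image itself."""
    f = check_image(image, unit_range=False)
    if not (sigma_s > 0):
        raise InvalidParameterError("sigma_s must be > 0")
    return Manifold(eta=_lowpass(f, sigma_s), depth=1)


def project_onto_manifold(image: np.ndarray, manifold: Manifold,
                          sigma_r: float) -> ProjectedSignal:
    """Project pixel values onto a manifold with Gaussian range weights.

    The weight of pixel i is ``phi_{sigma_r/sqrt(2)}(eta_ki - f_i)``,
    i.e. ``exp(-(eta_ki - f_i)^2 / sigma_r^2)``.
    """
    f = check_image(image, unit_range=False)
    check_same_shape(f, manifold.eta, names=("image", "manifold"))
    if not (sigma_r > 0):
        raise InvalidParameterError("sigma_r must be > 0")
    w = _phi(manifold.eta - f, sigma_r / math.sqrt(2.0))
    w = np.maximum(w, _WEIGHT_FLOOR)
    return ProjectedSignal(weighted_values=w * f, weights=w)


def blur_on_manifold(projected: ProjectedSignal, manifold: Manifold,
                     sigma_s: float, sigma_r: float) -> ProjectedSignal:
    """Low-pass filter a projected signal along its manifold.

    Conceptually this is Gaussian filtering over the joint space of pixel
    position and manifold value with covariance diag(sigma_s^2 I, sigma_r^2).
    Because each manifold is itself a low-pass field, its range value varies
    slowly within the spatial kernel support, so the blur is computed as a
    plain spatial Gaussian (sigma_s, reflect boundary, DC gain 1) applied to
    both the weighted values and the weights.
    """
    if not (sigma_s > 0 and sigma_r > 0):
        raise InvalidParameterError("sigma_s and sigma_r must be > 0")
    values = _lowpass(projected.weighted_values, sigma_s)
    weights = np.maximum(_lowpass(projected.weights, sigma_s), _WEIGHT_FLOOR)
    return ProjectedSignal(weighted_values=values, weights=weights)


def gather(blurred_list: Sequence[ProjectedSignal],
           weight_list: Sequence[np.ndarray]) -> np.ndarray:
    """Combine per-manifold blurred responses into the final filter output.

    ``g_i = sum_k w_ki * Psi2_k.values_i / sum_k w_ki * Psi2_k.weights_i``.

    Raises
    ------
    DegenerateWeightError
        If the denominator is exactly zero at any pixel (would produce NaN).
    """
    if len(blurred_list) == 0 or len(blurred_list) != len(weight_list):
        raise InvalidParameterError(
            "need >= 1 manifold and matching blurred/weight list lengths")
    num = np.zeros_like(blurred_list[0].weighted_values)
    den = np.zeros_like(num)
    for psi2, w in zip(blurred_list, weight_list):
        w = np.asarray(w, dtype=np.float64)
        check_same_shape(num, w, names=("signal", "gather weights"))
        check_same_shape(num, psi2.weighted_values,
                         names=("signal", "blurred signal"))
        num += w * psi2.weighted_values
        den += w * psi2.weights
    if np.any(den == 0.0):
        raise DegenerateWeightError(
            "total gather weight is zero at "
            f"{int(np.count_nonzero(den == 0.0))} pixel(s)")
    return num / den


def segment_pixels(image: np.ndarray, manifold: Manifold
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Partition the pixel grid by the sign of the residual ``f - eta``.

    Returns ``(above, below)`` boolean masks with ``above = (f - eta >= 0)``;
    the masks are disjoint and cover the full grid.
    """
    f = check_image(image, unit_range=False)
    check_same_shape(f, manifold.eta, names=("image", "manifold"))
    above = (f - manifold.eta) >= 0.0
    return above, ~above


def _child_manifold(f: np.ndarray, parent: Manifold, mask: np.ndarray,
                    sigma_s: float) -> Manifold:
    """Build one child manifold from the residual restricted to ``mask``.

    The child is the parent plus a normalized masked low-pass of the
    residual; an empty mask degenerates to a copy of the parent.
    """
    if not mask.any():
        return Manifold(eta=parent.eta.copy(), depth=parent.depth + 1)
    residual = f - parent.eta
    theta = mask.astype(np.float64)
    lp_res = _lowpass(theta * residual, sigma_s)
    lp_mask = _lowpass(theta, sigma_s)
    correction = np.where(lp_mask > 1e-12, lp_res / np.maximum(lp_mask, 1e-12), 0.0)
    return Manifold(eta=parent.eta + correction, depth=parent.depth + 1)


def build_manifold_tree(image: np.ndarray, sigma_s: float, k: int
                        ) -> List[Manifold]:
    """Build K manifolds breadth-first: eta_1, then residual-sign children."""
    f = check_image(image, unit_range=False)
    root = build_first_manifold(f, sigma_s)
    manifolds: List[Manifold] = [root]
    queue: List[Manifold] = [root]
    while len(manifolds) < k:
        parent = queue.pop(0)
        above, below = segment_pixels(f, parent)
        for mask in (above, below):
            if len(manifolds) >= k:
                break
            child = _child_manifold(f, parent, mask, sigma_s)
            manifolds.append(child)
            queue.append(child)
    return manifolds


def amf_filter(image: np.ndarray, params: FilterParams) -> np.ndarray:
    """Adaptive-manifold edge-preserving filter of a normalized image.

    Parameters
    ----------
    image : ndarray
        2-D grayscale image with values in [0, 1].
    params : FilterParams
        Spatial/range standard deviations and manifold count.

    Returns
    -------
    ndarray
        Filtered image, same shape, values in [0, 1].  Deterministic.
    """
    f = check_image(image)
    if params.num_manifolds == "auto":
        # K's formula needs sigma_r <= 1; very large sigma_r (the pure
        # Gaussian-blur limit) clamps to the K of sigma_r = 1.
        k = compute_num_manifolds(
            FilterParams(params.sigma_s, min(params.sigma_r, 1.0), "auto"))
    else:
        k = int(params.num_manifolds)

    manifolds = build_manifold_tree(f, params.sigma_s, k)
    blurred: List[ProjectedSignal] = []
    omegas: List[np.ndarray] = []
    for m in manifolds:
        proj = project_onto_manifold(f, m, params.sigma_r)
        blurred.append(blur_on_manifold(proj, m, params.sigma_s, params.sigma_r))
        omegas.append(proj.weights)

    try:
        g = gather(blurred, omegas)
    except DegenerateWeightError:
        # Fall back to the first-manifold response at degenerate pixels.
        num = sum(w * b.weighted_values for w, b in zip(omegas, blurred))
        den = sum(w * b.weights for w, b in zip(omegas, blurred))
        eta1 = manifolds[0].eta
        g = np.where(den > 0, num / np.where(den > 0, den, 1.0), eta1)

    # The gather ratio is a convex combination of input values; clip only the
    # last few ulps of rounding noise.
    return np.clip(g, 0.0, 1.0)
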