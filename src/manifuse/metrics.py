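"""Objective fusion-quality metrics: mutual information and Q^AB/F.

**Mutual information.**  For source t and fused image F quantized into L
gray levels, with joint normalized histogram h_tF and marginals h_t, h_F:

    MI(t;F) = sum_uv h_tF(u,v) * log2( h_tF(u,v) / (h_t(u) h_F(v)) )

The fusion score is the sum over both sources, MI = MI(x;F) + MI(y;F);
larger means the fused image retains more source information.

**Edge-based similarity Q^AB/F** (Xydeas-Petrovic).  Sobel gradients give
per-pixel edge strength g and orientation alpha for each source and for F.
Relative strength G and relative orientation A in [0, 1] are mapped through
sigmoids to preservation scores

    Q_g = Gamma_g / (1 + exp(kappa_g * (G - sigma_g)))
    Q_a = Gamma_a / (1 + exp(kappa_a * (A - sigma_a)))

and Q^xF = Q_g * Q_a.  Q^AB/F is the edge-strength-weighted average of
Q^xF and Q^yF over all pixels and lies in [0, 1].  Note that with the
standard sigmoid constants the score of a *perfect* fusion (F identical to
both sources) is the sigmoid ceiling Q_g(1) * Q_a(1), about 0.975, not 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._validate import check_image, check_same_shape
from .errors import InvalidParameterError

__all__ = [
    "MetricConfig",
    "joint_histogram",
    "mutual_information",
    "fusion_mutual_information",
    "edge_similarity",
    "edge_similarity_ceiling",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricConfig:
    """Histogram bin count and Q^AB/F sigmoid constants.

    The sigmoid constants default to the reference values of the
    Xydeas-Petrovic edge-preservation metric; they are exposed here so the
    metric is auditable rather than hard-coded.
    """

    bins: int = 256
    gamma_g: float = 0.9994
    kappa_g: float = -15.0
    sigma_g: float = 0.5
    gamma_a: float = 0.9879
    kappa_a: float = -22.0
    sigma_a: float = 0.8
    edge_weight_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise InvalidParameterError(f"bins must be >= 2, got {self.bins}")
        for name in ("gamma_g", "gamma_a"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise InvalidParameterError(f"{name} must be in (0, 1], got {v}")
        for name in ("sigma_g", "sigma_a"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise InvalidParameterError(f"{name} must be in (0, 1), got {v}")


def joint_histogram(t: np.ndarray, f: np.ndarray,
                    bins: int = 256) -> np.ndarray:
    """Normalized L x L joint gray-level histogram of two [0, 1] images."""
    a = check_image(t, name="t")
    b = check_image(f, name="f")
    check_same_shape(a, b, names=("t", "f"))
    counts, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins,
                                  range=[[0.0, 1.0], [0.0, 1.0]])
    return counts / counts.sum()


def mutual_information(t: np.ndarray, f: np.ndarray,
                       config: MetricConfig | None = None) -> float:
    """Mutual information in bits between two images' gray levels (>= 0)."""
    cfg = config or MetricConfig()
    h = joint_histogram(t, f, cfg.bins)
    ht = h.sum(axis=1)
    hf = h.sum(axis=0)
    nz = h > 0
    outer = ht[:, None] * hf[None, :]
    mi = float(np.sum(h[nz] * np.log2(h[nz] / outer[nz])))
    return max(mi, 0.0)


def fusion_mutual_information(x: np.ndarray, y: np.ndarray, f: np.ndarray,
                              config: MetricConfig | None = None) -> float:
    """MI fusion score: MI(x;F) + MI(y;F)."""
    return mutual_information(x, f, config) + mutual_information(y, f, config)


def _sobel_strength_orientation(img: np.ndarray):
    """Per-pixel Sobel edge strength and orientation in [-pi/2, pi/2]."""
    sx = ndimage.sobel(img, axis=1, mode="reflect")
    sy = ndimage.sobel(img, axis=0, mode="reflect")
    g = np.hypot(sx, sy)
    alpha = np.arctan2(sy, sx)
    # Fold to the atan(sy/sx) convention: orientation, not direction.
    alpha = np.where(alpha > math.pi / 2, alpha - math.pi, alpha)
    alpha = np.where(alpha < -math.pi / 2, alpha + math.pi, alpha)
    return g, alpha


def _edge_preservation(g_s, a_s, g_f, a_f, cfg: MetricConfig) -> np.ndarray:
    """Per-pixel Q^sF for one source s against the fused image."""
    both_zero = (g_s == 0) & (g_f == 0)
    g_max = np.maximum(g_s, g_f)
    g_min = np.minimum(g_s, g_f)
    # Relative edge strength in [0, 1]; 0 where one side has an edge and the
    # other has none.
    rel_g = np.where(g_max > 0, g_min / np.where(g_max > 0, g_max, 1.0), 0.0)
    rel_a = 1.0 - np.abs(a_s - a_f) / (math.pi / 2.0)
    q_g = cfg.gamma_g / (1.0 + np.exp(cfg.kappa_g * (rel_g - cfg.sigma_g)))
    q_a = cfg.gamma_a / (1.0 + np.exp(cfg.kappa_a * (rel_a - cfg.sigma_a)))
    q = q_g * q_a
    # Flat-on-flat pixels carry no edge information to lose.
    return np.where(both_zero, edge_similarity_ceiling(cfg), q)


def edge_similarity_ceiling(config: MetricConfig | None = None) -> float:
    """Q^xF at perfect preservation (G = 1, A = 1) for the given constants."""
    cfg = config or MetricConfig()
    q_g = cfg.gamma_g / (1.0 + math.exp(cfg.kappa_g * (1.0 - cfg.sigma_g)))
    q_a = cfg.gamma_a / (1.0 + math.exp(cfg.kappa_a * (1.0 - cfg.sigma_a)))
    return q_g * q_a


def edge_similarity(x: np.ndarray, y: np.ndarray, f: np.ndarray,
                    config: MetricConfig | None = None) -> float:
    """Q^AB/F: edge-strength-weighted preservation score in [0, 1].

    If both sources are perfectly flat (all weights zero) there are no
    edges to transfer and the score is 1 by convention (logged).
    """
    cfg = config or MetricConfig()
    a = check_image(x, name="x")
    b = check_image(y, name="y")
    c = check_image(f, name="f")
    check_same_shape(a, b, names=("x", "y"))
    check_same_shape(a, c, names=("x", "f"))

    g_x, a_x = _sobel_strength_orientation(a)
    g_y, a_y = _sobel_strength_orientation(b)
    g_f, a_f = _sobel_strength_orientation(c)

    q_xf = _edge_preservation(g_x, a_x, g_f, a_f, cfg)
    q_yf = _edge_preservation(g_y, a_y, g_f, a_f, cfg)
    w_x = g_x ** cfg.edge_weight_exponent
    w_y = g_y ** cfg.edge_weight_exponent

    denom = float(np.sum(w_x) + np.sum(w_y))
    if denom == 0.0:
        logger.warning("edge_similarity: both sources are flat; returning 1.0")
        return 1.0
    score = float(np.sum(q_xf * w_x + q_yf * w_y) / denom)
    return float(np.clip(score, 0.0, 1.0))
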