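"""Independent brute-force oracles used by the test suite.

Everything here is deliberately slow and written with explicit loops or
dense O(n^2) sums, sharing no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np


def gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Truncated, normalized 1-D Gaussian (radius int(truncate*sigma+0.5))."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-(x * x) / (2.0 * sigma * sigma))
    return k / k.sum()


def gaussian_blur_bruteforce(img: np.ndarray, sigma: float,
                             truncate: float = 4.0) -> np.ndarray:
    """Direct separable Gaussian convolution with reflect (mirror) boundary."""
    k = gaussian_kernel_1d(sigma, truncate)
    r = (len(k) - 1) // 2
    padded = np.pad(img, r, mode="symmetric")
    m, n = img.shape
    tmp = np.empty((m + 2 * r, n), dtype=np.float64)
    for i in range(m + 2 * r):
        for j in range(n):
            tmp[i, j] = np.dot(padded[i, j:j + 2 * r + 1], k)
    out = np.empty((m, n), dtype=np.float64)
    for i in range(m):
        for j in range(n):
            out[i, j] = np.dot(tmp[i:i + 2 * r + 1, j], k)
    return out


def joint_space_blur_bruteforce(values, weights, eta, sigma_s, sigma_r,
                                truncate: float = 4.0):
    """Dense Gaussian-weighted sum over all pixel pairs in the
    (position, manifold-value) joint space, normalized to DC gain 1.

    The domain is reflect-extended so boundary handling matches a
    mirror-padded convolution.
    """
    r = int(truncate * sigma_s + 0.5)
    pv = np.pad(values, r, mode="symmetric")
    pw = np.pad(weights, r, mode="symmetric")
    pe = np.pad(eta, r, mode="symmetric")
    mp, np_ = pv.shape
    ii, jj = np.mgrid[0:mp, 0:np_].astype(np.float64)
    pos = np.stack([ii.ravel(), jj.ravel()], axis=1)
    ev = pe.ravel()
    m, n = values.shape
    out_v = np.empty((m, n))
    out_w = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            pi, pj = i + r, j + r
            d2 = (pos[:, 0] - pi) ** 2 + (pos[:, 1] - pj) ** 2
            de = ev - pe[pi, pj]
            k = np.exp(-d2 / (2 * sigma_s ** 2) - de ** 2 / (2 * sigma_r ** 2))
            k /= k.sum()
            out_v[i, j] = np.dot(k, pv.ravel())
            out_w[i, j] = np.dot(k, pw.ravel())
    return out_v, out_w


def bilateral_bruteforce(img: np.ndarray, sigma_s: float,
                         sigma_r: float) -> np.ndarray:
    """Dense normalized joint bilateral (space-range Gaussian) filter."""
    m, n = img.shape
    ii, jj = np.mgrid[0:m, 0:n].astype(np.float64)
    pos_i, pos_j, vals = ii.ravel(), jj.ravel(), img.ravel()
    out = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            d2 = (pos_i - i) ** 2 + (pos_j - j) ** 2
            dr = vals - img[i, j]
            k = np.exp(-d2 / (2 * sigma_s ** 2) - dr ** 2 / (2 * sigma_r ** 2))
            out[i, j] = np.dot(k, vals) / k.sum()
    return out


def msf_map_bruteforce(img: np.ndarray, radius: int,
                       sf_fn, df_fn) -> np.ndarray:
    """Per-pixel MSF by explicit window extraction and scalar SF/DF calls."""
    padded = np.pad(img, radius, mode="symmetric")
    m, n = img.shape
    side = 2 * radius + 1
    out = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            w = padded[i:i + side, j:j + side]
            sf, df = sf_fn(w), df_fn(w)
            out[i, j] = np.sqrt(sf * sf + df * df)
    return out


def entropy_bits(img: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of an image's normalized gray-level histogram."""
    counts, _ = np.histogram(img.ravel(), bins=bins, range=(0.0, 1.0))
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))
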