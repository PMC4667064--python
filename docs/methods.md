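# Methods

## Problem and model

Co-registered multimodal medical images (CT/MRI, T1/T2-weighted MRI,
MRI/MRA, ...) carry complementary content: bone and calcification dominate
one modality, soft-tissue detail the other. `manifuse` fuses two such
grayscale images in the spatial domain by selecting, at every pixel, the
source with the larger *modified local contrast*

    MLC(i,j) = MSF(i,j) / AMF(i,j)     (AMF(i,j) != 0)
             = MSF(i,j)                (AMF(i,j) == 0)

where MSF is the modified spatial frequency (a sliding-window RMS of first
differences along rows, columns and both diagonals — the high-frequency
activity) and AMF is the adaptive-manifold edge-preserving filter response
(the local background brightness — the low-frequency term). The decision
map is `D = 1` where `MLC_x >= MLC_y` (ties to the first input) and the
fused image is `F = Ix*D + Iy*(1-D)`. Selection, never blending: every
fused pixel is a verbatim copy of a source pixel, so source quantization
round-trips losslessly through 8-/16-bit I/O.

Assumptions: inputs are single-channel, co-registered, equal-size, and
normalized to [0, 1] (8-/16-bit rasters are divided by their full-scale
value). Registration is upstream of this package.

## Adaptive manifold filter

The filter approximates space–range (bilateral-type) Gaussian filtering by
projecting the image onto K nonlinear manifolds, blurring along each, and
gathering:

1. manifold count: `K = 2 + max(2, ceil(H_S * L_R))`, with
   `H_S = max(1, ceil(log2(sigma_s)) - 1)` (tree height from the spatial
   scale) and `L_R = 1 - sigma_r` (range correction). At the default
   operating point (sigma_s = 14, sigma_r = 0.10), K = 5. K is independent
   of image dimensionality and never below 4.
2. first manifold: `eta_1 = h_{sigma_s} * f`, a separable Gaussian low-pass
   with reflect (mirror) boundary. Child manifolds are built breadth-first:
   pixels are split by the sign of the residual `f - eta_k`, and each
   side's residual is low-pass filtered (normalized by the blurred mask)
   and added to the parent; an empty side degenerates to a copy of the
   parent. The same sigma_s is used at every tree level.
3. projection: `w_ki = exp(-(eta_ki - f_i)^2 / sigma_r^2)` — a Gaussian
   with covariance `sigma_r^2 / 2`, i.e. half the range variance, because
   the blur along the manifold contributes the other half. Kernels are
   unnormalized; the constant cancels in the gather ratio. Weights are
   floored at the smallest positive double so the denominator below can
   never be exactly zero through underflow.
4. blurring: `w*f` and `w` are filtered with the spatial Gaussian along
   the manifold. Since every manifold is itself a low-pass field, its
   range value varies slowly inside the kernel support and a plain spatial
   blur tracks the full joint space–range Gaussian closely (verified in
   the tests against a dense O(n^2) joint-space oracle at 5e-3 MAE, and
   end-to-end against a dense bilateral filter at 5e-2 MAE on 16x16
   fields).
5. gathering: `g_i = sum_k w_ki Psi2_k(w f) / sum_k w_ki Psi2_k(w)`.
   Because this is a convex combination of input values, the output is
   range-bounded by construction; if a caller hands `gather` all-zero
   weights it raises rather than emitting NaN, and the full filter falls
   back to the first-manifold response at any degenerate pixel.

`amf_filter` accepts sigma_r > 1 (the limit in which it collapses to the
plain spatial Gaussian blur — a useful correctness check); for "auto"
manifold counting sigma_r is clamped to 1 inside the K formula, whose
derivation assumes a unit range.

## Saliency

MSF is evaluated per pixel on a (2r+1)x(2r+1) sliding window (default
r = 1, the smallest window supporting all four difference directions),
with reflect padding so the map keeps the image shape without biasing
border saliency toward zero. Each difference term is summed over exactly
its valid index range and normalized by the window area. The global
formulas are thus read as per-pixel statistics, which the per-pixel
decision map requires; the window radius is exposed in the configuration.

The MLC zero branch uses exact floating-point equality: on normalized
images a true zero background arises only in identically black regions,
where passing MSF through unchanged is the intended behavior.

## Metrics

**Mutual information.** `MI = MI(x;F) + MI(y;F)` from 256-bin joint
gray-level histograms (matching 8-bit sources), log base 2, zero-mass
terms contributing zero. Note the estimator's finite-sample bias: two
*independent* 256x256 images score ~0.8 bits at 256 bins, which is the
floor against which fused-image MI values should be read.

**Edge similarity (Q^AB/F).** Sobel 3x3 gradients give per-pixel edge
strength g and orientation alpha (folded to [-pi/2, pi/2]). Relative
strength `G = min(g_s, g_F) / max(g_s, g_F)` and relative orientation
`A = 1 - |alpha_s - alpha_F| / (pi/2)` pass through sigmoids

    Q_g = 0.9994 / (1 + exp(-15  (G - 0.5)))
    Q_a = 0.9879 / (1 + exp(-22  (A - 0.8)))

and `Q^sF = Q_g * Q_a`; the final score is the g-weighted average
(weight exponent 1) over both sources, clipped to [0, 1]. The sigmoid
constants are the reference values in common use and are exposed in
`MetricConfig` rather than hard-coded. Two conventions resolve 0/0
ambiguities deterministically: where source and fused gradients are both
zero, Q is set to the preservation ceiling (nothing to lose); where both
*sources* are entirely flat the score is 1 by convention (logged).
With these constants even a perfect fusion (F identical to both sources)
scores the sigmoid ceiling `Q_g(1) * Q_a(1) = 0.9748`, not 1.0 — a
property of the standard constants, asserted in the tests.

## Synthetic phantoms

`generate_phantom_pair` emulates the contract of a co-registered CT/MRI
pair on known geometry: a bright ring plus blobs with fine internal
texture in modality A (bone-like), an oriented sinusoidal patch with
sharp boundary edges in modality B (soft-tissue-like), a faint smooth
shared "anatomy" bump in both (so the sources are statistically
dependent), and independent additive Gaussian noise. Defaults: 256x256
(a typical clinical slice raster), noise sigma 0.01.

The ground-truth masks mark where each modality carries structure; fine
seeded texture inside the masks guarantees the structured modality
dominates local variance (>= 4x) everywhere in its mask, so the masks are
a valid reference for the decision map. What the phantom does *not*
emulate: realistic anatomy, modality-specific noise statistics (Rician
MRI noise, CT streaking), partial-volume effects, or registration error.
Passing the phantom tests shows the pipeline selects the structured
source where structure exists and preserves it verbatim; it does not
certify clinical image quality.

## Numerical choices

- Gaussian low-pass: `scipy.ndimage.gaussian_filter`, reflect boundary,
  default truncation (4 sigma). Reflect avoids edge darkening and
  preserves the image mean exactly for symmetric kernels.
- Decision ties select the first input; the decision map is applied raw
  (no consistency smoothing), with an optional off-by-default majority
  vote exposed as an extension.
- MSF window sums flatten the window axes before reducing so the
  summation order matches a per-window scalar computation bit for bit;
  the final composition uses explicit multiplication (`x*x`, not `x**2`)
  because libm `pow` is not always correctly rounded.
- Intensity normalization maps native bit depth to [0, 1]; sigma_r = 0.10
  is meaningful only on this unit range. Writing back rounds to the
  original depth, which is lossless for values that originated there.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `sigma_s` | 14 | px | spatial support of the background estimate |
| `sigma_r` | 0.10 | normalized intensity | edge-stopping range scale |
| `num_manifolds` | auto (K = 5 at defaults) | — | space–range approximation order |
| `msf_window_radius` | 1 | px | saliency locality (3x3 window) |
| `bins` | 256 | — | MI histogram resolution (8-bit sources) |

## Known limitations

- Two sources only; no color/pseudo-color (PET) fusion.
- The raw per-pixel decision map can produce isolated-pixel switching in
  regions where both saliencies are comparable; the optional majority
  vote trades fidelity to the selection rule for spatial consistency.
- The MI estimator is biased upward at small sample/bin ratios; compare
  values only at fixed image size and bin count.
- Problem sizes in the test suite and acceptance script (10 pairs at
  256x256) were chosen as the package's own validation scale; larger
  rasters run fine but are not exercised by default.
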