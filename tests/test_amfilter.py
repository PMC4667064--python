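"""Adaptive-manifold filter: unit, oracle and property tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage

from manifuse.amfilter import (FilterParams, Manifold, ProjectedSignal,
                               amf_filter, blur_on_manifold,
                               build_first_manifold, build_manifold_tree,
                               compute_num_manifolds, gather,
                               project_onto_manifold, segment_pixels)
from manifuse.errors import (DegenerateWeightError, InvalidParameterError,
                             ShapeMismatchError)

from _oracles import (bilateral_bruteforce, gaussian_blur_bruteforce,
                      joint_space_blur_bruteforce)

unit_images = hnp.arrays(
    np.float64, hnp.array_shapes(min_dims=2, max_dims=2, min_side=4, max_side=8),
    elements=st.floats(0.0, 1.0, allow_nan=False))


class TestNumManifolds:
    @pytest.mark.parametrize("sigma_s, sigma_r, expected", [
        (2.0, 0.5, 4),     # H_S*L_R <= 2, the max clamps: K = 2 + 2
        (14.0, 0.10, 5),   # H_S=3, L_R=0.9, ceil(2.7)=3 -> K=5
        (1.0, 1.0, 4),
        (100.0, 0.05, 2 + math.ceil(6 * 0.95)),
    ])
    def test_examples(self, sigma_s, sigma_r, expected):
        assert compute_num_manifolds(FilterParams(sigma_s, sigma_r)) == expected

    @given(st.floats(0.01, 200), st.floats(0.001, 1.0))
    @settings(derandomize=True, max_examples=50)
    def test_lower_bound(self, sigma_s, sigma_r):
        assert compute_num_manifolds(FilterParams(sigma_s, sigma_r)) >= 4

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            FilterParams(sigma_s=-1.0)
        with pytest.raises(InvalidParameterError):
            FilterParams(sigma_r=0.0)
        with pytest.raises(InvalidParameterError):
            compute_num_manifolds(FilterParams(14.0, 1.5))
        with pytest.raises(InvalidParameterError):
            FilterParams(num_manifolds=0)


class TestFirstManifold:
    def test_constant_image(self):
        m = build_first_manifold(np.full((8, 8), 0.42), sigma_s=3.0)
        np.testing.assert_allclose(m.eta, 0.42, atol=1e-12)

    def test_mean_preserved(self, random_image):
        m = build_first_manifold(random_image, sigma_s=2.0)
        assert abs(m.eta.mean() - random_image.mean()) < 1e-6

    def test_matches_direct_convolution(self, rng):
        img = rng.random((32, 32))
        m = build_first_manifold(img, sigma_s=4.0)
        ref = gaussian_blur_bruteforce(img, 4.0)
        assert np.abs(m.eta - ref).max() < 1e-6

    def test_range_bounded(self, random_image):
        m = build_first_manifold(random_image, sigma_s=5.0)
        assert m.eta.min() >= random_image.min() - 1e-9
        assert m.eta.max() <= random_image.max() + 1e-9


class TestProjection:
    def test_zero_range_distance_gives_peak_weights(self, random_image):
        m = Manifold(eta=random_image.copy())
        proj = project_onto_manifold(random_image, m, sigma_r=0.1)
        np.testing.assert_allclose(proj.weights, 1.0)
        np.testing.assert_allclose(proj.weighted_values, random_image)

    def test_large_distance_small_sigma_kills_weights(self):
        img = np.zeros((4, 4))
        m = Manifold(eta=np.ones((4, 4)))
        proj = project_onto_manifold(img, m, sigma_r=0.01)
        assert proj.weights.max() < 1e-300  # floored at tiny, never zero
        assert proj.weights.min() > 0

    def test_scalar_gaussian_evaluation(self):
        # w = exp(-(eta-f)^2 / sigma_r^2): covariance Sigma_R/2 convention
        img = np.full((2, 2), 0.5)
        m = Manifold(eta=np.full((2, 2), 0.3))
        proj = project_onto_manifold(img, m, sigma_r=0.2)
        np.testing.assert_allclose(proj.weights, math.exp(-1.0), rtol=1e-12)

    def test_shape_mismatch(self, random_image):
        with pytest.raises(ShapeMismatchError):
            project_onto_manifold(random_image, Manifold(np.zeros((4, 4))), 0.1)


class TestBlurOnManifold:
    def test_constant_signal_unchanged(self):
        proj = ProjectedSignal(np.full((8, 8), 0.2), np.full((8, 8), 0.5))
        out = blur_on_manifold(proj, Manifold(np.full((8, 8), 0.4)), 2.0, 0.1)
        np.testing.assert_allclose(out.weighted_values, 0.2, atol=1e-12)
        np.testing.assert_allclose(out.weights, 0.5, atol=1e-12)

    def test_weight_sum_conserved(self, rng):
        w = 0.1 + 0.9 * rng.random((12, 12))
        proj = ProjectedSignal(w * rng.random((12, 12)), w)
        out = blur_on_manifold(proj, Manifold(rng.random((12, 12))), 2.0, 0.2)
        assert abs(out.weights.sum() - w.sum()) < 1e-6

    def test_matches_joint_space_bruteforce(self, smooth_image):
        """Spatial blur along a smooth manifold tracks the dense
        (position, manifold-value) joint-space Gaussian filter."""
        sigma_s, sigma_r = 2.0, 0.2
        m = build_first_manifold(smooth_image, sigma_s)
        proj = project_onto_manifold(smooth_image, m, sigma_r)
        out = blur_on_manifold(proj, m, sigma_s, sigma_r)
        ref_v, ref_w = joint_space_blur_bruteforce(
            proj.weighted_values, proj.weights, m.eta, sigma_s, sigma_r)
        assert np.abs(out.weighted_values - ref_v).mean() < 5e-3
        assert np.abs(out.weights - ref_w).mean() < 5e-3


class TestGather:
    def test_single_manifold_constant_ratio(self):
        w = np.full((6, 6), 0.3)
        psi2 = ProjectedSignal(w * 0.7, w)
        out = gather([psi2], [w])
        np.testing.assert_allclose(out, 0.7, rtol=1e-12)

    def test_identical_manifolds_idempotent(self, rng):
        w = 0.2 + 0.8 * rng.random((8, 8))
        psi2 = ProjectedSignal(w * rng.random((8, 8)), w)
        one = gather([psi2], [w])
        two = gather([psi2, psi2], [w, w])
        np.testing.assert_allclose(one, two, rtol=1e-12)

    def test_matches_scalar_loop_oracle(self, rng):
        blurred, omegas = [], []
        for _ in range(2):
            w = 0.1 + 0.9 * rng.random((8, 8))
            blurred.append(ProjectedSignal(rng.random((8, 8)), w))
            omegas.append(0.1 + 0.9 * rng.random((8, 8)))
        out = gather(blurred, omegas)
        for i in range(8):
            for j in range(8):
                num = sum(o[i, j] * b.weighted_values[i, j]
                          for o, b in zip(omegas, blurred))
                den = sum(o[i, j] * b.weights[i, j]
                          for o, b in zip(omegas, blurred))
                assert out[i, j] == pytest.approx(num / den, rel=1e-12)

    def test_zero_total_weight_raises(self):
        w = np.full((4, 4), 0.5)
        psi2 = ProjectedSignal(w * 0.1, w)
        with pytest.raises(DegenerateWeightError):
            gather([psi2], [np.zeros((4, 4))])


class TestSegmentPixels:
    def test_degenerate_split_image_equals_manifold(self, random_image):
        above, below = segment_pixels(random_image, Manifold(random_image.copy()))
        assert above.all() and not below.any()

    def test_all_above(self, random_image):
        m = Manifold(random_image - 0.5)
        above, below = segment_pixels(random_image + 0.0, m)
        assert above.all()

    def test_checkerboard_residual(self):
        eta = np.full((8, 8), 0.5)
        ii, jj = np.mgrid[0:8, 0:8]
        phase = (ii + jj) % 2 == 0
        img = np.where(phase, 0.7, 0.3)
        above, below = segment_pixels(img, Manifold(eta))
        assert np.array_equal(above, phase)
        assert np.array_equal(below, ~phase)

    def test_masks_partition_grid(self, random_image, rng):
        m = Manifold(rng.random((16, 16)))
        above, below = segment_pixels(random_image, m)
        assert np.array_equal(above | below, np.ones((16, 16), bool))
        assert not np.any(above & below)

    def test_empty_side_child_falls_back_to_parent(self):
        img = np.full((8, 8), 0.5)
        tree = build_manifold_tree(img, sigma_s=2.0, k=4)
        for m in tree[1:]:
            np.testing.assert_allclose(m.eta, tree[0].eta, atol=1e-12)


class TestAmfFilter:
    def test_constant_idempotence(self):
        img = np.full((16, 16), 0.37)
        out = amf_filter(img, FilterParams())
        assert np.abs(out - 0.37).max() <= 1e-9

    def test_gaussian_limit(self, rng):
        """With huge sigma_r the range term is inert and the filter collapses
        to the plain spatial Gaussian blur."""
        img = rng.random((32, 32))
        out = amf_filter(img, FilterParams(4.0, 10.0))
        ref = gaussian_blur_bruteforce(img, 4.0)
        assert np.abs(out - ref).mean() < 1e-2

    def test_step_edge_preserved(self):
        img = np.zeros((48, 128))
        img[:, 64:] = 1.0
        out = amf_filter(img, FilterParams(14.0, 0.10))
        # pixels >= 3 sigma_s from the edge keep their value
        assert np.abs(out[:, :22]).max() < 0.05
        assert np.abs(out[:, 106:] - 1.0).max() < 0.05

    def test_deterministic(self, random_image):
        p = FilterParams(3.0, 0.15)
        a = amf_filter(random_image, p)
        b = amf_filter(random_image, p)
        assert np.array_equal(a, b)

    def test_full_pipeline_tracks_bilateral_oracle(self, smooth_image):
        """On tiny images the manifold approximation stays close to the
        dense space-range Gaussian (bilateral) filter it approximates."""
        out = amf_filter(smooth_image, FilterParams(3.0, 0.3))
        ref = bilateral_bruteforce(smooth_image, 3.0, 0.3)
        assert np.abs(out - ref).mean() < 5e-2

    @given(unit_images)
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_range_bounded(self, img):
        out = amf_filter(img, FilterParams(2.0, 0.2))
        assert out.min() >= img.min() - 1e-6
        assert out.max() <= img.max() + 1e-6
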