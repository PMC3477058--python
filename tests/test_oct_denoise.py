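"""Oracles for the OCT smoothing chain and the anisotropic diffusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage

import retscreen as rs
from retscreen import oct_denoise as od


def brute_gaussian(img: np.ndarray, kern: np.ndarray) -> np.ndarray:
    """Direct-summation convolution with scipy-'reflect' (symmetric) borders."""
    kh, kw = kern.shape
    # scipy.ndimage.convolve centers a size-10 kernel at index 5 and flips it
    oh, ow = kh // 2, kw // 2
    flipped = kern[::-1, ::-1]
    padded = np.pad(img, ((kh - 1 - oh, oh), (kw - 1 - ow, ow)), mode="symmetric")
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.sum(padded[i : i + kh, j : j + kw] * flipped)
    return out


class TestGaussianSmooth:
    def test_constant_fixed_point(self):
        img = rs.OctImage(np.full((40, 50), 0.37))
        np.testing.assert_allclose(od.gaussian_smooth(img).pixels, 0.37, atol=1e-12)

    def test_impulse_response_is_kernel(self):
        px = np.zeros((41, 41))
        px[20, 20] = 1.0
        out = od.gaussian_smooth(rs.OctImage(px)).pixels
        kern = od.gaussian_kernel()
        assert kern.shape == (10, 10)
        assert kern.sum() == pytest.approx(1.0)
        # the 10x10 kernel appears around the impulse (kernel is flipped by
        # convolution but symmetric, so it reads back directly)
        window = out[out > 0]
        np.testing.assert_allclose(np.sort(window), np.sort(kern.ravel()), atol=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        img = rng.random((24, 31))
        out = od.gaussian_smooth(rs.OctImage(img)).pixels
        np.testing.assert_allclose(out, brute_gaussian(img, od.gaussian_kernel()), atol=1e-12)

    def test_mean_preserved_away_from_borders(self, rng):
        # with constant margins wider than the kernel, reflective borders are
        # exact and the unit-DC kernel preserves the mean
        img = np.full((60, 60), 0.5)
        img[10:-10, 10:-10] = rng.random((40, 40))
        out = od.gaussian_smooth(rs.OctImage(img)).pixels
        assert abs(out.mean() - img.mean()) < 1e-6


class TestMedianFilter:
    def test_constant_unchanged(self):
        img = rs.OctImage(np.full((20, 20), 0.6))
        np.testing.assert_array_equal(od.median_filter(img).pixels, 0.6)

    def test_spike_removed(self):
        px = np.full((21, 21), 0.5)
        px[10, 10] = 1.0
        out = od.median_filter(rs.OctImage(px)).pixels
        assert out[10, 10] == pytest.approx(0.5)

    def test_matches_brute_force_sort(self, rng):
        img = rng.random((8, 8))
        out = od.median_filter(rs.OctImage(img)).pixels
        padded = np.pad(img, 1, mode="symmetric")
        for i in range(8):
            for j in range(8):
                win = np.sort(padded[i : i + 3, j : j + 3].ravel())
                assert out[i, j] == pytest.approx(win[4], abs=1e-15)


class TestConduction:
    def test_zero_gradient_full_conduction(self):
        assert od.conduction(0.0, K=1.0) == pytest.approx(1.0)

    def test_at_K_is_inverse_e(self):
        assert od.conduction(2.5, K=2.5) == pytest.approx(np.exp(-1.0))

    def test_strictly_decreasing(self):
        vals = od.conduction(np.linspace(0, 3, 50), K=0.7)
        assert (np.diff(vals) < 0).all()

    def test_symmetric_in_sign(self):
        assert od.conduction(-0.4, K=1.0) == pytest.approx(od.conduction(0.4, K=1.0))

    def test_bad_K_rejected(self):
        with pytest.raises(rs.ParameterError):
            od.conduction(1.0, K=0.0)


LINEAR_STENCIL = np.array(
    [[0.125, 0.125, 0.125], [0.125, 0.0, 0.125], [0.125, 0.125, 0.125]]
)


class TestAnisotropicDiffuse:
    def test_constant_fixed_point(self):
        img = rs.OctImage(np.full((30, 30), 0.42))
        p = rs.DiffusionParams(lam=0.125, K=0.5, n_iter=7)
        np.testing.assert_array_equal(od.anisotropic_diffuse(img, p).pixels, 0.42)

    @pytest.mark.parametrize("n_iter", [1, 5, 20])
    def test_linear_limit_matches_convolution_oracle(self, rng, n_iter):
        img = rng.random((64, 64))
        p = rs.DiffusionParams(lam=0.125, K=np.inf, n_iter=n_iter)
        out = od.anisotropic_diffuse(rs.OctImage(img), p).pixels
        lam = 0.125
        kern = lam * np.ones((3, 3))
        kern[1, 1] = 1 - 8 * lam
        ref = img.copy()
        for _ in range(n_iter):
            ref = ndimage.convolve(ref, kern, mode="nearest")
        np.testing.assert_allclose(out, ref, atol=1e-10)

    def test_single_step_two_region_hand_computed(self):
        # left half u, right half v; h = v - u >> K.  For a pixel in the left
        # column adjacent to the edge, three neighbors (E, NE, SE) differ by h,
        # so one step adds lam * 3 * g(h) * h; deep-interior pixels see zero
        # difference everywhere and stay put.
        u, v, K, lam = 0.1, 0.9, 0.08, 0.125
        h = v - u
        img = np.full((9, 12), u)
        img[:, 6:] = v
        p = rs.DiffusionParams(lam=lam, K=K, n_iter=1)
        out = od.anisotropic_diffuse(rs.OctImage(img), p).pixels
        g = np.exp(-((h / K) ** 2))
        expected_edge = u + lam * 3.0 * g * h
        assert out[4, 5] == pytest.approx(expected_edge, abs=1e-12)
        assert out[4, 2] == pytest.approx(u, abs=1e-12)  # interior unchanged
        assert out[4, 9] == pytest.approx(v, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(
        img=hnp.arrays(
            float, (16, 16), elements=st.floats(0.0, 1.0, allow_nan=False, width=32)
        ),
        K=st.floats(0.01, 2.0),
        n_iter=st.integers(1, 10),
    )
    def test_maximum_principle(self, img, K, n_iter):
        p = rs.DiffusionParams(lam=0.125, K=K, n_iter=n_iter)
        out = od.anisotropic_diffuse(rs.OctImage(img), p).pixels
        assert out.min() >= img.min() - 1e-12
        assert out.max() <= img.max() + 1e-12

    def test_edge_preserved_variance_reduced(self, rng):
        # step of height 5K: edge gradient survives 20 iterations while
        # within-region variance falls monotonically
        K = 0.1
        img = np.full((40, 40), 0.2) + 0.02 * rng.standard_normal((40, 40))
        img[:, 20:] += 5 * K
        img = np.clip(img, 0, 1)
        edge_grad = lambda a: np.abs(a[:, 20] - a[:, 19]).mean()
        before = edge_grad(img)
        variances = []
        cur = rs.OctImage(img)
        for _ in range(20):
            cur = od.anisotropic_diffuse(cur, rs.DiffusionParams(lam=0.125, K=K, n_iter=1))
            variances.append(cur.pixels[5:-5, 2:17].var())
        assert edge_grad(cur.pixels) > 0.9 * before
        assert all(b < a + 1e-15 for a, b in zip(variances, variances[1:]))

    def test_invalid_params_fail_before_iterating(self):
        with pytest.raises(rs.ParameterError):
            rs.DiffusionParams(lam=0.5)

    def test_statistical_K_positive(self, rng):
        assert od.statistical_K(rng.random((50, 50))) > 0
        assert od.statistical_K(np.zeros((50, 50))) > 0
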