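"""Core filter primitives against dense brute-force oracles and invariants."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    convolve_planewise_brute,
    gaussian_kernel_brute,
    reconstruct_brute,
    threshold_components_brute,
    tophat_brute,
)
from rosellapipe.filters import (
    GaussianSpec,
    butterworth_highpass_plane,
    complement_image,
    difference_of_gaussians,
    gaussian_convolve,
    gaussian_kernel,
    label_volume,
    laplacian_of_gaussian,
    log_kernel,
    morphological_reconstruct,
    ratio_image,
    threshold_components,
    tophat_gray,
)


@pytest.fixture()
def volume(rng):
    return rng.uniform(0, 4000, size=(3, 32, 32))


class TestGaussianConvolve:
    def test_kernel_unit_sum_and_symmetry(self):
        for size, sd in [(20, 1.0), (20, 7.0), (5, 2.0), (101, 20.0)]:
            k = gaussian_kernel(GaussianSpec(size, sd))
            assert k.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(k, k.T)

    def test_constant_preserved(self):
        img = np.full((2, 16, 16), 1234.5)
        out = gaussian_convolve(img, GaussianSpec(9, 2.0))
        assert np.allclose(out, 1234.5)

    def test_impulse_reproduces_kernel(self):
        img = np.zeros((1, 41, 41))
        img[0, 20, 20] = 1.0
        out = gaussian_convolve(img, GaussianSpec(21, 1.0))
        k = gaussian_kernel(GaussianSpec(21, 1.0))
        assert np.allclose(out[0, 10:31, 10:31], k, atol=1e-12)

    def test_matches_brute_force(self, volume):
        for spec in [GaussianSpec(20, 1.0), GaussianSpec(7, 2.5)]:
            expected = convolve_planewise_brute(volume, gaussian_kernel_brute(spec.size, spec.sd))
            got = gaussian_convolve(volume, spec)
            np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-8)

    def test_linearity(self, rng):
        a, b = 2.5, -1.25
        i1 = rng.uniform(0, 100, (1, 32, 32))
        i2 = rng.uniform(0, 100, (1, 32, 32))
        spec = GaussianSpec(9, 1.5)
        lhs = gaussian_convolve(a * i1 + b * i2, spec)
        rhs = a * gaussian_convolve(i1, spec) + b * gaussian_convolve(i2, spec)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GaussianSpec(20, 0.0)
        with pytest.raises(ValueError):
            GaussianSpec(0, 1.0)


class TestDifferenceOfGaussians:
    def test_constant_maps_to_zero(self):
        img = np.full((2, 24, 24), 777.0)
        out = difference_of_gaussians(img, GaussianSpec(20, 1), GaussianSpec(20, 7))
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_inverted_band_rejected(self):
        img = np.zeros((1, 8, 8))
        with pytest.raises(ValueError):
            difference_of_gaussians(img, GaussianSpec(20, 7), GaussianSpec(20, 1))
        with pytest.raises(ValueError):
            difference_of_gaussians(img, GaussianSpec(20, 2), GaussianSpec(20, 2))

    def test_impulse_centre_value(self):
        img = np.zeros((1, 64, 64))
        img[0, 32, 32] = 1.0
        out = difference_of_gaussians(img, GaussianSpec(20, 1), GaussianSpec(20, 7))
        kf = gaussian_kernel_brute(20, 1.0)
        kb = gaussian_kernel_brute(20, 7.0)
        # even-sized kernel anchors the centre tap at index s//2
        assert out[0, 32, 32] == pytest.approx(kf[10, 10] - kb[10, 10], rel=1e-9)

    def test_matches_brute_force(self, volume):
        fg, bg = GaussianSpec(11, 1.0), GaussianSpec(25, 6.0)
        expected = convolve_planewise_brute(
            volume, gaussian_kernel_brute(11, 1.0)
        ) - convolve_planewise_brute(volume, gaussian_kernel_brute(25, 6.0))
        np.testing.assert_allclose(
            difference_of_gaussians(volume, fg, bg), expected, rtol=1e-6, atol=1e-6
        )


class TestLaplacianOfGaussian:
    def test_zero_sum_kernel_and_constant(self):
        k = log_kernel(20, 1.0)
        assert abs(k.sum()) < 1e-12
        img = np.full((1, 30, 30), 500.0)
        assert np.allclose(laplacian_of_gaussian(img, 20, 1.0), 0.0, atol=1e-8)

    def test_bright_disk_sign_pattern(self):
        img = np.zeros((1, 64, 64))
        yy, xx = np.mgrid[0:64, 0:64]
        disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 9
        img[0, disk] = 5000.0
        out = laplacian_of_gaussian(img, 9, 1.0)
        assert out[0, 32, 32] < -100  # interior strongly negative
        assert out[0, 32, 32 + 5] > 100  # positive ring just outside

    def test_impulse_reproduces_kernel_and_oracle(self, volume):
        expected = convolve_planewise_brute(volume, log_kernel(9, 1.0))
        np.testing.assert_allclose(
            laplacian_of_gaussian(volume, 9, 1.0), expected, rtol=1e-6, atol=1e-6
        )


class TestTophat:
    def test_constant_maps_to_zero(self):
        img = np.full((1, 20, 20), 432.0)
        assert np.allclose(tophat_gray(img, 5), 0.0)

    def test_small_disk_recovered_and_nonnegative(self):
        img = np.zeros((1, 80, 80))
        yy, xx = np.mgrid[0:80, 0:80]
        disk = (yy - 40) ** 2 + (xx - 40) ** 2 <= 100
        img[0, disk] = 900.0
        out = tophat_gray(img, 25)
        assert out.min() >= 0
        assert out[0, 40, 40] == pytest.approx(900.0, rel=1e-6)

    def test_ramp_suppressed_peak_retained(self):
        ramp = np.tile(np.linspace(0, 400, 48), (48, 1))[None]
        img = ramp.copy()
        img[0, 24, 24] += 1000.0
        out = tophat_gray(img, 10)
        assert out[0, 24, 24] > 900.0
        far = out[0, 5:15, 30:40]
        assert far.max() < 150.0  # ramp background largely removed

    def test_matches_brute_force(self, rng):
        plane = rng.uniform(0, 1000, (18, 18))
        for radius in (2, 4):
            np.testing.assert_allclose(
                tophat_gray(plane[None], radius)[0],
                tophat_brute(plane, radius),
                rtol=1e-6,
                atol=1e-6,
            )


class TestButterworth:
    def test_constant_killed_and_parameters_checked(self):
        plane = np.full((32, 32), 900.0)
        assert np.allclose(butterworth_highpass_plane(plane, 10, 5), 0.0, atol=1e-8)
        with pytest.raises(ValueError):
            butterworth_highpass_plane(plane, 0, 5)
        with pytest.raises(ValueError):
            butterworth_highpass_plane(plane, 10, 0)
        with pytest.raises(ValueError):
            butterworth_highpass_plane(np.full((4, 4), np.nan), 10, 5)

    def test_half_gain_at_cutoff(self):
        n, d0 = 64, 8.0
        x = np.arange(n)
        plane = np.cos(2 * np.pi * d0 * x / n)[None, :].repeat(n, axis=0)
        out = butterworth_highpass_plane(plane, d0, 5)
        assert np.abs(out).max() == pytest.approx(0.5, rel=1e-6)

    def test_high_frequency_preserved(self):
        n, d0 = 256, 4.0
        x = np.arange(n)
        plane = np.sin(2 * np.pi * (8 * d0) * x / n)[None, :].repeat(n, axis=0)
        out = butterworth_highpass_plane(plane, d0, 5)
        analytic_gain = 1.0 / (1.0 + (d0 / (8 * d0)) ** 10)
        assert np.abs(out).max() == pytest.approx(analytic_gain, rel=0.01)


class TestRatioAndComplement:
    def test_uniform_ratio(self):
        g = np.full((2, 16, 16), 500.0)
        r = np.full((2, 16, 16), 1000.0)
        assert np.allclose(ratio_image(g, r), 0.5)
        assert np.allclose(ratio_image(g, g), 1.0)

    def test_zero_red_clamped_finite(self):
        g = np.full((1, 16, 16), 400.0)
        r = np.zeros((1, 16, 16))
        out = ratio_image(g, r)
        assert np.all(np.isfinite(out))
        assert out.max() <= 400.0  # bounded by green / eps

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ratio_image(np.zeros((1, 8, 8)), np.zeros((1, 9, 9)))

    def test_complement_involution_and_ordering(self, rng):
        img = rng.uniform(0, 10, (2, 12, 12))
        comp = complement_image(img)
        assert comp.min() == pytest.approx(0.0)
        # ordering reversed: argmax becomes argmin
        assert np.argmax(img) == np.argmin(comp)
        # involution up to the reference maximum: double complement shifts
        # the original down by its minimum
        double = complement_image(comp)
        np.testing.assert_allclose(double, img - img.min(), atol=1e-9)

    def test_dark_vesicle_becomes_brightest(self):
        ratio = np.full((1, 32, 32), 5.0)
        ratio[0, 10:15, 10:15] = 0.5
        comp = complement_image(ratio)
        assert comp[0, 12, 12] == comp.max()


class TestThresholdComponents:
    def test_empty_and_comparator_validation(self):
        img = np.zeros((2, 8, 8))
        assert not threshold_components(img, ">", 400).any()
        with pytest.raises(ValueError):
            threshold_components(img, "!=", 0)
        with pytest.raises(ValueError):
            threshold_components(img, ">", 0, min_size=10, max_size=5)

    def test_size_window_removes_both_blobs(self):
        img = np.zeros((5, 40, 40))
        img[1, 5:10, 5:11] = 900.0  # 150 voxels: below window
        img[0:5, 15:35, 15:40] = 900.0  # 2500 voxels: above window
        out = threshold_components(img, ">", 400, min_size=200, max_size=2000)
        assert not out.any()

    def test_inclusive_bounds_and_oracle(self, rng):
        img = (rng.uniform(0, 1, (3, 16, 16)) > 0.7) * 1000.0
        for comparator, value, lo, hi in [(">", 400, 3, 40), (">=", 1000, 1, 10), ("<", 500, 5, 200)]:
            got = threshold_components(img, comparator, value, lo, hi)
            expected = threshold_components_brute(img, comparator, value, lo, hi)
            np.testing.assert_array_equal(got, expected)
        # a blob of exactly min_size voxels is retained
        img2 = np.zeros((1, 10, 10))
        img2[0, 2:4, 2:5] = 100.0  # 6 voxels
        assert threshold_components(img2, ">", 50, min_size=6, max_size=6).sum() == 6

    @given(st.integers(0, 2**31 - 1), st.floats(100, 900))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_threshold(self, seed, thr):
        img = np.random.default_rng(seed).uniform(0, 1000, (2, 12, 12))
        low = threshold_components(img, ">", thr)
        high = threshold_components(img, ">", thr + 50)
        assert not (high & ~low).any()


class TestMorphologicalReconstruct:
    def test_trivial_cases(self):
        limit = np.zeros((2, 8, 8), dtype=bool)
        limit[0, 2:5, 2:5] = True
        empty = np.zeros_like(limit)
        assert not morphological_reconstruct(empty, limit).any()
        np.testing.assert_array_equal(morphological_reconstruct(limit, limit), limit)

    def test_selects_touched_components(self, rng):
        limit = rng.uniform(0, 1, (3, 24, 24)) > 0.75
        seed = np.zeros_like(limit)
        nz = np.argwhere(limit)
        for row in nz[:: max(len(nz) // 5, 1)]:
            seed[tuple(row)] = True
        got = morphological_reconstruct(seed, limit)
        expected = reconstruct_brute(seed, limit)
        np.testing.assert_array_equal(got, expected)

    def test_three_components_two_seeded(self):
        limit = np.zeros((1, 10, 30), dtype=bool)
        limit[0, 2:6, 1:6] = True
        limit[0, 2:6, 10:15] = True
        limit[0, 2:6, 20:25] = True
        seed = np.zeros_like(limit)
        seed[0, 3, 2] = True
        seed[0, 3, 22] = True
        out = morphological_reconstruct(seed, limit)
        _, n = label_volume(out)
        assert n == 2
        assert not out[0, :, 10:15].any()

    def test_idempotent_and_monotone_in_seed(self, rng):
        limit = rng.uniform(0, 1, (2, 16, 16)) > 0.7
        seed1 = limit & (rng.uniform(0, 1, limit.shape) > 0.8)
        seed2 = seed1 | (limit & (rng.uniform(0, 1, limit.shape) > 0.8))
        r1 = morphological_reconstruct(seed1, limit)
        r2 = morphological_reconstruct(seed2, limit)
        np.testing.assert_array_equal(morphological_reconstruct(r1, limit), r1)
        assert not (r1 & ~r2).any()
        assert (r1 >= (seed1 & limit)).all() and (limit >= r1).all()
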