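"""Wavelet decomposition, shrinkage rules, and perfect reconstruction."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from denobench.pyramid import DepthError
from denobench.wavelet import (
    FAMILIES,
    SubbandTree,
    ThresholdRule,
    decompose,
    denoise_wavelet,
    estimate_noise_sigma,
    hard_threshold,
    reconstruct_wavelet,
    soft_threshold,
    threshold_coefficients,
    universal_threshold,
)


class TestDecompose:
    def test_constant_2x2_haar_concentrates_in_approximation(self):
        tree = decompose(np.ones((2, 2)), "haar", 1)
        np.testing.assert_allclose(tree.approx, [[2.0]], atol=1e-12)
        for band in tree.details[0]:
            np.testing.assert_allclose(band, 0.0, atol=1e-12)

    def test_haar_matches_hand_butterfly(self):
        # separable orthonormal Haar on a 4x4 block: each 2x2 cell maps to
        # (sum, row-diff, col-diff, cross-diff) / 2
        block = np.array(
            [[1.0, 2, 3, 4], [5, 6, 7, 8], [9, 10, 11, 12], [13, 14, 15, 16]]
        )
        tree = decompose(block, "haar", 1)
        ll = np.zeros((2, 2))
        lh = np.zeros((2, 2))
        hl = np.zeros((2, 2))
        hh = np.zeros((2, 2))
        for x in range(2):
            for y in range(2):
                a, b = block[2 * x, 2 * y], block[2 * x, 2 * y + 1]
                c, d = block[2 * x + 1, 2 * y], block[2 * x + 1, 2 * y + 1]
                ll[x, y] = (a + b + c + d) / 2
                lh[x, y] = (a - b + c - d) / 2  # vertical edges (col diff)
                hl[x, y] = (a + b - c - d) / 2  # horizontal edges (row diff)
                hh[x, y] = (a - b - c + d) / 2
        np.testing.assert_allclose(tree.approx, ll, atol=1e-10)
        np.testing.assert_allclose(tree.details[0][0], lh, atol=1e-10)
        np.testing.assert_allclose(tree.details[0][1], hl, atol=1e-10)
        np.testing.assert_allclose(tree.details[0][2], hh, atol=1e-10)

    @pytest.mark.parametrize("family", FAMILIES)
    @pytest.mark.parametrize("depth", [1, 2, 3])
    def test_round_trip_is_exact(self, rng, family, depth):
        image = rng.random((32, 32)) * 255
        tree = decompose(image, family, depth)
        np.testing.assert_allclose(reconstruct_wavelet(tree), image, atol=1e-8)

    def test_odd_shapes_round_trip(self, rng):
        image = rng.random((37, 41)) * 255
        tree = decompose(image, "db4", 2)
        out = reconstruct_wavelet(tree)
        assert out.shape == (37, 41)
        np.testing.assert_allclose(out, image, atol=1e-8)

    def test_infeasible_depth(self):
        with pytest.raises(DepthError):
            decompose(np.zeros((8, 8)), "haar", 10)

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            decompose(np.zeros((16, 16)), "bior2.2", 1)


class TestThresholding:
    def test_zero_threshold_is_identity(self, rng):
        image = rng.random((32, 32)) * 255
        tree = decompose(image, "db4", 2)
        for mode in ("soft", "hard"):
            out = threshold_coefficients(tree, ThresholdRule(mode=mode, value=0.0))
            for lvl_in, lvl_out in zip(tree.details, out.details):
                for band_in, band_out in zip(lvl_in, lvl_out):
                    np.testing.assert_array_equal(band_in, band_out)

    def test_soft_and_hard_on_known_coefficients(self):
        coeffs = np.array([3.0, -1.0, 0.5])
        np.testing.assert_allclose(soft_threshold(coeffs, 1.0), [2.0, 0.0, 0.0])
        np.testing.assert_allclose(hard_threshold(coeffs, 1.0), [3.0, -1.0, 0.0])

    def test_approximation_never_thresholded(self, rng):
        tree = decompose(rng.random((32, 32)) * 255, "haar", 2)
        out = threshold_coefficients(tree, ThresholdRule(mode="soft", value=1e6))
        np.testing.assert_array_equal(out.approx, tree.approx)
        assert all(
            np.all(band == 0.0) for level in out.details for band in level
        )

    def test_negative_fixed_threshold_rejected(self):
        with pytest.raises(ValueError):
            ThresholdRule(mode="soft", value=-1.0)

    def test_universal_selector_recovers_noise_scale(self):
        # sigma estimated from a pure-noise diagonal subband should put T
        # within 5% of sigma*sqrt(2 ln N)
        sigma, n = 10.0, 4096
        target = sigma * np.sqrt(2 * np.log(n))
        estimates = []
        for seed in range(20):
            hh = np.random.default_rng(seed).normal(0.0, sigma, n)
            estimates.append(universal_threshold(estimate_noise_sigma(hh), n))
        assert abs(np.mean(estimates) - target) / target < 0.05
        assert all(abs(t - target) / target < 0.10 for t in estimates)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        coeffs=hnp.arrays(
            np.float64,
            (64,),
            elements=st.floats(-1000, 1000, allow_nan=False),
        ),
        t1=st.floats(0, 50),
        t2=st.floats(0, 50),
    )
    def test_shrinkage_properties(self, coeffs, t1, t2):
        lo, hi = sorted((t1, t2))
        soft = soft_threshold(coeffs, hi)
        hard = hard_threshold(coeffs, hi)
        # soft non-expansiveness; hard is a masked copy
        assert (np.abs(soft) <= np.abs(coeffs) + 1e-12).all()
        assert ((hard == coeffs) | (hard == 0.0)).all()
        # monotonicity: larger T never increases the support
        for shrink in (soft_threshold, hard_threshold):
            assert np.count_nonzero(shrink(coeffs, hi)) <= np.count_nonzero(
                shrink(coeffs, lo)
            )


class TestReconstruction:
    def test_zeroed_details_obey_energy_bound(self, rng):
        image = rng.random((64, 64)) * 255
        tree = decompose(image, "haar", 2)
        smooth = reconstruct_wavelet(
            threshold_coefficients(tree, ThresholdRule(mode="hard", value=1e9))
        )
        assert np.sum(smooth**2) <= np.sum(image**2) * (1 + 1e-6)

    def test_corrupted_subband_shapes_rejected(self, rng):
        tree = decompose(rng.random((32, 32)), "haar", 1)
        bad = SubbandTree(
            approx=tree.approx,
            details=[tuple(band[:-1] for band in tree.details[0])],
            family="haar",
            original_shape=tree.original_shape,
        )
        with pytest.raises(ValueError):
            reconstruct_wavelet(bad)

    @pytest.mark.parametrize("family", ["haar", "db4"])
    def test_single_diagonal_atom_is_separable_filter_product(self, family):
        # a lone unit HH coefficient away from borders reconstructs to the
        # rank-1 outer product of the family's high-pass synthesis filter
        tree = decompose(np.zeros((64, 64)), family, 1)
        hh = np.zeros_like(tree.details[0][2])
        hh[hh.shape[0] // 2, hh.shape[1] // 2] = 1.0
        atom = reconstruct_wavelet(
            SubbandTree(
                approx=np.zeros_like(tree.approx),
                details=[(np.zeros_like(hh), np.zeros_like(hh), hh)],
                family=family,
                original_shape=(64, 64),
            )
        )
        # rank-1 separability
        s = np.linalg.svd(atom, compute_uv=False)
        assert s[1] < 1e-10
        # the 1-D profile equals rec_hi up to position (and overall sign)
        rec_hi = np.asarray(pywt.Wavelet(family).rec_hi)
        row = atom[np.abs(atom).sum(axis=1).argmax()]
        profile = np.trim_zeros(np.where(np.abs(row) < 1e-12, 0.0, row))
        profile = profile / np.abs(profile).max() * np.abs(rec_hi).max()
        match = min(
            np.max(np.abs(profile - rec_hi)), np.max(np.abs(profile + rec_hi))
        )
        assert match < 1e-10


class TestDenoiseWavelet:
    def test_fixed_zero_threshold_is_identity(self, rng):
        image = rng.random((64, 64)) * 255
        out = denoise_wavelet(image, "haar", 2, ThresholdRule(mode="soft", value=0.0))
        np.testing.assert_allclose(out, image, atol=1e-8)

    def test_universal_soft_gains_on_gaussian_noise(self, phantom):
        from denobench.metrics import psnr
        from denobench.noise import NoiseSpec, add_noise

        for seed in range(5):
            noisy = add_noise(phantom, NoiseSpec("gaussian", seed=seed))
            out = denoise_wavelet(noisy, "db4", 2, ThresholdRule(mode="soft"))
            assert psnr(phantom, out) > psnr(phantom, noisy)

    def test_soft_and_hard_differ_at_equal_threshold(self, phantom):
        noisy = add_noise_gaussian(phantom)
        soft = denoise_wavelet(noisy, "db4", 2, ThresholdRule("soft", value=20.0))
        hard = denoise_wavelet(noisy, "db4", 2, ThresholdRule("hard", value=20.0))
        assert np.abs(soft - hard).max() > 1.0


def add_noise_gaussian(image):
    from denobench.noise import NoiseSpec, add_noise

    return add_noise(image, NoiseSpec("gaussian", seed=0))
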