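"""Similarity metrics: closed-form identities, oracle equivalence, properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from organcolor import WphConfig, psnr, ssim, wph
from organcolor.metrics import default_roi


def brute_force_wph(img, ref, patch, bins, roi_weight, roi=None):
    """Independent oracle: explicit per-patch loops and np.histogram."""
    g = img.shape[0] // patch
    sims = np.zeros((g, g))
    for i in range(g):
        for j in range(g):
            acc = 0.0
            for c in range(3):
                p1 = img[i * patch : (i + 1) * patch, j * patch : (j + 1) * patch, c]
                p2 = ref[i * patch : (i + 1) * patch, j * patch : (j + 1) * patch, c]
                h1, _ = np.histogram(p1, bins=bins, range=(0, 256))
                h2, _ = np.histogram(p2, bins=bins, range=(0, 256))
                acc += np.minimum(h1 / p1.size, h2 / p2.size).sum()
            sims[i, j] = acc / 3.0
    if roi is None:
        roi = default_roi(g)
    w = np.where(roi, roi_weight, 1.0)
    return (w * sims).sum() / w.sum(), sims


class TestPsnr:
    def test_identical_images_are_infinite(self, random_rgb):
        img = random_rgb()
        assert math.isinf(psnr(img, img))

    def test_unit_offset_gives_log_peak(self, random_rgb):
        img = random_rgb().astype(np.int16)
        shifted = np.clip(img + 1, None, 255)
        img = np.where(shifted == img, img - 1, img)  # keep |diff| = 1 at 255
        assert psnr(img, shifted) == pytest.approx(20 * math.log10(255), abs=1e-9)

    def test_full_scale_error_is_zero_db(self):
        a = np.zeros((8, 8, 3), np.uint8)
        b = np.full((8, 8, 3), 255, np.uint8)
        assert psnr(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((4, 4, 3)), np.zeros((8, 8, 3)))

    def test_matches_reference_implementation(self, random_rgb):
        skm = pytest.importorskip("skimage.metrics")
        a, b = random_rgb(), random_rgb()
        ref = skm.peak_signal_noise_ratio(b, a, data_range=255)
        assert psnr(a, b) == pytest.approx(ref, abs=1e-6)


class TestSsim:
    def test_identical_images_score_one(self, random_rgb):
        img = random_rgb()
        assert ssim(img, img) == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_pattern_is_negative(self, rng):
        x = rng.integers(0, 256, (64, 64), dtype=np.uint8)
        assert ssim(x, 255 - x) < 0.0

    def test_constant_images_luminance_closed_form(self):
        a = np.full((32, 32), 100.0)
        b = np.full((32, 32), 110.0)
        c1 = (0.01 * 255) ** 2
        expected = (2 * 100 * 110 + c1) / (100**2 + 110**2 + c1)
        assert ssim(a, b) == pytest.approx(expected, abs=1e-12)

    def test_image_smaller_than_window_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((8, 8)), np.zeros((8, 8)))

    def test_matches_reference_implementation(self, random_rgb):
        skm = pytest.importorskip("skimage.metrics")
        for _ in range(3):
            a, b = random_rgb(), random_rgb()
            ref = skm.structural_similarity(
                a, b, channel_axis=-1, gaussian_weights=True, sigma=1.5,
                use_sample_covariance=False, data_range=255,
            )
            assert ssim(a, b) == pytest.approx(ref, abs=1e-4)


class TestWph:
    CFG = WphConfig(patch_size=32, bins=32, roi_weight=1.5)

    def test_identical_images_score_one(self, random_rgb):
        img = random_rgb()
        score, patch_map = wph(img, img, WphConfig(patch_size=16))
        assert score == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(patch_map, 1.0)

    def test_disjoint_histograms_score_zero(self):
        a = np.zeros((64, 64, 3), np.uint8)
        b = np.full((64, 64, 3), 255, np.uint8)
        score, _ = wph(a, b, self.CFG)
        assert score == 0.0

    def test_symmetry(self, random_rgb):
        a, b = random_rgb(), random_rgb()
        assert wph(a, b, self.CFG)[0] == pytest.approx(wph(b, a, self.CFG)[0], abs=1e-15)

    def test_brute_force_oracle_equivalence(self, random_rgb):
        for _ in range(3):
            a, b = random_rgb(64), random_rgb(64)
            mine, mine_map = wph(a, b, self.CFG)
            oracle, oracle_map = brute_force_wph(a, b, 32, 32, 1.5)
            assert mine == pytest.approx(oracle, abs=1e-12)
            np.testing.assert_allclose(mine_map, oracle_map, atol=1e-12)

    def test_intra_patch_permutation_invariance(self, rng, random_rgb):
        """Histograms discard pixel position inside a patch."""
        a, b = random_rgb(64), random_rgb(64)
        shuffled = a.copy()
        perm = rng.permutation(32 * 32)
        block = shuffled[:32, 32:].reshape(-1, 3)[perm]
        shuffled[:32, 32:] = block.reshape(32, 32, 3)
        assert wph(a, b, self.CFG)[0] == pytest.approx(
            wph(shuffled, b, self.CFG)[0], abs=1e-15
        )

    def test_unit_multiplier_is_unweighted_mean(self, random_rgb):
        a, b = random_rgb(64), random_rgb(64)
        cfg = WphConfig(patch_size=16, roi_weight=1.0)
        score, patch_map = wph(a, b, cfg)
        assert score == pytest.approx(patch_map.mean(), abs=1e-15)

    def test_roi_upweights_central_block(self):
        """Making only the central patches match raises the score more than
        the unweighted mean would."""
        a = np.zeros((64, 64, 3), np.uint8)
        b = np.full((64, 64, 3), 255, np.uint8)
        b[16:48, 16:48] = 0  # central 2×2 patches of the 4×4 grid agree
        cfg = WphConfig(patch_size=16, roi_weight=1.5)
        score, patch_map = wph(a, b, cfg)
        assert score > patch_map.mean()

    def test_indivisible_patch_size_rejected(self, random_rgb):
        with pytest.raises(ValueError):
            wph(random_rgb(48), random_rgb(48), WphConfig(patch_size=32))

    def test_default_roi_is_central_half_block(self):
        roi = default_roi(8)
        assert roi.sum() == 16
        assert roi[2:6, 2:6].all()


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_wph_bounded_and_reflexive(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
    b = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
    score, patch_map = wph(a, b, WphConfig(patch_size=16))
    assert 0.0 <= score <= 1.0
    assert np.all((patch_map >= 0) & (patch_map <= 1))
    assert wph(a, a, WphConfig(patch_size=16))[0] == pytest.approx(1.0, abs=1e-12)
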