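"""Network contracts: CBAM algebra and shapes, generator and discriminator."""

import numpy as np
import pytest

from organcolor import CBAM, PatchDiscriminator, UNetGenerator, cbam_refine


class TestCBAM:
    def test_zero_parameters_give_quarter_attenuation(self, rng):
        """Both attention sigmoids output 0.5 at zero parameters, so the
        refined map is (0.5)·(0.5)·F = 0.25·F element-wise."""
        mod = CBAM(8, reduction=4, rng=rng)
        for p in mod.parameters():
            p.value[...] = 0.0
        f = rng.standard_normal((2, 8, 6, 6)).astype(np.float32)
        out, mc, ms = cbam_refine(f, mod)
        np.testing.assert_allclose(out, 0.25 * f, atol=1e-6)
        np.testing.assert_allclose(mc, 0.5)
        np.testing.assert_allclose(ms, 0.5)

    def test_zero_input_maps_to_zero(self, rng):
        mod = CBAM(8, reduction=4, rng=rng)
        out, _, _ = cbam_refine(np.zeros((1, 8, 4, 4), np.float32), mod)
        assert np.all(out == 0.0)

    def test_attention_map_shapes(self, rng):
        mod = CBAM(8, reduction=4, rng=rng)
        f = rng.standard_normal((1, 8, 16, 16)).astype(np.float32)
        out, mc, ms = cbam_refine(f, mod)
        assert mc.shape == (1, 8, 1, 1)
        assert ms.shape == (1, 1, 16, 16)
        assert out.shape == f.shape

    def test_sequential_factorization(self, rng):
        """F'' equals Ms ⊗ (Mc ⊗ F) with the returned attention maps."""
        mod = CBAM(16, reduction=4, rng=rng)
        f = rng.standard_normal((3, 16, 5, 5)).astype(np.float32)
        out, mc, ms = cbam_refine(f, mod)
        np.testing.assert_allclose(out, (f * mc) * ms, rtol=1e-6, atol=1e-7)
        assert np.all((mc > 0) & (mc < 1)) and np.all((ms > 0) & (ms < 1))

    def test_incompatible_reduction_is_config_error(self):
        with pytest.raises(ValueError):
            CBAM(8, reduction=16)


class TestGenerator:
    def test_output_shape_and_range(self, rng):
        gen = UNetGenerator(img_size=64, base=8, cbam_reduction=8, rng=rng)
        x = rng.uniform(-1, 1, (2, 1, 64, 64)).astype(np.float32)
        out = gen.forward(x, train=False)
        assert out.shape == (2, 2, 64, 64)
        assert np.all(out > -1.0) and np.all(out < 1.0)

    def test_paper_scale_geometry(self):
        gen = UNetGenerator(img_size=256, base=4, cbam_reduction=4,
                            rng=np.random.default_rng(0))
        assert gen.depth == 8
        x = np.zeros((1, 1, 256, 256), np.float32)
        assert gen.forward(x, train=False).shape == (1, 2, 256, 256)

    def test_depth_auto_reduces_for_small_images(self):
        gen = UNetGenerator(img_size=64, base=4, cbam_reduction=4,
                            rng=np.random.default_rng(0))
        assert gen.depth == 6

    def test_deterministic_given_seed(self, rng):
        x = rng.uniform(-1, 1, (1, 1, 32, 32)).astype(np.float32)
        outs = []
        for _ in range(2):
            gen = UNetGenerator(img_size=32, base=8, cbam_reduction=8,
                                rng=np.random.default_rng(99))
            outs.append(gen.forward(x.copy(), train=False))
        assert np.array_equal(outs[0], outs[1])

    def test_rejects_bad_geometry(self, rng):
        with pytest.raises(ValueError):
            UNetGenerator(img_size=48)
        gen = UNetGenerator(img_size=32, base=8, cbam_reduction=8, rng=rng)
        with pytest.raises(ValueError):
            gen.forward(np.zeros((1, 1, 64, 64), np.float32), train=False)


class TestDiscriminator:
    def test_mean_score_is_patch_mean(self, rng):
        disc = PatchDiscriminator(in_ch=3, base=8, rng=rng)
        cond = rng.uniform(-1, 1, (2, 1, 64, 64)).astype(np.float32)
        ab = rng.uniform(-1, 1, (2, 2, 64, 64)).astype(np.float32)
        patches, mean = disc.scores(cond, ab)
        np.testing.assert_allclose(mean, patches.mean(axis=(1, 2, 3)), atol=1e-6)
        assert np.all((patches > 0) & (patches < 1))

    def test_receptive_field_geometry_at_256(self):
        disc = PatchDiscriminator(in_ch=3, base=2, rng=np.random.default_rng(0))
        logits = disc.forward(
            np.zeros((1, 1, 256, 256), np.float32),
            np.zeros((1, 2, 256, 256), np.float32),
            train=False,
        )
        assert logits.shape == (1, 1, 30, 30)

    def test_deterministic(self, rng):
        disc = PatchDiscriminator(in_ch=3, base=8, rng=np.random.default_rng(3))
        cond = rng.uniform(-1, 1, (1, 1, 32, 32)).astype(np.float32)
        ab = rng.uniform(-1, 1, (1, 2, 32, 32)).astype(np.float32)
        a = disc.forward(cond, ab, train=False)
        b = disc.forward(cond, ab, train=False)
        assert np.array_equal(a, b)

    def test_misaligned_inputs_rejected(self, rng):
        disc = PatchDiscriminator(in_ch=3, base=8, rng=rng)
        with pytest.raises(ValueError):
            disc.forward(
                np.zeros((1, 1, 64, 64), np.float32),
                np.zeros((1, 2, 32, 32), np.float32),
                train=False,
            )

    def test_translation_covariance_at_patch_stride(self, rng):
        """Circularly shifting both inputs by one output stride (8 px)
        shifts the score map by one cell, away from the borders.  Checked on
        the normalization-free variant: batch statistics are global, so any
        normalized score map is only approximately covariant."""
        disc = PatchDiscriminator(in_ch=3, base=8, norm=False,
                                  rng=np.random.default_rng(5))
        cond = rng.uniform(-1, 1, (1, 1, 128, 128)).astype(np.float32)
        ab = rng.uniform(-1, 1, (1, 2, 128, 128)).astype(np.float32)
        base = disc.forward(cond, ab, train=False)
        rolled = disc.forward(
            np.roll(cond, 8, axis=3), np.roll(ab, 8, axis=3), train=False
        )
        # columns whose 70-px receptive field avoids the wrapped border strip
        np.testing.assert_allclose(
            base[0, 0, :, 3:10], rolled[0, 0, :, 4:11], atol=1e-6
        )
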