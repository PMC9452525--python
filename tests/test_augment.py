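import numpy as np
import pytest

from cryoseg import augment as ag


@pytest.fixture()
def slice_sample(rng):
    img = rng.random((24, 16, 3)).astype(np.float32)
    lab = rng.integers(0, 4, size=(24, 16)).astype(np.int16)
    return img, lab


class TestGaussianBlur:
    def test_sigma_zero_is_identity(self, slice_sample):
        img, _ = slice_sample
        np.testing.assert_array_equal(ag.gaussian_blur(img, 0.0), img)

    def test_constant_image_unchanged(self):
        img = np.full((10, 10, 3), 0.4, dtype=np.float32)
        np.testing.assert_allclose(ag.gaussian_blur(img, 0.5), 0.4, atol=1e-6)

    def test_impulse_reproduces_sampled_kernel(self):
        """Blurring an impulse must yield the (truncated, normalized)
        sampled Gaussian kernel, computed here independently."""
        sigma = 0.5
        img = np.zeros((17, 17, 1), dtype=np.float32)
        img[8, 8, 0] = 1.0
        out = ag.gaussian_blur(img, sigma)
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        k /= k.sum()
        expected = np.outer(k, k)
        got = out[8 - radius:8 + radius + 1, 8 - radius:8 + radius + 1, 0]
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_negative_sigma_rejected(self, slice_sample):
        with pytest.raises(ValueError):
            ag.gaussian_blur(slice_sample[0], -0.1)


class TestUnsharpMask:
    def test_constant_image_unchanged(self):
        img = np.full((10, 10, 3), 0.6, dtype=np.float32)
        np.testing.assert_allclose(ag.unsharp_mask(img, 5.0, 0.3), 0.6, atol=1e-5)

    def test_alpha_zero_equals_single_blur(self, slice_sample):
        img, _ = slice_sample
        np.testing.assert_allclose(
            ag.unsharp_mask(img, 0.0, 0.4),
            np.clip(ag.gaussian_blur(img, 0.4), 0, 1),
            atol=1e-6,
        )

    def test_step_edge_matches_two_pass_oracle(self):
        """Sharpening amplifies the edge overshoot; verify against a direct
        two-pass evaluation built from an explicitly sampled kernel."""
        sigma, alpha = 0.3, 2.0
        img = np.zeros((40, 8, 1), dtype=np.float32)
        img[20:, :, :] = 0.8  # step along x, constant along y

        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        k /= k.sum()

        def blur_1d(profile):
            padded = np.pad(profile, radius, mode="reflect")
            return np.convolve(padded, k, mode="valid")

        profile = img[:, 0, 0]
        b1 = blur_1d(profile)
        b2 = blur_1d(b1)
        expected = np.clip(b1 + (b1 - b2) * alpha, 0.0, 1.0)

        out = ag.unsharp_mask(img, alpha, sigma)
        np.testing.assert_allclose(out[:, 4, 0], expected, atol=1e-5)
        # the overshoot is a real overshoot
        assert out[:, 4, 0].max() > 0.8


class TestNoise:
    def test_sd_zero_identity(self, slice_sample, rng):
        img, _ = slice_sample
        np.testing.assert_array_equal(ag.add_noise(img, 0.0, rng), img)

    def test_sample_sd_matches_request(self, rng):
        img = np.full((120, 120, 3), 0.5, dtype=np.float32)
        out = ag.add_noise(img, 0.01, rng)
        measured = (out - img).std()
        assert abs(measured - 0.01) / 0.01 < 0.05
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_clipping_keeps_range(self, rng):
        img = np.ones((50, 50, 3), dtype=np.float32)
        out = ag.add_noise(img, 0.5, rng)
        assert out.max() <= 1.0


class TestBrightnessContrast:
    def test_brightness_examples(self):
        img = np.full((4, 4, 1), 0.5, dtype=np.float32)
        np.testing.assert_allclose(ag.adjust_brightness(img, 1.0), img)
        np.testing.assert_allclose(ag.adjust_brightness(img, 1.2), 0.6, rtol=1e-6)
        bright = np.full((4, 4, 1), 0.9, dtype=np.float32)
        np.testing.assert_allclose(ag.adjust_brightness(bright, 1.2), 1.0)

    def test_contrast_identity_and_constant(self, slice_sample):
        img, _ = slice_sample
        np.testing.assert_allclose(ag.adjust_contrast(img, 1.0), img, atol=1e-6)
        const = np.full((6, 6, 3), 0.3, dtype=np.float32)
        np.testing.assert_allclose(ag.adjust_contrast(const, 0.6), 0.3, atol=1e-6)

    def test_contrast_two_voxel_example(self):
        img = np.array([0.4, 0.6], dtype=np.float32).reshape(2, 1, 1)
        out = ag.adjust_contrast(img, 0.6)
        np.testing.assert_allclose(out.ravel(), [0.44, 0.56], rtol=1e-6)

    def test_per_channel_factors(self):
        img = np.full((4, 4, 3), 0.5, dtype=np.float32)
        out = ag.adjust_brightness(img, [1.0, 1.2, 0.8])
        np.testing.assert_allclose(out[0, 0], [0.5, 0.6, 0.4], rtol=1e-6)


class TestSpatialTransform:
    def test_identity(self, slice_sample):
        img, lab = slice_sample
        out_img, out_lab = ag.spatial_transform(img, lab, 0.0, 1.0)
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_lab, lab)

    def test_full_turn_is_identity(self, slice_sample):
        img, lab = slice_sample
        out_img, out_lab = ag.spatial_transform(img, lab, 360.0, 1.0)
        assert np.abs(out_img - img).max() < 1e-6
        np.testing.assert_array_equal(out_lab, lab)

    def test_label_value_closure(self, slice_sample):
        img, lab = slice_sample
        _, out_lab = ag.spatial_transform(img, lab, 17.0, 0.95)
        assert set(np.unique(out_lab)) <= set(np.unique(lab)) | {0}

    def test_3d_rotation_preserves_shape(self, rng):
        img = rng.random((12, 10, 6, 3)).astype(np.float32)
        lab = rng.integers(0, 3, size=(12, 10, 6)).astype(np.int16)
        out_img, out_lab = ag.spatial_transform(img, lab, 8.0, 1.05)
        assert out_img.shape == img.shape
        assert out_lab.shape == lab.shape

    def test_geometry_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ag.spatial_transform(
                rng.random((8, 8, 3)), np.zeros((4, 4), dtype=np.int16), 5.0, 1.0
            )


class TestStackedAugment:
    def test_p_zero_is_identity(self, slice_sample):
        img, lab = slice_sample
        cfg = ag.AugmentConfig(p_apply=0.0)
        out_img, out_lab = ag.stacked_augment(img, lab, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_lab, lab)

    def test_p_one_with_identity_ranges_is_identity(self, slice_sample):
        img, lab = slice_sample
        cfg = ag.AugmentConfig(
            p_apply=1.0, sigma_range=(0.0, 0.0), alpha_range=(0.0, 0.0),
            noise_sd_range=(0.0, 0.0), brightness_range=(1.0, 1.0),
            beta_range=(1.0, 1.0), rotation_range_deg=(0.0, 0.0),
            scale_range=(1.0, 1.0),
        )
        out_img, out_lab = ag.stacked_augment(img, lab, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(out_img, img, atol=1e-6)
        np.testing.assert_array_equal(out_lab, lab)

    def test_seed_determinism(self, slice_sample):
        img, lab = slice_sample
        cfg = ag.AugmentConfig()
        a = ag.stacked_augment(img, lab, cfg, np.random.default_rng(7))
        b = ag.stacked_augment(img, lab, cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_output_range_and_label_integrity(self, slice_sample):
        img, lab = slice_sample
        cfg = ag.AugmentConfig(p_apply=1.0, rotation_range_deg=(0.0, 0.0),
                               scale_range=(1.0, 1.0))
        out_img, out_lab = ag.stacked_augment(img, lab, cfg, np.random.default_rng(3))
        assert out_img.min() >= 0.0 and out_img.max() <= 1.0
        # intensity-only chain: label untouched
        np.testing.assert_array_equal(out_lab, lab)

    def test_equals_manual_composition_in_fixed_order(self, slice_sample):
        """With p=1 and a replayed parameter stream, the stacked engine must
        equal applying the seven operations manually in the documented order."""
        img, lab = slice_sample
        cfg = ag.AugmentConfig(p_apply=1.0)
        out_img, out_lab = ag.stacked_augment(img, lab, cfg, np.random.default_rng(11))

        r = np.random.default_rng(11)
        mi, ml = img, lab
        assert r.random() < 1
        mi, ml = ag.spatial_transform(mi, ml, r.uniform(*cfg.rotation_range_deg), 1.0)
        assert r.random() < 1
        mi, ml = ag.spatial_transform(mi, ml, 0.0, r.uniform(*cfg.scale_range))
        assert r.random() < 1
        mi = ag.adjust_brightness(mi, r.uniform(*cfg.brightness_range, size=3))
        assert r.random() < 1
        mi = ag.adjust_contrast(mi, r.uniform(*cfg.beta_range, size=3))
        assert r.random() < 1
        mi = np.clip(ag.gaussian_blur(mi, r.uniform(*cfg.sigma_range)), 0, 1).astype(np.float32)
        assert r.random() < 1
        mi = ag.unsharp_mask(mi, r.uniform(*cfg.alpha_range), r.uniform(*cfg.sigma_range))
        assert r.random() < 1
        mi = ag.add_noise(mi, r.uniform(*cfg.noise_sd_range), r)

        np.testing.assert_array_equal(out_img, mi)
        np.testing.assert_array_equal(out_lab, ml)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ag.AugmentConfig(p_apply=1.5)
        with pytest.raises(ValueError):
            ag.AugmentConfig(sigma_range=(0.5, 0.1))
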