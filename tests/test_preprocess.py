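import numpy as np
import pytest

from cryoseg import preprocess as pp
from cryoseg.volio import ColorVolume, LabelMap


def _color(data, spacing=(10.0, 10.0, 40.0)):
    return ColorVolume(np.asarray(data, dtype=np.float32), spacing)


class TestDownsample:
    def test_spacing_follows_factors(self, rng):
        vol = _color(rng.random((16, 16, 8, 3)), spacing=(10, 10, 40))
        out = pp.downsample(vol, (8, 8, 4))
        assert out.spacing_um == (80.0, 80.0, 160.0)
        assert out.shape == (2, 2, 2)

    def test_identity_factors(self, rng):
        data = rng.random((6, 5, 4, 3)).astype(np.float32)
        out = pp.downsample(_color(data), (1, 1, 1))
        np.testing.assert_allclose(out.data, data)

    def test_constant_volume_stays_constant(self):
        out = pp.downsample(_color(np.full((8, 8, 8, 3), 0.25)), (2, 4, 2))
        np.testing.assert_allclose(out.data, 0.25, atol=1e-7)

    def test_block_mean_matches_manual(self, rng):
        data = rng.random((4, 4, 4, 3)).astype(np.float32)
        out = pp.downsample(_color(data), (2, 2, 2))
        manual = data.reshape(2, 2, 2, 2, 2, 2, 3).mean(axis=(1, 3, 5))
        np.testing.assert_allclose(out.data, manual, rtol=1e-6)

    def test_ceil_output_length_with_partial_block(self, rng):
        out = pp.downsample(_color(rng.random((7, 4, 4, 3))), (2, 2, 2))
        assert out.shape == (4, 2, 2)

    def test_factor_larger_than_axis_rejected(self, rng):
        with pytest.raises(ValueError):
            pp.downsample(_color(rng.random((4, 4, 4, 3))), (8, 1, 1))

    def test_label_majority_vote(self):
        lab = np.zeros((4, 4, 4), dtype=np.int16)
        lab[:2, :2, :2] = 3  # fills one full 2x2x2 block
        lab[2, 2, 2] = 5  # minority voxel in its block
        out = pp.downsample_labels(LabelMap(lab, (10, 10, 10)), (2, 2, 2))
        assert out.data[0, 0, 0] == 3
        assert out.data[1, 1, 1] == 0


class TestRescaleIntensity:
    def test_endpoints_and_linearity(self):
        data = np.array([[[[0.0, 128.0, 255.0]]]])
        out = pp.rescale_intensity(_color(data))
        np.testing.assert_allclose(
            out.data[0, 0, 0], [0.0, 128.0 / 255.0, 1.0], rtol=1e-6
        )

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            pp.rescale_intensity(_color(np.full((2, 2, 2, 3), -1.0)))


class TestCropToBody:
    def test_crop_matches_phantom_body_box(self, clean_phantom):
        vol, lab = clean_phantom
        body = vol.data.mean(axis=-1) > 0.05
        idx = np.nonzero(body)
        margin = 2
        cropped, clab = pp.crop_to_body(vol, lab, threshold=0.05, margin=margin)
        for ax in range(3):
            lo = max(int(idx[ax].min()) - margin, 0)
            hi = min(int(idx[ax].max()) + 1 + margin, vol.shape[ax])
            assert cropped.origin_crop[ax] == lo
            assert cropped.shape[ax] == hi - lo
        assert clab.shape == cropped.shape

    def test_crop_is_idempotent(self, clean_phantom):
        vol, _ = clean_phantom
        once, _ = pp.crop_to_body(vol, None, threshold=0.05, margin=0)
        twice, _ = pp.crop_to_body(once, None, threshold=0.05, margin=0)
        assert twice.shape == once.shape
        np.testing.assert_array_equal(twice.data, once.data)

    def test_all_background_rejected(self):
        with pytest.raises(ValueError):
            pp.crop_to_body(_color(np.zeros((8, 8, 8, 3))), None, threshold=0.1)


class TestSlices:
    def test_one_sample_per_z_and_exact_size(self, default_phantom):
        vol, lab = default_phantom
        samples = pp.make_slices(vol, lab, slice_size=(96, 32))
        assert len(samples) == vol.shape[2]
        for s in samples[:3]:
            assert s.image.shape == (96, 32, 3)
            assert s.label.shape == (96, 32)
            assert s.source_shape_xy == vol.shape[:2]

    def test_nearest_neighbour_label_closure(self, default_phantom):
        vol, lab = default_phantom
        samples = pp.make_slices(vol, lab, slice_size=(96, 32))
        for s in samples:
            src = set(np.unique(lab.data[:, :, s.z_index]).tolist())
            assert set(np.unique(s.label).tolist()) <= src

    def test_filter_keeps_only_organ_slices(self, default_phantom):
        vol, lab = default_phantom
        samples = pp.make_slices(vol, lab, slice_size=(96, 32))
        kept = pp.filter_slices(samples)
        assert 0 < len(kept) < len(samples)
        assert all((s.label > 0).any() for s in kept)
        # a single organ voxel is enough to keep a slice
        one = samples[0]
        one.label[:] = 0
        one.label[0, 0] = 3
        assert pp.filter_slices([one]) == [one]
        # idempotent
        assert pp.filter_slices(kept) == kept


class TestWhole:
    def test_exact_output_size_and_constant(self):
        vol = _color(np.full((20, 12, 8, 3), 0.5))
        lab = LabelMap(np.zeros((20, 12, 8), dtype=np.int16), vol.spacing_um)
        w = pp.make_whole(vol, lab, size=(32, 16, 8))
        assert w.image.shape == (32, 16, 8, 3)
        assert w.label.shape == (32, 16, 8)
        np.testing.assert_allclose(w.image, 0.5, atol=1e-6)
        assert w.source_shape == (20, 12, 8)

    def test_body_mask_round_trip_dice(self, default_phantom):
        from skimage.transform import resize

        from cryoseg.evaluate import dice_score

        vol, lab = default_phantom
        w = pp.make_whole(vol, lab, size=(384, 128, 64))
        back = resize(
            w.label, vol.shape, order=0, mode="edge",
            anti_aliasing=False, preserve_range=True,
        ).astype(np.int16)
        assert dice_score(lab.data > 0, back > 0) >= 0.95


class TestPatches:
    def test_corner_grid_and_padding_along_long_axis(self):
        corners, pad = pp.patch_grid((928, 96, 48), (288, 96, 48), (72, 24, 12))
        xs = sorted({c[0] for c in corners})
        assert xs == [0, 216, 432, 648]
        assert pad == (8, 0, 0)
        assert len(corners) == 4

    def test_volume_smaller_than_window_gives_single_padded_patch(self, rng):
        vol = _color(rng.random((10, 10, 6, 3)))
        lab = LabelMap(np.zeros((10, 10, 6), dtype=np.int16), vol.spacing_um)
        patches = pp.make_patches(vol, lab, window=(16, 16, 8), overlap=(4, 4, 2))
        assert len(patches) == 1
        assert patches[0].image.shape == (16, 16, 8, 3)
        assert patches[0].pad == (6, 6, 2)
        np.testing.assert_allclose(patches[0].image[10:], 0.0)

    def test_every_padded_voxel_covered(self):
        shape = (50, 30, 20)
        window, overlap = (16, 12, 8), (4, 4, 2)
        corners, pad = pp.patch_grid(shape, window, overlap)
        padded = tuple(n + p for n, p in zip(shape, pad))
        cover = np.zeros(padded, dtype=int)
        for c in corners:
            sl = tuple(slice(ci, ci + w) for ci, w in zip(c, window))
            cover[sl] += 1
        assert cover.min() >= 1
        # overlap bands are covered at least twice
        stride = tuple(w - o for w, o in zip(window, overlap))
        assert cover[stride[0], 0, 0] >= 2

    def test_overlap_must_be_smaller_than_window(self):
        with pytest.raises(ValueError):
            pp.patch_grid((64, 64, 64), (16, 16, 16), (16, 4, 4))

    def test_filter_patches_strict_threshold(self, rng):
        window = (10, 10, 10)

        def patch_with_organ_frac(frac):
            lab = np.zeros(window, dtype=np.int16)
            n = int(round(frac * lab.size))
            lab.ravel()[:n] = 4
            return pp.PatchSample(
                rng.random((*window, 3)).astype(np.float32), lab, (0, 0, 0), (0, 0, 0)
            )

        exactly_ten = patch_with_organ_frac(0.10)
        above = patch_with_organ_frac(0.101)
        all_organ = patch_with_organ_frac(1.0)
        kept = pp.filter_patches([exactly_ten, above, all_organ], min_fraction=0.10)
        assert kept == [above, all_organ]
        assert pp.filter_patches([]) == []
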