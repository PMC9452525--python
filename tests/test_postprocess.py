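import numpy as np
import pytest

from cryoseg import postprocess as post
from cryoseg import preprocess as pp
from cryoseg.volio import ColorVolume, LabelMap, ProbabilityMaps

SPACING = (80.0, 80.0, 160.0)


class TestReconstructFromSlices:
    def test_constant_slices_give_constant_volume(self):
        slices = [(np.full((8, 6, 3), 0.2, dtype=np.float32), z) for z in range(4)]
        out = post.reconstruct_from_slices(slices, (12, 9), SPACING)
        assert out.shape == (12, 9, 4)
        np.testing.assert_allclose(out.data, 0.2, atol=1e-6)

    def test_single_slice_volume(self):
        out = post.reconstruct_from_slices(
            [(np.zeros((8, 6, 2), dtype=np.float32), 0)], (8, 6), SPACING
        )
        assert out.shape == (8, 6, 1)

    def test_box_maps_back_within_one_voxel(self):
        """A probability box drawn at slice resolution must land on the
        corresponding source-resolution box after inverse resampling."""
        big, small = (32, 16), (16, 8)
        probs = np.zeros((*big, 2), dtype=np.float32)
        probs[8:24, 4:12, 1] = 1.0  # central half in both axes
        out = post.reconstruct_from_slices([(probs, 0)], small, SPACING)
        mask = out.data[:, :, 0, 1] > 0.5
        idx = np.nonzero(mask)
        lo = (idx[0].min(), idx[1].min())
        hi = (idx[0].max() + 1, idx[1].max() + 1)
        assert abs(lo[0] - 4) <= 1 and abs(lo[1] - 2) <= 1
        assert abs(hi[0] - 12) <= 1 and abs(hi[1] - 6) <= 1

    def test_missing_or_duplicate_z_rejected(self):
        s = np.zeros((4, 4, 2), dtype=np.float32)
        with pytest.raises(ValueError):
            post.reconstruct_from_slices([(s, 0), (s, 2)], (4, 4), SPACING)
        with pytest.raises(ValueError):
            post.reconstruct_from_slices([(s, 0), (s, 0)], (4, 4), SPACING)


class TestReconstructFromWhole:
    def test_identity_at_equal_shape(self, rng):
        probs = rng.random((8, 6, 4, 3)).astype(np.float32)
        out = post.reconstruct_from_whole(probs, (8, 6, 4), SPACING)
        np.testing.assert_allclose(out.data, probs, atol=1e-6)

    def test_values_stay_in_unit_range_and_constant_preserved(self, rng):
        probs = rng.random((8, 6, 4, 3)).astype(np.float32)
        out = post.reconstruct_from_whole(probs, (19, 13, 9), SPACING)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0
        const = np.full((4, 4, 4, 2), 0.7, dtype=np.float32)
        out2 = post.reconstruct_from_whole(const, (9, 9, 9), SPACING)
        np.testing.assert_allclose(out2.data, 0.7, atol=1e-6)


class TestReconstructFromPatches:
    def test_identity_on_unmodified_patches(self, rng):
        """Cutting a probability volume into overlapping patches and fusing
        them back is the exact identity (max of identical values)."""
        shape = (40, 24, 16)
        window, overlap = (16, 12, 8), (4, 4, 2)
        vol = ColorVolume(rng.random((*shape, 3)).astype(np.float32), SPACING)
        probs = rng.random((*shape, 5)).astype(np.float32)
        corners, pad = pp.patch_grid(shape, window, overlap)
        padded = np.pad(probs, [(0, pad[0]), (0, pad[1]), (0, pad[2]), (0, 0)])
        patches = []
        for c in corners:
            sl = tuple(slice(ci, ci + w) for ci, w in zip(c, window))
            patches.append((padded[sl], c))
        out = post.reconstruct_from_patches(
            patches, padded.shape[:3], pad, SPACING
        )
        np.testing.assert_array_equal(out.data, probs)

    def test_overlap_takes_maximum(self):
        patches = [
            (np.full((4, 4, 4, 1), 0.3, dtype=np.float32), (0, 0, 0)),
            (np.full((4, 4, 4, 1), 0.7, dtype=np.float32), (2, 0, 0)),
        ]
        out = post.reconstruct_from_patches(patches, (6, 4, 4), (0, 0, 0), SPACING)
        assert out.data[3, 0, 0, 0] == pytest.approx(0.7)
        assert out.data[0, 0, 0, 0] == pytest.approx(0.3)

    def test_matches_brute_force_fusion_oracle(self, rng):
        shape = (10, 8, 6)
        window, overlap = (6, 4, 4), (2, 2, 2)
        corners, pad = pp.patch_grid(shape, window, overlap)
        padded_shape = tuple(n + p for n, p in zip(shape, pad))
        patches = [(rng.random((*window, 3)).astype(np.float32), c) for c in corners]
        out = post.reconstruct_from_patches(patches, padded_shape, pad, SPACING)

        expected = np.full((*padded_shape, 3), -1.0, dtype=np.float32)
        for probs, corner in patches:
            for ix in range(window[0]):
                for iy in range(window[1]):
                    for iz in range(window[2]):
                        v = (corner[0] + ix, corner[1] + iy, corner[2] + iz)
                        expected[v] = np.maximum(expected[v], probs[ix, iy, iz])
        crop = tuple(slice(0, n) for n in shape)
        np.testing.assert_array_equal(out.data, expected[crop])

    def test_uncovered_voxel_rejected(self):
        patches = [(np.zeros((4, 4, 4, 1), dtype=np.float32), (0, 0, 0))]
        with pytest.raises(ValueError):
            post.reconstruct_from_patches(patches, (8, 4, 4), (0, 0, 0), SPACING)


class TestLabelsFromProbabilities:
    def test_one_hot_recovery(self, rng):
        labels = rng.integers(0, 11, size=(6, 5, 4)).astype(np.int16)
        probs = np.zeros((6, 5, 4, 11), dtype=np.float32)
        for c in range(11):
            probs[..., c] = labels == c
        out = post.labels_from_probabilities(ProbabilityMaps(probs, SPACING))
        np.testing.assert_array_equal(out.data, labels)

    def test_all_equal_probabilities_give_background(self):
        probs = np.full((4, 4, 2, 11), 0.3, dtype=np.float32)
        out = post.labels_from_probabilities(ProbabilityMaps(probs, SPACING))
        assert (out.data == 0).all()

    def test_matches_per_voxel_loop(self, rng):
        probs = rng.random((5, 4, 3, 11)).astype(np.float32)
        out = post.labels_from_probabilities(ProbabilityMaps(probs, SPACING))
        for x in range(5):
            for y in range(4):
                for z in range(3):
                    assert out.data[x, y, z] == int(np.argmax(probs[x, y, z]))


def _smooth_random_labels(rng, shape=(24, 20, 12), n_organs=3):
    """Blobby random label maps (smoothed noise thresholds)."""
    from scipy import ndimage

    labels = np.zeros(shape, dtype=np.int16)
    for c in range(1, n_organs + 1):
        field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.5)
        mask = field > np.quantile(field, 0.92)
        labels[mask & (labels == 0)] = c
    return LabelMap(labels, SPACING)


class TestMorphologicalClean:
    def test_interior_hole_filled(self):
        lab = np.zeros((10, 10, 6), dtype=np.int16)
        lab[2:8, 2:8, 2:5] = 4
        lab[5, 5, 3] = 0  # one-voxel interior hole
        out = post.morphological_clean(LabelMap(lab, SPACING))
        assert out.data[5, 5, 3] == 4

    def test_only_largest_component_survives(self):
        lab = np.zeros((20, 10, 8), dtype=np.int16)
        lab[1:6, 1:6, 1:5] = 2  # 100 voxels
        lab[14:15, 7:8, 5:7] = 2  # tiny distant satellite
        out = post.morphological_clean(LabelMap(lab, SPACING))
        assert (out.data[14:15, 7:8, 5:7] == 0).all()
        assert (out.data[2:5, 2:5, 2:4] == 2).all()

    def test_idempotent_on_random_blobs(self, rng):
        for _ in range(5):
            lab = _smooth_random_labels(rng)
            once = post.morphological_clean(lab)
            twice = post.morphological_clean(once)
            np.testing.assert_array_equal(twice.data, once.data)

    def test_single_component_per_organ_and_valid_classes(self, rng):
        from scipy import ndimage

        lab = _smooth_random_labels(rng, n_organs=4)
        out = post.morphological_clean(lab)
        assert set(np.unique(out.data)) <= set(range(11))
        for c in range(1, 5):
            mask = out.data == c
            if mask.any():
                _, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
                assert n == 1

    def test_empty_input_passes_through(self):
        lab = LabelMap(np.zeros((8, 8, 4), dtype=np.int16), SPACING)
        out = post.morphological_clean(lab)
        assert (out.data == 0).all()


class TestResizeLabels:
    def test_identity_at_equal_shape(self, rng):
        lab = LabelMap(rng.integers(0, 5, size=(6, 5, 4)).astype(np.int16), SPACING)
        out = post.resize_labels_to_original(lab, (6, 5, 4))
        np.testing.assert_array_equal(out.data, lab.data)

    def test_upsampling_scales_voxel_counts(self, rng):
        lab = LabelMap(rng.integers(0, 3, size=(8, 8, 8)).astype(np.int16), SPACING)
        out = post.resize_labels_to_original(lab, (16, 16, 16))
        for c in range(3):
            n_small = (lab.data == c).sum()
            n_big = (out.data == c).sum()
            assert abs(n_big - 8 * n_small) / max(8 * n_small, 1) < 0.2

    def test_class_set_never_grows(self, rng):
        lab = LabelMap(rng.integers(0, 7, size=(9, 7, 5)).astype(np.int16), SPACING)
        out = post.resize_labels_to_original(lab, (4, 3, 2))
        assert set(np.unique(out.data)) <= set(np.unique(lab.data))


def test_full_pipeline_label_range(rng):
    """reconstruct -> argmax -> clean -> resize never leaves 0..10."""
    probs = rng.random((12, 10, 8, 11)).astype(np.float32)
    pm = ProbabilityMaps(probs, SPACING)
    labels = post.labels_from_probabilities(pm)
    cleaned = post.morphological_clean(labels, pm)
    resized = post.resize_labels_to_original(cleaned, (18, 15, 12))
    assert resized.data.min() >= 0 and resized.data.max() <= 10
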