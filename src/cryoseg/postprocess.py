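"""Reconstruction of whole-mouse predictions and morphological cleaning.

Step 1 (regime-specific) rebuilds a whole-mouse probability volume: slice
predictions are resampled back to the source in-plane size and stacked;
whole-volume predictions are trilinearly resampled to the source size; patch
predictions are fused by the per-class *maximum* over all patches covering a
voxel, then the zero padding is cropped.  Step 2 assigns each voxel the class
of maximum probability (ties resolved toward the lowest class index, so
background wins a tie against any organ).  Step 3 cleans each organ mask:
per-coronal-slice 2D hole filling, 3D closing with a radius-1 ball
(3 x 3 x 3), then keep only the largest 3D connected component.  Step 4
resizes the label map back to the original whole-mouse size by nearest
neighbour.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import ball
from skimage.transform import resize

from .volio import LabelMap, ProbabilityMaps

__all__ = [
    "reconstruct_from_slices",
    "reconstruct_from_whole",
    "reconstruct_from_patches",
    "labels_from_probabilities",
    "morphological_clean",
    "resize_labels_to_original",
]


def _resize_probs(probs: np.ndarray, out_shape) -> np.ndarray:
    target = (*out_shape, probs.shape[-1])
    out = resize(
        probs.astype(np.float32), target, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def reconstruct_from_slices(
    slice_probs: list[tuple[np.ndarray, int]],
    source_shape_xy: tuple[int, int],
    spacing_um,
    origin_crop=(0, 0, 0),
) -> ProbabilityMaps:
    """Stack per-slice class probabilities back into a volume.

    ``slice_probs`` holds ``(probs_2d, z_index)`` pairs where ``probs_2d`` is
    channels-last ``(X, Y, n_classes)`` at the network slice size.  Every z
    index of the source volume must appear exactly once.
    """
    z_indices = [z for _, z in slice_probs]
    nz = len(z_indices)
    if sorted(z_indices) != list(range(nz)):
        raise ValueError(f"z indices must be 0..{nz - 1} exactly once, got {sorted(z_indices)}")
    n_classes = slice_probs[0][0].shape[-1]
    out = np.empty((*source_shape_xy, nz, n_classes), dtype=np.float32)
    for probs2d, z in slice_probs:
        out[:, :, z, :] = _resize_probs(probs2d, source_shape_xy)
    return ProbabilityMaps(out, spacing_um, origin_crop)


def reconstruct_from_whole(
    whole_probs: np.ndarray, source_shape, spacing_um, origin_crop=(0, 0, 0)
) -> ProbabilityMaps:
    """Trilinearly resample whole-volume class probabilities to source size."""
    out = _resize_probs(whole_probs, source_shape)
    return ProbabilityMaps(out, spacing_um, origin_crop)


def reconstruct_from_patches(
    patch_probs: list[tuple[np.ndarray, tuple[int, int, int]]],
    padded_shape: tuple[int, int, int],
    pad: tuple[int, int, int],
    spacing_um,
    origin_crop=(0, 0, 0),
) -> ProbabilityMaps:
    """Fuse overlapping patch probabilities by the per-class maximum.

    ``patch_probs`` holds ``(probs, corner)`` pairs with ``probs`` channels-
    last ``(wx, wy, wz, n_classes)``.  Every voxel of the padded volume must
    be covered by at least one patch; the high-end zero padding is cropped
    from the result.
    """
    if not patch_probs:
        raise ValueError("no patches given")
    n_classes = patch_probs[0][0].shape[-1]
    acc = np.full((*padded_shape, n_classes), -1.0, dtype=np.float32)
    for probs, corner in patch_probs:
        window = probs.shape[:-1]
        sl = tuple(slice(c, c + w) for c, w in zip(corner, window))
        if any(s.stop > n for s, n in zip(sl, padded_shape)):
            raise ValueError(f"patch at {corner} exceeds padded shape {padded_shape}")
        np.maximum(acc[sl], probs, out=acc[sl])
    if (acc < 0).any():
        raise ValueError("patch tiling does not cover the padded volume")
    crop = tuple(slice(0, n - p) for n, p in zip(padded_shape, pad))
    return ProbabilityMaps(acc[crop], spacing_um, origin_crop)


def labels_from_probabilities(probs: ProbabilityMaps) -> LabelMap:
    """Per-voxel argmax over class channels; ties go to the lowest index."""
    data = probs.data
    labels = np.argmax(data, axis=-1).astype(np.int16)  # argmax takes first max
    return LabelMap(labels, probs.spacing_um, probs.origin_crop)


def _clean_mask(mask: np.ndarray, struct: np.ndarray, connectivity: int) -> np.ndarray:
    if not mask.any():
        return mask
    # 2D hole filling slice by slice in the coronal (x, y) plane
    filled = np.empty_like(mask)
    for z in range(mask.shape[2]):
        filled[:, :, z] = ndimage.binary_fill_holes(mask[:, :, z])
    # 3D closing with a radius-1 ball (3 x 3 x 3 structuring element)
    closed = ndimage.binary_closing(filled, structure=struct)
    # keep only the largest 3D connected component
    comp = cc_label(closed, connectivity=connectivity)
    if comp.max() == 0:
        return np.zeros_like(mask)
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    return comp == sizes.argmax()


def morphological_clean(
    labels: LabelMap,
    probs: ProbabilityMaps | None = None,
    connectivity: int = 3,
) -> LabelMap:
    """Clean each organ label independently, then rebuild the label map.

    Per organ class 1..10 in index order: 2D hole fill per coronal slice,
    3D ball(1) closing, largest connected component.  Because closing can
    expand masks, a voxel may be claimed by two cleaned organs: the conflict
    is resolved by the higher pre-cleaning probability when ``probs`` is
    given, else by the lower class index.
    """
    struct = ball(1)
    data = labels.data
    classes = [c for c in range(1, int(data.max()) + 1)]
    cleaned = {c: _clean_mask(data == c, struct, connectivity) for c in classes}

    out = np.zeros_like(data)
    claimed = np.zeros(data.shape, dtype=bool)
    for c in classes:  # increasing class index: first claim wins ties
        mask = cleaned[c]
        new = mask & ~claimed
        conflict = mask & claimed
        out[new] = c
        claimed |= mask
        if conflict.any() and probs is not None:
            # give the voxel to whichever organ had the higher probability
            ix, iy, iz = np.nonzero(conflict)
            cur = out[ix, iy, iz].astype(np.intp)
            better = probs.data[ix, iy, iz, c] > probs.data[ix, iy, iz, cur]
            out[ix[better], iy[better], iz[better]] = c
    return labels.with_data(out)


def resize_labels_to_original(labels: LabelMap, target_shape) -> LabelMap:
    """Nearest-neighbour resample of a label map to the original size."""
    out = resize(
        labels.data, tuple(target_shape), order=0, mode="edge",
        anti_aliasing=False, preserve_range=True,
    ).astype(labels.data.dtype)
    return labels.with_data(out)
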