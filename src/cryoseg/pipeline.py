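"""End-to-end inference: regime-specific prediction of a whole mouse.

Each ``predict_*`` function chains the preprocessing of its input regime,
per-sample network inference, the matching reconstruction, argmax labeling
and morphological cleaning, returning a cleaned whole-mouse label map plus
the reconstructed probability volume.
"""

from __future__ import annotations

import numpy as np

from . import postprocess, preprocess
from .volio import ColorVolume, LabelMap, ProbabilityMaps

__all__ = ["predict_slices", "predict_whole", "predict_patches"]


def _finalize(probs: ProbabilityMaps, clean: bool) -> tuple[LabelMap, ProbabilityMaps]:
    labels = postprocess.labels_from_probabilities(probs)
    if clean:
        labels = postprocess.morphological_clean(labels, probs)
    return labels, probs


def predict_slices(
    model,
    vol: ColorVolume,
    slice_size: tuple[int, int] = preprocess.DEFAULT_SLICE_SIZE,
    clean: bool = True,
) -> tuple[LabelMap, ProbabilityMaps]:
    """Slice the volume coronally, segment each slice, restack and clean."""
    dummy = LabelMap(np.zeros(vol.shape, dtype=np.int16), vol.spacing_um)
    samples = preprocess.make_slices(vol, dummy, slice_size)
    slice_probs = [(model.predict_probs(s.image), s.z_index) for s in samples]
    probs = postprocess.reconstruct_from_slices(
        slice_probs, samples[0].source_shape_xy, vol.spacing_um, vol.origin_crop
    )
    return _finalize(probs, clean)


def predict_whole(
    model,
    vol: ColorVolume,
    size: tuple[int, int, int] = preprocess.DEFAULT_WHOLE_SIZE,
    clean: bool = True,
) -> tuple[LabelMap, ProbabilityMaps]:
    """Segment the downsampled whole volume and resample back."""
    dummy = LabelMap(np.zeros(vol.shape, dtype=np.int16), vol.spacing_um)
    sample = preprocess.make_whole(vol, dummy, size)
    whole_probs = model.predict_probs(sample.image)
    probs = postprocess.reconstruct_from_whole(
        whole_probs, sample.source_shape, vol.spacing_um, vol.origin_crop
    )
    return _finalize(probs, clean)


def predict_patches(
    model,
    vol: ColorVolume,
    window: tuple[int, int, int] = preprocess.DEFAULT_PATCH_WINDOW,
    overlap: tuple[int, int, int] = preprocess.DEFAULT_PATCH_OVERLAP,
    clean: bool = True,
) -> tuple[LabelMap, ProbabilityMaps]:
    """Sliding-window inference fused by the per-class maximum."""
    dummy = LabelMap(np.zeros(vol.shape, dtype=np.int16), vol.spacing_um)
    samples = preprocess.make_patches(vol, dummy, window, overlap)
    patch_probs = [(model.predict_probs(s.image), s.corner) for s in samples]
    pad = samples[0].pad
    padded_shape = tuple(n + p for n, p in zip(vol.shape, pad))
    probs = postprocess.reconstruct_from_patches(
        patch_probs, padded_shape, pad, vol.spacing_um, vol.origin_crop
    )
    return _finalize(probs, clean)
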