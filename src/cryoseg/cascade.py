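"""Two-stage cascade for small, poorly contrasted organs (bladder fix).

A first-stage whole-mouse prediction localizes the organ with a bounding
box; the color crop inside that box is resampled to a fixed small size
(64 x 64 x 16 by default) and re-segmented by a dedicated 3D U-Net trained
binary (organ vs everything else).  The refined mask is mapped back into the
whole-mouse label map, replacing only that organ's stage-1 voxels and never
overwriting other organs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .volio import ColorVolume, LabelMap

__all__ = [
    "DEFAULT_STAGE2_SIZE",
    "CascadeCrop",
    "stage1_bounding_box",
    "prior_box",
    "extract_and_resample",
    "cascade_predict",
    "make_stage2_training_set",
]

logger = logging.getLogger(__name__)

DEFAULT_STAGE2_SIZE = (64, 64, 16)

Box = tuple[tuple[int, int, int], tuple[int, int, int]]  # (lo, hi), hi exclusive


@dataclass
class CascadeCrop:
    """A resampled local field of view plus what is needed to invert it."""

    image: np.ndarray  # (tx, ty, tz, 3)
    label: np.ndarray | None  # (tx, ty, tz) binary, when truth is supplied
    box: Box
    source_shape: tuple[int, int, int]


def prior_box(volume_shape: tuple[int, int, int]) -> Box:
    """Fallback field of view when stage 1 found no organ.

    The pelvic region of a head-first mouse: the posterior portion of the
    volume along x (60-95% of the extent) and the central half in y and z.
    """
    nx, ny, nz = volume_shape
    lo = (int(0.60 * nx), int(0.25 * ny), int(0.25 * nz))
    hi = (max(int(0.95 * nx), lo[0] + 1), max(int(0.75 * ny), lo[1] + 1),
          max(int(0.75 * nz), lo[2] + 1))
    return lo, hi


def stage1_bounding_box(
    stage1_labels: LabelMap, organ: int, margin: int = 4
) -> Box:
    """Tight box of the organ's stage-1 mask, grown by ``margin`` and clipped.

    If stage 1 predicted no voxel of the organ, a fixed prior box covering
    the pelvic region is returned (with a logged warning) so that stage 2
    always has a field of view to refine.
    """
    mask = stage1_labels.data == organ
    shape = stage1_labels.shape
    if not mask.any():
        logger.warning(
            "organ %d absent from stage-1 prediction; falling back to prior box",
            organ,
        )
        return prior_box(shape)
    idx = np.nonzero(mask)
    lo = tuple(max(int(a.min()) - margin, 0) for a in idx)
    hi = tuple(min(int(a.max()) + 1 + margin, n) for a, n in zip(idx, shape))
    return lo, hi


def extract_and_resample(
    vol: ColorVolume,
    label: LabelMap | None,
    box: Box,
    organ: int | None = None,
    target_size: tuple[int, int, int] = DEFAULT_STAGE2_SIZE,
) -> CascadeCrop:
    """Crop the box and resample it to the stage-2 input size.

    The image is interpolated linearly, the label (binarized to the target
    organ when ``organ`` is given) by nearest neighbour.  The box and its
    original shape are retained so predictions can be mapped back exactly.
    """
    lo, hi = box
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    img = vol.data[sl]
    source_shape = img.shape[:3]
    out_img = resize(
        img.astype(np.float32), (*target_size, img.shape[-1]), order=1,
        mode="edge", anti_aliasing=False, preserve_range=True,
    )
    out_img = np.clip(out_img, 0.0, 1.0).astype(np.float32)
    out_lab = None
    if label is not None:
        lab = label.data[sl]
        if organ is not None:
            lab = (lab == organ).astype(np.int16)
        out_lab = resize(
            lab, target_size, order=0, mode="edge",
            anti_aliasing=False, preserve_range=True,
        ).astype(np.int16)
    return CascadeCrop(out_img, out_lab, box, source_shape)


def make_stage2_training_set(
    cohort: list[tuple[ColorVolume, LabelMap]],
    organ: int,
    margin: int = 4,
    target_size: tuple[int, int, int] = DEFAULT_STAGE2_SIZE,
    n_jitter: int = 3,
    max_margin: int = 24,
    include_prior_box: bool = True,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Local training crops for stage 2 from ground-truth organ boxes.

    Each mouse contributes one crop around the true organ box, ``n_jitter``
    crops with per-side margins drawn up to ``max_margin`` voxels, and (by
    default) one crop of the fixed prior fallback box — together emulating
    the box distribution stage 1 delivers at inference time, from tight
    localizations to the wide fallback field of view.  Labels are binarized
    to organ-vs-rest.
    """
    rng = np.random.default_rng(seed)
    samples = []
    for vol, lab in cohort:
        mask = lab.data == organ
        if not mask.any():
            continue
        idx = np.nonzero(mask)
        shape = lab.shape
        boxes = []
        for j in range(n_jitter + 1):
            if j == 0:
                margins = np.full(6, margin)
            else:
                margins = rng.integers(1, max_margin + 1, size=6)
            lo = tuple(max(int(a.min()) - int(m), 0) for a, m in zip(idx, margins[:3]))
            hi = tuple(min(int(a.max()) + 1 + int(m), n)
                       for a, m, n in zip(idx, margins[3:], shape))
            boxes.append((lo, hi))
        if include_prior_box:
            boxes.append(prior_box(shape))
        for box in boxes:
            crop = extract_and_resample(vol, lab, box, organ, target_size)
            samples.append((crop.image, crop.label))
    return samples


def cascade_predict(
    vol: ColorVolume,
    stage1_labels: LabelMap,
    stage2_model,
    organ: int,
    margin: int = 4,
    target_size: tuple[int, int, int] = DEFAULT_STAGE2_SIZE,
    threshold: float = 0.5,
) -> LabelMap:
    """Refine one organ with the stage-2 model; other organs are untouched.

    ``stage2_model`` must expose ``predict_probs(image)`` returning
    channels-last class probabilities with the organ in channel 1 (binary
    head).  The stage-1 voxels of the target organ are cleared, and the
    refined mask is written back inside the box wherever no other organ
    claims the voxel.
    """
    net_cfg = getattr(getattr(stage2_model, "net", None), "config", None)
    if net_cfg is not None and net_cfg.dims != 3:
        raise ValueError("stage-2 model must be a 3D network")

    crop = extract_and_resample(vol, None,
                                stage1_bounding_box(stage1_labels, organ, margin),
                                target_size=target_size)
    probs = stage2_model.predict_probs(crop.image)  # (tx, ty, tz, 2)
    organ_prob = probs[..., 1] if probs.shape[-1] > 1 else probs[..., 0]
    mask_small = organ_prob >= threshold
    mask_box = resize(
        mask_small.astype(np.float32), crop.source_shape, order=0,
        mode="edge", anti_aliasing=False, preserve_range=True,
    ) > 0.5

    out = stage1_labels.data.copy()
    out[out == organ] = 0
    lo, hi = crop.box
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    region = out[sl]
    region[mask_box & (region == 0)] = organ
    out[sl] = region
    return stage1_labels.with_data(out)
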