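"""Downsampling, cropping and conversion into the three training regimes.

Three input regimes are produced from a cropped, intensity-rescaled
whole-mouse volume:

* ``2D-slices``   -- every coronal (x, y) slice, resampled in-plane to a
  fixed size (default 768 x 256);
* ``3D-whole``    -- the whole volume resampled to a fixed size
  (default 384 x 128 x 64);
* ``3D-patches``  -- a sliding window (default 288 x 96 x 48 with overlap
  72 x 24 x 12), the volume zero-padded at the high end so the last patch
  fits.

Training-sample filtering keeps slices with at least one organ voxel and
patches whose organ fraction strictly exceeds 10% of the patch volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .volio import ColorVolume, LabelMap

__all__ = [
    "SliceSample",
    "WholeSample",
    "PatchSample",
    "DEFAULT_SLICE_SIZE",
    "DEFAULT_WHOLE_SIZE",
    "DEFAULT_PATCH_WINDOW",
    "DEFAULT_PATCH_OVERLAP",
    "rescale_intensity",
    "downsample",
    "downsample_labels",
    "crop_to_body",
    "make_slices",
    "filter_slices",
    "make_whole",
    "make_patches",
    "filter_patches",
    "patch_grid",
]

DEFAULT_SLICE_SIZE = (768, 256)
DEFAULT_WHOLE_SIZE = (384, 128, 64)
DEFAULT_PATCH_WINDOW = (288, 96, 48)
DEFAULT_PATCH_OVERLAP = (72, 24, 12)


@dataclass
class SliceSample:
    """One coronal slice: image (X, Y, 3) at the fixed slice size."""

    image: np.ndarray
    label: np.ndarray
    z_index: int
    source_shape_xy: tuple[int, int]


@dataclass
class WholeSample:
    """The whole mouse resampled to the fixed 3D input size."""

    image: np.ndarray
    label: np.ndarray
    source_shape: tuple[int, int, int]


@dataclass
class PatchSample:
    """One sliding-window patch with its corner in the padded volume."""

    image: np.ndarray
    label: np.ndarray
    corner: tuple[int, int, int]
    pad: tuple[int, int, int]


def rescale_intensity(vol: ColorVolume) -> ColorVolume:
    """Map raw 0-255 intensities onto 0-1 by multiplying with 1/255."""
    data = np.asarray(vol.data)
    if data.size and data.min() < 0:
        raise ValueError("negative intensities: input is not on the raw 0-255 scale")
    return vol.with_data((data.astype(np.float32)) * np.float32(1.0 / 255.0))


def _block_reduce_mean(data: np.ndarray, factors) -> np.ndarray:
    """Block-average over integer factors, edge-padding to a full block."""
    pads = []
    for ax, f in enumerate(factors):
        rem = (-data.shape[ax]) % f
        pads.append((0, rem))
    pads += [(0, 0)] * (data.ndim - len(factors))
    padded = np.pad(data, pads, mode="edge")
    shape = []
    for ax, f in enumerate(factors):
        shape += [padded.shape[ax] // f, f]
    shape += list(padded.shape[len(factors):])
    view = padded.reshape(shape)
    axes = tuple(2 * i + 1 for i in range(len(factors)))
    return view.mean(axis=axes)


def downsample(vol: ColorVolume, factors: tuple[int, int, int]) -> ColorVolume:
    """Downsample by integer factors with block averaging per color channel.

    Output axis lengths are ``ceil(n / factor)`` (the trailing partial block
    is edge-padded before averaging) and the voxel spacing is multiplied by
    the factors -- e.g. factors (8, 8, 4) take 10 x 10 x 40 um spacing to
    80 x 80 x 160 um.
    """
    factors = tuple(int(f) for f in factors)
    if any(f < 1 for f in factors):
        raise ValueError("factors must be positive integers")
    for ax, f in enumerate(factors):
        if f > vol.data.shape[ax]:
            raise ValueError(f"factor {f} exceeds axis {ax} length {vol.data.shape[ax]}")
    data = _block_reduce_mean(np.asarray(vol.data, dtype=np.float32), factors)
    spacing = tuple(s * f for s, f in zip(vol.spacing_um, factors))
    return ColorVolume(data.astype(np.float32), spacing, vol.origin_crop)


def downsample_labels(label: LabelMap, factors: tuple[int, int, int]) -> LabelMap:
    """Downsample a label map by per-block majority vote."""
    factors = tuple(int(f) for f in factors)
    if any(f < 1 for f in factors):
        raise ValueError("factors must be positive integers")
    data = label.data
    pads = [((0, (-data.shape[ax]) % f)) for ax, f in enumerate(factors)]
    padded = np.pad(data, pads, mode="edge")
    shape = []
    for ax, f in enumerate(factors):
        shape += [padded.shape[ax] // f, f]
    blocks = padded.reshape(shape).transpose(0, 2, 4, 1, 3, 5)
    flat = blocks.reshape(*blocks.shape[:3], -1)
    n_cls = int(data.max()) + 1
    counts = np.stack([(flat == c).sum(axis=-1) for c in range(n_cls)], axis=-1)
    out = counts.argmax(axis=-1).astype(np.int16)
    spacing = tuple(s * f for s, f in zip(label.spacing_um, factors))
    return LabelMap(out, spacing, label.origin_crop, label.class_names)


def crop_to_body(
    vol: ColorVolume,
    label: LabelMap | None = None,
    threshold: float = 0.1,
    margin: int = 2,
    min_component_vox: int = 64,
) -> tuple[ColorVolume, LabelMap | None]:
    """Crop to the tight bounding box of the foreground plus a margin.

    Foreground is where the channel-mean intensity exceeds ``threshold``;
    small speckle components are removed before the box is taken so isolated
    noise voxels do not inflate it.  ``origin_crop`` is updated so the crop
    can be undone.  The label map, if given, is cropped identically.
    """
    data = np.asarray(vol.data)
    fg = data.mean(axis=-1) > threshold
    if min_component_vox > 1 and fg.any():
        lab, n = ndimage.label(fg)
        sizes = np.bincount(lab.ravel())
        keep = sizes >= min_component_vox
        keep[0] = False
        if keep.any():
            fg = keep[lab]
    if not fg.any():
        raise ValueError("no foreground above threshold: cannot crop")
    idx = np.nonzero(fg)
    lo = [max(int(a.min()) - margin, 0) for a in idx]
    hi = [min(int(a.max()) + 1 + margin, data.shape[i]) for i, a in enumerate(idx)]
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    origin = tuple(o + l for o, l in zip(vol.origin_crop, lo))
    out_vol = ColorVolume(data[sl], vol.spacing_um, origin)
    out_lab = None
    if label is not None:
        out_lab = LabelMap(label.data[sl], label.spacing_um, origin, label.class_names)
    return out_vol, out_lab


def _resize_image(img: np.ndarray, out_shape) -> np.ndarray:
    """Linear resample of a channels-last image to out_shape (spatial only)."""
    target = (*out_shape, img.shape[-1])
    out = resize(
        img.astype(np.float32), target, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _resize_label(lab: np.ndarray, out_shape) -> np.ndarray:
    out = resize(
        lab, out_shape, order=0, mode="edge", anti_aliasing=False, preserve_range=True,
    )
    return np.rint(out).astype(np.int16)


def make_slices(
    vol: ColorVolume, label: LabelMap, slice_size: tuple[int, int] = DEFAULT_SLICE_SIZE
) -> list[SliceSample]:
    """Cut the volume into coronal slices resampled in-plane to slice_size.

    The image is interpolated linearly, the label by nearest neighbour; the
    original in-plane size is recorded for exact inversion.  The in-plane
    aspect ratio is not preserved: slices are stretched to the target size.
    """
    nx, ny, nz = vol.shape
    samples = []
    for z in range(nz):
        img = _resize_image(vol.data[:, :, z, :], slice_size)
        lab = _resize_label(label.data[:, :, z], slice_size)
        samples.append(SliceSample(img, lab, z, (nx, ny)))
    return samples


def filter_slices(samples: list[SliceSample]) -> list[SliceSample]:
    """Keep slices with at least one voxel of any organ of interest."""
    return [s for s in samples if (s.label > 0).any()]


def make_whole(
    vol: ColorVolume, label: LabelMap, size: tuple[int, int, int] = DEFAULT_WHOLE_SIZE
) -> WholeSample:
    """Resample the whole mouse to the fixed 3D input size."""
    img = _resize_image(vol.data, size)
    lab = _resize_label(label.data, size)
    return WholeSample(img, lab, vol.shape)


def patch_grid(
    shape: tuple[int, int, int],
    window: tuple[int, int, int],
    overlap: tuple[int, int, int],
) -> tuple[list[tuple[int, int, int]], tuple[int, int, int]]:
    """Sliding-window corner grid and high-end zero padding.

    Per axis, stride = window - overlap and corners sit at multiples of the
    stride starting at 0; the volume is padded at the high end so the last
    patch fits.  Returns (corners, pad).
    """
    window = tuple(int(w) for w in window)
    overlap = tuple(int(o) for o in overlap)
    if any(o >= w for o, w in zip(overlap, window)):
        raise ValueError("overlap must be smaller than window on every axis")
    strides = tuple(w - o for w, o in zip(window, overlap))
    axes_corners = []
    pad = []
    for n, w, s in zip(shape, window, strides):
        if n <= w:
            corners = [0]
        else:
            count = int(np.ceil((n - w) / s)) + 1
            corners = [i * s for i in range(count)]
        axes_corners.append(corners)
        pad.append(max(corners[-1] + w - n, 0))
    all_corners = [
        (cx, cy, cz)
        for cx in axes_corners[0]
        for cy in axes_corners[1]
        for cz in axes_corners[2]
    ]
    return all_corners, tuple(pad)


def make_patches(
    vol: ColorVolume,
    label: LabelMap,
    window: tuple[int, int, int] = DEFAULT_PATCH_WINDOW,
    overlap: tuple[int, int, int] = DEFAULT_PATCH_OVERLAP,
) -> list[PatchSample]:
    """Cut the volume into overlapping patches of fixed window size.

    The parent volume is zero-padded at the high end so every patch has the
    full window size; the union of patches covers the padded volume.
    """
    corners, pad = patch_grid(vol.shape, window, overlap)
    img = np.pad(vol.data, [(0, pad[0]), (0, pad[1]), (0, pad[2]), (0, 0)])
    lab = np.pad(label.data, [(0, p) for p in pad])
    samples = []
    for c in corners:
        sl = tuple(slice(ci, ci + w) for ci, w in zip(c, window))
        samples.append(PatchSample(img[sl], lab[sl], c, pad))
    return samples


def filter_patches(
    samples: list[PatchSample], min_fraction: float = 0.10
) -> list[PatchSample]:
    """Keep patches whose organ-voxel fraction strictly exceeds min_fraction."""
    kept = []
    for s in samples:
        frac = float((s.label > 0).mean())
        if frac > min_fraction:
            kept.append(s)
    return kept
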