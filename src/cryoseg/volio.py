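"""Core volume containers and NIfTI-1 input/output.

Axis convention used throughout the package: array index order is
``(x, y, z)`` where ``x`` is the head-to-tail long axis of the mouse and
``z`` is the sectioning axis.  A *coronal slice* is the ``(x, y)`` plane at a
fixed ``z``.  Color volumes are stored channels-last, ``(x, y, z, 3)``;
probability stacks likewise, ``(x, y, z, n_classes)``.

Voxel spacing is carried in micrometres.  On disk (NIfTI header zooms) it is
recorded in millimetres, the unit NIfTI viewers expect.  Crop offsets and the
organ name list do not fit naturally in a NIfTI header, so they travel in a
small JSON sidecar ``<stem>.meta.json`` next to the image file.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "CLASS_NAMES",
    "N_CLASSES",
    "ColorVolume",
    "LabelMap",
    "ProbabilityMaps",
    "read_volume",
    "write_volume",
    "VolumeFormatError",
]

#: Fixed organ order: index in this tuple == integer label in a LabelMap.
CLASS_NAMES: tuple[str, ...] = (
    "background",
    "brain",
    "thymus",
    "lung",
    "heart",
    "liver",
    "stomach",
    "spleen",
    "left kidney",
    "right kidney",
    "bladder",
)

#: Ten organs plus background.
N_CLASSES: int = len(CLASS_NAMES)


class VolumeFormatError(ValueError):
    """Raised when a file or array does not match the expected volume layout."""


def _check_spacing(spacing_um) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_um)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing_um must be 3 positive values, got {spacing_um!r}")
    return spacing


@dataclass
class ColorVolume:
    """3D RGB image volume, channels-last ``(x, y, z, 3)``.

    ``data`` holds intensities either on the raw 0-255 camera scale or on the
    normalized 0-1 scale (after :func:`cryoseg.preprocess.rescale_intensity`).
    ``origin_crop`` is the voxel offset of this (possibly cropped) volume
    inside its parent full volume, used to undo cropping.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    origin_crop: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise VolumeFormatError(
                f"ColorVolume data must be (x, y, z, 3), got shape {self.data.shape}"
            )
        self.spacing_um = _check_spacing(self.spacing_um)
        self.origin_crop = tuple(int(v) for v in self.origin_crop)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray) -> "ColorVolume":
        return replace(self, data=data)


@dataclass
class LabelMap:
    """Integer class volume sharing geometry with its :class:`ColorVolume`."""

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    origin_crop: tuple[int, int, int] = (0, 0, 0)
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise VolumeFormatError(f"LabelMap data must be 3D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.mod(arr, 1) == 0):
                raise VolumeFormatError("LabelMap values must be integral")
            arr = arr.astype(np.int16)
        if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES):
            raise VolumeFormatError(
                f"LabelMap values must lie in 0..{N_CLASSES - 1}, "
                f"got range [{arr.min()}, {arr.max()}]"
            )
        self.data = arr
        self.spacing_um = _check_spacing(self.spacing_um)
        self.origin_crop = tuple(int(v) for v in self.origin_crop)
        self.class_names = tuple(self.class_names)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "LabelMap":
        return replace(self, data=data)


@dataclass
class ProbabilityMaps:
    """Per-class probability stack, channels-last ``(x, y, z, n_classes)``."""

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    origin_crop: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise VolumeFormatError(
                f"ProbabilityMaps data must be (x, y, z, c), got {self.data.shape}"
            )
        if self.data.size and (self.data.min() < -1e-6 or self.data.max() > 1 + 1e-6):
            raise VolumeFormatError("probabilities must lie in [0, 1]")
        self.spacing_um = _check_spacing(self.spacing_um)
        self.origin_crop = tuple(int(v) for v in self.origin_crop)

    @property
    def n_classes(self) -> int:
        return self.data.shape[-1]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


# ---------------------------------------------------------------------------
# NIfTI round trip
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return path.with_name(stem + ".meta.json")


def _affine(spacing_um) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = (s / 1000.0 for s in spacing_um)
    return aff


def write_volume(vol, path) -> Path:
    """Write a volume to NIfTI-1, plus a ``<stem>.meta.json`` sidecar.

    Labels are stored losslessly as int16; color and probabilities as float32.
    ``.nii.gz`` output is gzipped with a zeroed timestamp so that re-writing
    identical content is byte-stable.
    """
    path = Path(path)
    if isinstance(vol, LabelMap):
        arr = vol.data.astype(np.int16)
        meta = {"kind": "label", "class_names": list(vol.class_names)}
    elif isinstance(vol, ColorVolume):
        arr = vol.data.astype(np.float32)
        meta = {"kind": "color", "intensity_scale": "as-stored"}
    elif isinstance(vol, ProbabilityMaps):
        arr = vol.data.astype(np.float32)
        meta = {"kind": "probability"}
    else:
        raise TypeError(f"cannot write object of type {type(vol).__name__}")
    meta["origin_crop"] = list(vol.origin_crop)
    meta["spacing_um"] = list(vol.spacing_um)

    img = nib.Nifti1Image(arr, _affine(vol.spacing_um))
    img.header.set_zooms((*(s / 1000.0 for s in vol.spacing_um), *([1.0] * (arr.ndim - 3))))
    raw = img.to_bytes()
    if path.name.endswith(".gz"):
        payload = gzip.compress(raw, mtime=0)
    elif path.name.endswith(".nii"):
        payload = raw
    else:
        raise VolumeFormatError(f"unsupported extension for {path.name}; use .nii or .nii.gz")
    path.write_bytes(payload)
    _sidecar_path(path).write_text(json.dumps(meta, indent=0, sort_keys=True))
    return path


def read_volume(path) -> ColorVolume | LabelMap | ProbabilityMaps:
    """Read a NIfTI file written by :func:`write_volume` (or any NIfTI).

    4D files with a trailing axis of length 3 parse as :class:`ColorVolume`;
    other 4D files as :class:`ProbabilityMaps`; 3D files with integral values
    as :class:`LabelMap`.  Spacing comes from the header zooms (mm, converted
    back to um); origin_crop and class names come from the sidecar when
    present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various types for bad files
        raise VolumeFormatError(f"{path} is not a readable NIfTI file: {exc}") from exc
    arr = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    spacing_um = tuple(float(z) * 1000.0 for z in zooms)

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "spacing_um" in meta:
            spacing_um = tuple(meta["spacing_um"])  # exact, header zooms are float32
    origin = tuple(meta.get("origin_crop", (0, 0, 0)))

    if arr.ndim == 4:
        if meta.get("kind") == "probability":
            return ProbabilityMaps(arr, spacing_um, origin)
        if arr.shape[-1] != 3:
            raise VolumeFormatError(
                f"4D NIfTI with trailing axis {arr.shape[-1]} is neither RGB nor "
                "a declared probability stack"
            )
        return ColorVolume(np.asarray(arr, dtype=np.float32), spacing_um, origin)
    if arr.ndim == 3:
        class_names = tuple(meta.get("class_names", CLASS_NAMES))
        return LabelMap(arr, spacing_um, origin, class_names)
    raise VolumeFormatError(f"expected a 3D or 4D NIfTI, got {arr.ndim}D in {path}")
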