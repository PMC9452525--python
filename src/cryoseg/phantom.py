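"""Synthetic whole-mouse phantom generator.

Every downstream stage of the pipeline (preprocessing, augmentation, network
training, post-processing, evaluation, the small-organ cascade and the
learning-curve study) is exercised on these phantoms, so they reproduce the
*regime* of whole-mouse color cryo-images without attempting anatomy:

* a body-shaped foreground: an elongated, tapered superellipsoid whose long
  axis is ``x`` (head-tail), mimicking the roughly 928 x 327 x 146 voxel
  aspect of a downsampled mouse;
* ten disjoint "organ" blobs of widely varying size -- from a brain-like
  ~3.5% of body volume down to a thymus-like ~0.25% -- each a rotated
  ellipsoid placed at a fixed anatomical station with per-mouse jitter;
* per-organ RGB color statistics: each organ's mean color is offset from the
  body tissue color by a configurable *contrast* (Euclidean RGB distance on
  the 0-1 scale), plus smooth speckle texture.  One organ (the bladder) gets
  near-zero contrast by default: the deliberately hard case;
* camera noise: additive Gaussian, clipped to [0, 1].

Determinism: the same :class:`PhantomSpec` (including ``seed``) always yields
bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volio import CLASS_NAMES, ColorVolume, LabelMap

__all__ = ["PhantomSpec", "PackingError", "generate_phantom", "generate_cohort"]


class PackingError(RuntimeError):
    """Organs could not be placed disjointly inside the body."""


#: Default per-organ volume fractions of the *body* volume, in label order
#: (brain .. bladder).  Sizes span >10x to mirror the large/small organ mix.
DEFAULT_SIZE_FRACTIONS: tuple[float, ...] = (
    0.020,  # brain
    0.0025,  # thymus
    0.018,  # lung
    0.010,  # heart
    0.050,  # liver
    0.015,  # stomach
    0.004,  # spleen
    0.007,  # left kidney
    0.007,  # right kidney
    0.004,  # bladder
)

#: Default color contrast of each organ against body tissue (0-1 RGB scale).
#: The bladder is near-isointense with its surroundings: the hard case.
DEFAULT_CONTRAST_LEVELS: tuple[float, ...] = (
    0.35, 0.28, 0.30, 0.30, 0.30, 0.26, 0.30, 0.30, 0.30, 0.05,
)

# Organ stations in body-box relative coordinates (x: head=0 .. tail=1).
_ORGAN_CENTERS: tuple[tuple[float, float, float], ...] = (
    (0.16, 0.50, 0.50),  # brain
    (0.29, 0.30, 0.38),  # thymus
    (0.33, 0.66, 0.58),  # lung
    (0.41, 0.34, 0.62),  # heart
    (0.50, 0.52, 0.45),  # liver
    (0.62, 0.74, 0.36),  # stomach
    (0.63, 0.24, 0.60),  # spleen
    (0.76, 0.32, 0.62),  # left kidney
    (0.76, 0.68, 0.62),  # right kidney
    (0.87, 0.50, 0.45),  # bladder
)

# Axis ratios (x:y:z) of each organ ellipsoid before jitter.
_ORGAN_AXIS_RATIOS: tuple[tuple[float, float, float], ...] = (
    (1.3, 1.0, 0.9),
    (1.2, 1.0, 0.8),
    (1.3, 1.1, 0.9),
    (1.0, 1.0, 1.0),
    (1.4, 1.4, 0.9),
    (1.2, 1.0, 0.8),
    (1.8, 0.8, 0.7),
    (1.3, 1.0, 0.8),
    (1.3, 1.0, 0.8),
    (1.0, 1.0, 0.9),
)

# Unit RGB offset directions, one per organ, pairwise well-separated so that
# organs are distinguishable by color and not only by position.
_ORGAN_COLOR_DIRS: tuple[tuple[float, float, float], ...] = (
    (+0.30, +0.55, +0.78),  # brain: pale/bluish
    (+0.70, +0.57, +0.42),  # thymus: pale tan
    (+0.45, -0.63, -0.63),  # lung: deep red
    (-0.81, -0.41, -0.41),  # heart: dark muscle
    (-0.33, -0.67, +0.67),  # liver
    (+0.82, +0.41, -0.41),  # stomach: light content
    (-0.58, -0.58, +0.58),  # spleen: dark purple
    (-0.26, +0.64, -0.72),  # left kidney
    (-0.26, +0.72, -0.64),  # right kidney
    (+0.58, +0.58, +0.58),  # bladder: slightly brighter, same hue
)

_BODY_COLOR = np.array([0.55, 0.38, 0.35], dtype=np.float64)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic mouse.

    ``shape`` defaults to 232 x 82 x 37 voxels, one quarter (per axis) of the
    median downsampled mouse, so that CPU experiments stay fast; spacing is
    scaled accordingly (4 x 80, 4 x 80, 4 x 160 um).
    """

    shape: tuple[int, int, int] = (232, 82, 37)
    spacing_um: tuple[float, float, float] = (320.0, 320.0, 640.0)
    n_organs: int = 10
    organ_size_fractions: tuple[float, ...] = DEFAULT_SIZE_FRACTIONS
    contrast_levels: tuple[float, ...] = DEFAULT_CONTRAST_LEVELS
    noise_sd: float = 0.02
    texture_amplitude: float = 0.02
    pose_rotation_deg: float = 6.0
    pose_scale_jitter: float = 0.06
    center_jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if any(s < 32 for s in self.shape):
            raise ValueError("each phantom axis must be >= 32 voxels")
        if not 1 <= self.n_organs <= 10:
            raise ValueError("n_organs must be in 1..10")
        self.organ_size_fractions = tuple(self.organ_size_fractions)[: self.n_organs]
        self.contrast_levels = tuple(self.contrast_levels)[: self.n_organs]
        if len(self.organ_size_fractions) != self.n_organs:
            raise ValueError("need one size fraction per organ")
        if len(self.contrast_levels) != self.n_organs:
            raise ValueError("need one contrast level per organ")
        if sum(self.organ_size_fractions) >= 1.0:
            raise ValueError("organ_size_fractions must sum to < 1")
        if any(c < 0 for c in self.contrast_levels):
            raise ValueError("contrast_levels must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _rotation_matrix(deg: float) -> np.ndarray:
    """In-plane (x, y) rotation; the section axis z is left untouched."""
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _body_mask(shape, rot: np.ndarray, scale: float) -> np.ndarray:
    """Tapered superellipsoid body: exponent 3 along x elongates the trunk."""
    nx, ny, nz = shape
    center = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2])
    radii = np.array([0.46 * nx, 0.40 * ny, 0.40 * nz]) * scale
    xs = np.arange(nx)[:, None, None] - center[0]
    ys = np.arange(ny)[None, :, None] - center[1]
    zs = np.arange(nz)[None, None, :] - center[2]
    # rotate grid coordinates into the body frame
    rx = rot[0, 0] * xs + rot[0, 1] * ys + rot[0, 2] * zs
    ry = rot[1, 0] * xs + rot[1, 1] * ys + rot[1, 2] * zs
    rz = rot[2, 0] * xs + rot[2, 1] * ys + rot[2, 2] * zs
    # taper: cross-section shrinks toward head and tail
    u = rx / radii[0]
    taper = 1.0 - 0.25 * np.clip(np.abs(u), 0.0, 1.0) ** 2
    f = np.abs(u) ** 3 + (ry / (radii[1] * taper)) ** 2 + (rz / (radii[2] * taper)) ** 2
    return f <= 1.0


def _ellipsoid_mask(shape, center_vox, semi_axes, rot: np.ndarray) -> np.ndarray:
    nx, ny, nz = shape
    xs = np.arange(nx)[:, None, None] - center_vox[0]
    ys = np.arange(ny)[None, :, None] - center_vox[1]
    zs = np.arange(nz)[None, None, :] - center_vox[2]
    rx = rot[0, 0] * xs + rot[0, 1] * ys + rot[0, 2] * zs
    ry = rot[1, 0] * xs + rot[1, 1] * ys + rot[1, 2] * zs
    rz = rot[2, 0] * xs + rot[2, 1] * ys + rot[2, 2] * zs
    f = (rx / semi_axes[0]) ** 2 + (ry / semi_axes[1]) ** 2 + (rz / semi_axes[2]) ** 2
    return f <= 1.0


def _semi_axes_for_volume(target_vox: float, axis_ratios) -> np.ndarray:
    """Semi-axes (a, b, c) = s * ratios with (4/3) pi a b c = target_vox."""
    q = np.asarray(axis_ratios, dtype=np.float64)
    s = (target_vox / (4.0 / 3.0 * np.pi * np.prod(q))) ** (1.0 / 3.0)
    return q * s


def generate_phantom(spec: PhantomSpec) -> tuple[ColorVolume, LabelMap]:
    """Generate one phantom mouse: an RGB volume in [0, 1] and its labels.

    Raises :class:`PackingError` if an organ cannot be placed disjointly
    inside the body after shrinking its placement jitter; organs are never
    silently overlapped.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape

    pose_rot = _rotation_matrix(rng.uniform(-spec.pose_rotation_deg, spec.pose_rotation_deg))
    pose_scale = 1.0 + rng.uniform(-spec.pose_scale_jitter, spec.pose_scale_jitter)
    body = _body_mask(shape, pose_rot, pose_scale)
    if not body.any():
        raise PackingError("body mask is empty")
    body_vox = int(body.sum())

    # body bounding box, used as the organ placement frame
    idx = np.nonzero(body)
    lo = np.array([a.min() for a in idx], dtype=np.float64)
    hi = np.array([a.max() for a in idx], dtype=np.float64)
    extent = hi - lo

    # organs share (half of) the body's anisotropy so they fit the thin z axis
    half_extent = extent / 2.0
    aniso = (half_extent / np.exp(np.mean(np.log(half_extent)))) ** 0.5

    labels = np.zeros(shape, dtype=np.int16)
    for organ in range(spec.n_organs):
        cls = organ + 1
        frac = spec.organ_size_fractions[organ]
        target = frac * body_vox
        base_center = lo + np.asarray(_ORGAN_CENTERS[organ]) * extent
        ratios = np.asarray(_ORGAN_AXIS_RATIOS[organ]) * aniso
        body_centroid = lo + 0.5 * extent
        station = base_center.copy()
        placed = False
        shrink = 1.0
        for attempt in range(30):
            jit_scale = spec.center_jitter * (1.0 + 0.5 * attempt)
            center = station + rng.uniform(-1, 1, size=3) * jit_scale * extent
            semi = _semi_axes_for_volume(target, ratios) * shrink
            rot = _rotation_matrix(rng.uniform(-12.0, 12.0))
            mask = _ellipsoid_mask(shape, center, semi, rot)
            if mask.any() and np.all(body[mask]) and np.all(labels[mask] == 0):
                labels[mask] = cls
                placed = True
                break
            if mask.any() and not np.all(body[mask]):
                # clipped by the body surface: pull toward the body centroid
                # before giving up volume
                station = station + 0.15 * (body_centroid - station)
            if attempt >= 9 and attempt % 3 == 0:
                shrink *= 0.95
        if not placed:
            raise PackingError(
                f"could not place organ {CLASS_NAMES[cls]!r} "
                f"(fraction {frac}) disjointly inside the body"
            )

    # --- color synthesis -------------------------------------------------
    color = np.zeros((*shape, 3), dtype=np.float64)
    color[body] = _BODY_COLOR
    for organ in range(spec.n_organs):
        cls = organ + 1
        offset = spec.contrast_levels[organ] * np.asarray(_ORGAN_COLOR_DIRS[organ])
        color[labels == cls] = np.clip(_BODY_COLOR + offset, 0.0, 1.0)

    if spec.texture_amplitude > 0:
        speckle = rng.standard_normal(shape)
        speckle = ndimage.gaussian_filter(speckle, sigma=1.0)
        sd = speckle.std()
        if sd > 0:
            speckle = (speckle - speckle.mean()) / sd * spec.texture_amplitude
        color[body] += speckle[body, None]
    if spec.noise_sd > 0:
        color += rng.normal(0.0, spec.noise_sd, size=color.shape)
    np.clip(color, 0.0, 1.0, out=color)

    vol = ColorVolume(color.astype(np.float32), spec.spacing_um)
    lab = LabelMap(labels, spec.spacing_um)
    return vol, lab


def generate_cohort(
    n_mice: int, spec: PhantomSpec, seed: int
) -> list[tuple[ColorVolume, LabelMap]]:
    """Generate ``n_mice`` phantoms with per-mouse pose/placement jitter.

    Per-mouse sub-seeds are drawn deterministically from ``seed``, so the
    cohort is reproducible while individual mice differ in pose, organ
    placement, texture and noise.
    """
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=n_mice)
    cohort = []
    for s in sub_seeds:
        mouse_spec = PhantomSpec(
            shape=spec.shape,
            spacing_um=spec.spacing_um,
            n_organs=spec.n_organs,
            organ_size_fractions=spec.organ_size_fractions,
            contrast_levels=spec.contrast_levels,
            noise_sd=spec.noise_sd,
            texture_amplitude=spec.texture_amplitude,
            pose_rotation_deg=spec.pose_rotation_deg,
            pose_scale_jitter=spec.pose_scale_jitter,
            center_jitter=spec.center_jitter,
            seed=int(s),
        )
        cohort.append(generate_phantom(mouse_spec))
    return cohort
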