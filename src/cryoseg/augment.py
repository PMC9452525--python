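"""Deep stacked augmentation: seven operations in a fixed order.

Each training sample passes through the ordered chain

    rotation, scaling, brightness, contrast, blurring, sharpness, add noise

with each operation applied independently with probability ``p_apply``
(default 0.5) and its parameter drawn uniformly from the configured range.
Intensity operations clip to [0, 1] and never touch the label; the two
spatial operations transform image and label with the same affine (linear
interpolation for the image, nearest neighbour for the label, zero fill).

Images are channels-last arrays: ``(x, y, 3)`` for 2D slices or
``(x, y, z, 3)`` for 3D inputs.  Blur and noise share one parameter across
channels; brightness and contrast draw an independent factor per channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "AugmentConfig",
    "gaussian_blur",
    "unsharp_mask",
    "add_noise",
    "adjust_brightness",
    "adjust_contrast",
    "spatial_transform",
    "stacked_augment",
]


@dataclass
class AugmentConfig:
    """Parameter ranges of the seven stacked augmentation operations.

    The contrast upper bound defaults to 1.05 to avoid saturating bright
    tissue; noise sd is on the normalized 0-1 intensity scale.
    """

    p_apply: float = 0.5
    sigma_range: tuple[float, float] = (0.1, 0.5)
    alpha_range: tuple[float, float] = (2.0, 10.0)
    noise_sd_range: tuple[float, float] = (0.0, 0.01)
    brightness_range: tuple[float, float] = (0.8, 1.2)
    beta_range: tuple[float, float] = (0.6, 1.05)
    rotation_range_deg: tuple[float, float] = (-10.0, 10.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_apply <= 1.0:
            raise ValueError("p_apply must be in [0, 1]")
        for name in (
            "sigma_range", "alpha_range", "noise_sd_range",
            "brightness_range", "beta_range", "rotation_range_deg", "scale_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (lo <= hi), got {(lo, hi)}")


def _spatial_sigma(img: np.ndarray, sigma: float) -> tuple[float, ...]:
    # blur spatial axes only; the trailing channel axis is left untouched
    return (*([sigma] * (img.ndim - 1)), 0.0)


def gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur with one sigma (voxels) shared by all color channels."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return img.copy()
    return ndimage.gaussian_filter(img.astype(np.float32), _spatial_sigma(img, sigma))


def unsharp_mask(img: np.ndarray, alpha: float, sigma: float) -> np.ndarray:
    """Sharpen by amplifying the detail lost to a second blur.

    I_sharpened = I_blurred + (I_blurred - I_filteredblurred) * alpha, where
    I_blurred blurs the input once with ``sigma`` and I_filteredblurred blurs
    I_blurred again with the same sigma.  Output clipped to [0, 1].
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    blurred = gaussian_blur(img, sigma)
    filtered_blurred = gaussian_blur(blurred, sigma)
    out = blurred + (blurred - filtered_blurred) * alpha
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def add_noise(img: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. Gaussian noise per voxel per channel; clip to [0, 1]."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return img.copy()
    out = img + rng.normal(0.0, sd, size=img.shape)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _per_channel_factors(factor, n_channels: int) -> np.ndarray:
    f = np.asarray(factor, dtype=np.float32).ravel()
    if f.size == 1:
        f = np.full(n_channels, f[0], dtype=np.float32)
    if f.size != n_channels:
        raise ValueError(f"need 1 or {n_channels} factors, got {f.size}")
    return f


def adjust_brightness(img: np.ndarray, factor) -> np.ndarray:
    """Multiply each channel by its factor (scalar broadcast); clip to [0, 1]."""
    f = _per_channel_factors(factor, img.shape[-1])
    return np.clip(img * f, 0.0, 1.0).astype(np.float32)


def adjust_contrast(img: np.ndarray, beta) -> np.ndarray:
    """Scale each channel's deviation from its mean by beta; clip to [0, 1].

    I_contrast = (I - mean(I)) * beta + mean(I), with mean(I) the mean of
    that color channel.
    """
    b = _per_channel_factors(beta, img.shape[-1])
    axes = tuple(range(img.ndim - 1))
    mean = img.mean(axis=axes, keepdims=True)
    out = (img - mean) * b + mean
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _affine_params(ndim_spatial: int, rotation_deg: float, scale: float):
    """Inverse affine (matrix, offset) for a center rotation+scale.

    Rotation is in the coronal (x, y) plane for both 2D and 3D inputs; the
    section axis is not tilted.
    """
    t = np.deg2rad(rotation_deg)
    c, s = np.cos(t), np.sin(t)
    rot = np.eye(ndim_spatial)
    rot[0, 0], rot[0, 1], rot[1, 0], rot[1, 1] = c, -s, s, c
    # output voxel v maps to input coordinate  center + M (v - center)
    matrix = rot.T / scale  # inverse of (scale * rot)
    return matrix


def spatial_transform(
    img: np.ndarray,
    label: np.ndarray | None,
    rotation_deg: float,
    scale: float,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Rotate/scale image and label about the center with one shared affine.

    The image is interpolated linearly per channel, the label by nearest
    neighbour; the output keeps the input size and out-of-view regions are
    filled with zeros.  Rotations that are exact multiples of 360 degrees
    with scale 1 short-circuit to the identity.
    """
    if label is not None and label.shape != img.shape[:-1]:
        raise ValueError(
            f"image spatial shape {img.shape[:-1]} != label shape {label.shape}"
        )
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if rotation_deg % 360.0 == 0.0 and scale == 1.0:
        return img.copy(), None if label is None else label.copy()

    ndim = img.ndim - 1
    matrix = _affine_params(ndim, rotation_deg, scale)
    center = (np.array(img.shape[:-1], dtype=np.float64) - 1) / 2.0
    offset = center - matrix @ center

    out_img = np.empty_like(img, dtype=np.float32)
    for ch in range(img.shape[-1]):
        out_img[..., ch] = ndimage.affine_transform(
            img[..., ch].astype(np.float32), matrix, offset=offset,
            order=1, mode="constant", cval=0.0,
        )
    np.clip(out_img, 0.0, 1.0, out=out_img)
    out_label = None
    if label is not None:
        out_label = ndimage.affine_transform(
            label, matrix, offset=offset, order=0, mode="constant", cval=0,
        ).astype(label.dtype)
    return out_img, out_label


def stacked_augment(
    image: np.ndarray,
    label: np.ndarray | None,
    config: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply the seven augmentations, each with probability ``p_apply``.

    Operations run in the fixed order rotation, scaling, brightness,
    contrast, blurring, sharpness, add-noise; parameters are drawn uniformly
    from the configured ranges only for the operations actually applied.
    Only rotation and scaling touch the label.
    """
    img = image
    lab = label
    p = config.p_apply

    if rng.random() < p:  # rotation
        deg = rng.uniform(*config.rotation_range_deg)
        img, lab = spatial_transform(img, lab, deg, 1.0)
    if rng.random() < p:  # scaling
        s = rng.uniform(*config.scale_range)
        img, lab = spatial_transform(img, lab, 0.0, s)
    if rng.random() < p:  # brightness, independent per channel
        f = rng.uniform(*config.brightness_range, size=img.shape[-1])
        img = adjust_brightness(img, f)
    if rng.random() < p:  # contrast, independent per channel
        b = rng.uniform(*config.beta_range, size=img.shape[-1])
        img = adjust_contrast(img, b)
    if rng.random() < p:  # blurring
        sigma = rng.uniform(*config.sigma_range)
        img = np.clip(gaussian_blur(img, sigma), 0.0, 1.0).astype(np.float32)
    if rng.random() < p:  # sharpness
        alpha = rng.uniform(*config.alpha_range)
        sigma = rng.uniform(*config.sigma_range)
        img = unsharp_mask(img, alpha, sigma)
    if rng.random() < p:  # add noise
        sd = rng.uniform(*config.noise_sd_range)
        img = add_noise(img, sd, rng)

    if img is image:
        img = image.copy()
    if lab is label and lab is not None:
        lab = label.copy()
    return img, lab
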