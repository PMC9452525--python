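"""Configurable 2D/3D U-Net backbone and the multi-class soft Dice loss.

One code path serves both dimensionalities: ``dims`` selects 2D or 3D
kernels, everything else (channel schedule, block layout, skip wiring) is
identical.  Encoder levels are two (conv 3, pad 1, stride 1) -> batch norm ->
ReLU stages followed by 2x max pooling; kernel counts double per level
starting from ``base_kernels``.  Decoder levels upsample by a stride-2
transposed convolution, concatenate the skip connection, and apply three
convolutions with the kernel count of the skip-connected encoder level, each
followed by batch norm and a ReLU.  Decoder normalization is required for
stability: a nine-convolution chain without it grows activations and
gradients without bound under an adaptive-step optimizer until the optimizer
state overflows and training freezes.  A final 1x1 convolution and a
per-voxel sigmoid emit one independent probability map per class; channels
are deliberately *not* softmax-normalized.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .volio import N_CLASSES

__all__ = [
    "UNetConfig",
    "UNet",
    "build_unet",
    "dice_loss",
    "dice_loss_grad",
    "macro_dice_loss",
    "macro_dice_loss_grad",
]

_EPS = 1e-6  # guards the empty-input 0/0 only; the loss itself has no epsilon term


@dataclass
class UNetConfig:
    """Topology of a U-Net: dimensionality, depth and channel schedule."""

    dims: int = 2
    depth: int = 4
    base_kernels: int = 16
    n_classes: int = N_CLASSES
    in_channels: int = 3
    kernel_size: int = 3
    input_size: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.input_size is not None:
            self.input_size = tuple(int(s) for s in self.input_size)
            if len(self.input_size) != self.dims:
                raise ValueError("input_size must have one entry per spatial dim")
            div = 2 ** (self.depth - 1)
            bad = [s for s in self.input_size if s % div]
            if bad:
                raise ValueError(
                    f"input size {self.input_size} not divisible by {div} "
                    f"(2^(depth-1)) on every axis; pooling is infeasible"
                )

    @property
    def channel_schedule(self) -> tuple[int, ...]:
        return tuple(self.base_kernels * 2**i for i in range(self.depth))


class _Block:
    """A plain sequential stack of layers with shared forward/backward."""

    def __init__(self, layers):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class UNet:
    """U-Net model; use :func:`build_unet` to construct one from a config."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, k = config.dims, config.kernel_size
        chans = config.channel_schedule

        self.encoders: list[_Block] = []
        in_ch = config.in_channels
        for ch in chans:
            self.encoders.append(
                _Block([
                    nn.ConvNd(d, in_ch, ch, k, rng), nn.BatchNorm(ch), nn.ReLU(),
                    nn.ConvNd(d, ch, ch, k, rng), nn.BatchNorm(ch), nn.ReLU(),
                ])
            )
            in_ch = ch
        self.pools = [nn.MaxPool(d) for _ in range(config.depth - 1)]

        self.ups: list[nn.ConvTransposeNd] = []
        self.decoders: list[_Block] = []
        for lvl in range(config.depth - 1):
            ch_skip = chans[lvl]
            ch_deep = chans[lvl + 1]
            self.ups.append(nn.ConvTransposeNd(d, ch_deep, ch_skip, rng))
            self.decoders.append(
                _Block([
                    nn.ConvNd(d, 2 * ch_skip, ch_skip, k, rng), nn.BatchNorm(ch_skip), nn.ReLU(),
                    nn.ConvNd(d, ch_skip, ch_skip, k, rng), nn.BatchNorm(ch_skip), nn.ReLU(),
                    nn.ConvNd(d, ch_skip, ch_skip, k, rng), nn.BatchNorm(ch_skip), nn.ReLU(),
                ])
            )
        self.head = nn.ConvNd(d, chans[0], config.n_classes, 1, rng)
        self.out_act = nn.Sigmoid()
        self._skip_channels = chans

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[nn.Param]:
        out = []
        for enc in self.encoders:
            out += enc.params()
        for up, dec in zip(self.ups, self.decoders):
            out += up.params()
            out += dec.params()
        out += self.head.params()
        return out

    def _batchnorms(self) -> list[nn.BatchNorm]:
        layers = []
        for block in self.encoders + self.decoders:
            layers += [l for l in block.layers if isinstance(l, nn.BatchNorm)]
        return layers

    def named_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        for i, p in enumerate(self.params()):
            arrays[f"param_{i:04d}"] = p.value
        for i, bn in enumerate(self._batchnorms()):
            arrays[f"bn_{i:04d}_mean"] = bn.running_mean
            arrays[f"bn_{i:04d}_var"] = bn.running_var
        return arrays

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_arrays().items()}

    def set_weights(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            src = arrays[f"param_{i:04d}"]
            if src.shape != p.value.shape:
                raise ValueError(f"weight {i} shape mismatch: {src.shape} vs {p.value.shape}")
            p.value[...] = src
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = arrays[f"bn_{i:04d}_mean"]
            bn.running_var[...] = arrays[f"bn_{i:04d}_var"]

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path, **self.named_arrays())
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path) -> "UNet":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        if cfg.get("input_size") is not None:
            cfg["input_size"] = tuple(cfg["input_size"])
        model = cls(UNetConfig(**cfg))
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
            model.set_weights({k: data[k] for k in data.files})
        return model

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != self.config.dims + 2:
            raise ValueError(
                f"expected (N, C, {'X, Y' if self.config.dims == 2 else 'X, Y, Z'}) "
                f"input, got shape {x.shape}"
            )
        div = 2 ** (self.config.depth - 1)
        bad = [s for s in x.shape[2:] if s % div]
        if bad:
            raise ValueError(
                f"input spatial shape {x.shape[2:]} not divisible by {div} per axis"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Return per-class probabilities, shape ``(N, n_classes, *spatial)``."""
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        h = x
        for lvl, enc in enumerate(self.encoders):
            h = enc.forward(h, train)
            if lvl < len(self.pools):
                skips.append(h)
                h = self.pools[lvl].forward(h, train)
        for lvl in reversed(range(len(self.decoders))):
            h = self.ups[lvl].forward(h, train)
            h = np.concatenate([h, skips[lvl]], axis=1)
            h = self.decoders[lvl].forward(h, train)
        logits = self.head.forward(h, train)
        return self.out_act.forward(logits, train)

    def backward(self, dprobs: np.ndarray) -> None:
        """Accumulate parameter gradients for the last ``forward(train=True)``."""
        g = self.out_act.backward(dprobs)
        g = self.head.backward(g)
        skip_grads: dict[int, np.ndarray] = {}
        for lvl in range(len(self.decoders)):
            g = self.decoders[lvl].backward(g)
            ch = self._skip_channels[lvl]
            g_up, g_skip = g[:, :ch], g[:, ch:]
            skip_grads[lvl] = g_skip
            g = self.ups[lvl].backward(np.ascontiguousarray(g_up))
        g = self.encoders[-1].backward(g)
        for lvl in reversed(range(len(self.pools))):
            g = self.pools[lvl].backward(g)
            g = g + skip_grads[lvl]
            g = self.encoders[lvl].backward(g)


def build_unet(config: UNetConfig) -> UNet:
    """Build a U-Net from its config (raises if pooling is infeasible)."""
    return UNet(config)


def _dice_terms(R: np.ndarray, P: np.ndarray) -> tuple[float, float]:
    if R.shape != P.shape:
        raise ValueError(f"shape mismatch: R {R.shape} vs P {P.shape}")
    if P.size and (P.min() < -1e-6 or P.max() > 1 + 1e-6):
        raise ValueError("P must contain probabilities in [0, 1]")
    inter = float(np.sum(R.astype(np.float64) * P.astype(np.float64)))
    total = float(np.sum(R.astype(np.float64)) + np.sum(P.astype(np.float64)))
    return inter, total


def dice_loss(R: np.ndarray, P: np.ndarray) -> float:
    """Soft multi-class Dice loss, summed jointly over classes and voxels.

    ``1 - 2 * sum_i sum_v R_iv P_iv / sum_i sum_v (R_iv + P_iv)`` with R the
    one-hot ground truth (background included) and P the predicted
    probabilities.  Within a mini-batch the batch axis is treated as extra
    voxels.  A small epsilon guards the 0/0 of entirely empty inputs.
    """
    inter, total = _dice_terms(R, P)
    return 1.0 - 2.0 * inter / (total + _EPS)


def dice_loss_grad(R: np.ndarray, P: np.ndarray) -> tuple[float, np.ndarray]:
    """Dice loss and its gradient with respect to P (for training)."""
    inter, total = _dice_terms(R, P)
    B = total + _EPS
    loss = 1.0 - 2.0 * inter / B
    grad = (-2.0 * (R.astype(np.float64) * B - inter) / (B * B)).astype(np.float32)
    return loss, grad


def _macro_terms(R: np.ndarray, P: np.ndarray):
    if R.shape != P.shape:
        raise ValueError(f"shape mismatch: R {R.shape} vs P {P.shape}")
    # class axis is 1 for batches (N, C, ...) and 0 for single samples (C, ...)
    cls_axis = 1 if R.ndim >= 4 else 0
    axes = tuple(a for a in range(R.ndim) if a != cls_axis)
    R64 = R.astype(np.float64)
    P64 = P.astype(np.float64)
    A = (R64 * P64).sum(axis=axes)
    B = (R64 + P64).sum(axis=axes) + _EPS
    return A, B, cls_axis, axes


def macro_dice_loss(R: np.ndarray, P: np.ndarray) -> float:
    """Size-balanced Dice loss: the mean over classes of per-class Dice
    complements.

    Unlike the joint-ratio form of :func:`dice_loss`, every organ
    contributes equally regardless of its voxel count, which is what makes
    small structures (thymus, bladder) trainable.  This is the default
    training objective; :func:`dice_loss` remains the reported metric form.
    """
    A, B, _, _ = _macro_terms(R, P)
    return float(np.mean(1.0 - 2.0 * A / B))


def macro_dice_loss_grad(R: np.ndarray, P: np.ndarray) -> tuple[float, np.ndarray]:
    """Size-balanced Dice loss and its gradient with respect to P."""
    A, B, cls_axis, axes = _macro_terms(R, P)
    loss = float(np.mean(1.0 - 2.0 * A / B))
    n = R.shape[cls_axis]
    shape = [1] * R.ndim
    shape[cls_axis] = n
    A_b = A.reshape(shape)
    B_b = B.reshape(shape)
    grad = (-2.0 * (R.astype(np.float64) * B_b - A_b) / (B_b * B_b) / n)
    return loss, grad.astype(np.float32)
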