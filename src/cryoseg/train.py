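"""Training loop: Adam, plateau learning-rate schedule, early stopping,
and lowest-validation-loss model selection.

The schedule follows the plateau convention: a running best validation loss
is tracked with a strict "any decrease resets" rule (min-delta 0).  The
learning rate is divided by ``lr_drop_factor`` whenever the validation loss
has not decreased for ``lr_patience`` consecutive epochs; training stops when
it has not decreased for ``stop_patience`` epochs or when ``max_epochs`` is
reached, whichever comes first.  The returned weights are those of the epoch
with the lowest validation loss.  An epoch is one seeded-shuffle pass over
all (filtered) training samples; augmentation, when given, is applied to
training samples only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    UNet,
    dice_loss,
    dice_loss_grad,
    macro_dice_loss,
    macro_dice_loss_grad,
)
from .nn import Adam

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "SegmentationModel",
    "one_hot",
    "to_model_input",
    "train_model",
    "select_hyperparameters",
]


@dataclass
class TrainConfig:
    """Optimizer and schedule settings.

    The initial learning rate is the single tuned hyperparameter; the search
    grid spans 1e-4 to 1e-3 in steps of 2e-4.
    """

    initial_lr: float = 4e-4
    batch_size: int = 24
    lr_drop_factor: float = 10.0
    lr_patience: int = 10
    stop_patience: int = 15
    max_epochs: int = 200
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    loss: str = "macro_dice"  # "macro_dice" (size-balanced) or "dice" (joint ratio)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss not in ("macro_dice", "dice"):
            raise ValueError("loss must be 'macro_dice' or 'dice'")
        if self.lr_patience <= 0 or self.stop_patience <= 0:
            raise ValueError("patience values must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")


@dataclass
class TrainHistory:
    """Per-epoch curves plus the index (1-based) of the best epoch."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = 0

    @property
    def n_epochs(self) -> int:
        return len(self.val_loss)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """One-hot encode integer labels to channels-first float32."""
    out = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = labels == c
    return out


def to_model_input(image: np.ndarray) -> np.ndarray:
    """Channels-last sample image -> channels-first model input."""
    return np.ascontiguousarray(np.moveaxis(image, -1, 0), dtype=np.float32)


class SegmentationModel:
    """A U-Net bundled with its optimizer and the Dice training objective."""

    def __init__(self, net: UNet, config: TrainConfig):
        self.net = net
        self.optimizer = Adam(
            net.params(), lr=config.initial_lr,
            beta1=config.adam_beta1, beta2=config.adam_beta2,
        )
        if config.loss == "macro_dice":
            self._loss_grad, self._loss = macro_dice_loss_grad, macro_dice_loss
        else:
            self._loss_grad, self._loss = dice_loss_grad, dice_loss

    @property
    def lr(self) -> float:
        return self.optimizer.lr

    def set_lr(self, lr: float) -> None:
        self.optimizer.lr = float(lr)

    def _batch(self, images, labels):
        x = np.stack([to_model_input(im) for im in images])
        r = np.stack([one_hot(lb, self.net.config.n_classes) for lb in labels])
        return x, r

    def train_step(self, images, labels) -> float:
        x, r = self._batch(images, labels)
        probs = self.net.forward(x, train=True)
        loss, grad = self._loss_grad(r, probs)
        self.optimizer.zero_grad()
        self.net.backward(grad)
        self.optimizer.step()
        return float(loss)

    def eval_loss(self, images, labels) -> float:
        x, r = self._batch(images, labels)
        probs = self.net.forward(x, train=False)
        return float(self._loss(r, probs))

    def predict_probs(self, image: np.ndarray) -> np.ndarray:
        """Per-class probabilities for one channels-last image, channels-last."""
        x = to_model_input(image)[None]
        probs = self.net.forward(x, train=False)[0]
        return np.moveaxis(probs, 0, -1)

    def get_weights(self):
        return self.net.get_weights()

    def set_weights(self, weights) -> None:
        self.net.set_weights(weights)


def _iter_batches(n: int, batch_size: int, order: np.ndarray):
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train_model(
    model,
    train_samples: list[tuple[np.ndarray, np.ndarray]],
    val_samples: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
    augment_fn=None,
) -> tuple[dict, TrainHistory]:
    """Train until the plateau stopping rule fires; return best weights.

    ``model`` must expose ``train_step(images, labels)``,
    ``eval_loss(images, labels)``, ``set_lr``, ``get_weights`` and
    ``set_weights`` (see :class:`SegmentationModel`).  ``augment_fn`` is
    called per training sample as ``augment_fn(image, label, rng)``.
    On return the model carries the best-epoch weights.
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    lr = config.initial_lr
    model.set_lr(lr)

    best_val = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    since_best = 0

    n = len(train_samples)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for batch_idx in _iter_batches(n, config.batch_size, order):
            images, labels = [], []
            for i in batch_idx:
                img, lab = train_samples[i]
                if augment_fn is not None:
                    img, lab = augment_fn(img, lab, rng)
                images.append(img)
                labels.append(lab)
            losses.append(model.train_step(images, labels))
        train_loss = float(np.mean(losses))

        val_losses = []
        for start in range(0, len(val_samples), config.batch_size):
            chunk = val_samples[start:start + config.batch_size]
            val_losses.append(model.eval_loss([s[0] for s in chunk], [s[1] for s in chunk]))
        val_loss = float(np.mean(val_losses))

        if not np.isfinite(train_loss) or not np.isfinite(val_loss):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: train={train_loss}, val={val_loss}"
            )

        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.lr.append(lr)

        if val_loss < best_val:  # strict: any decrease resets both counters
            best_val = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1

        if since_best >= config.stop_patience:
            break
        if since_best > 0 and since_best % config.lr_patience == 0:
            lr = lr / config.lr_drop_factor
            model.set_lr(lr)

    history.best_epoch = best_epoch
    model.set_weights(best_weights)
    return best_weights, history


def select_hyperparameters(
    candidates: list[TrainConfig],
    model_factory,
    train_samples,
    val_samples,
    augment_fn=None,
) -> TrainConfig:
    """Train one model per candidate config; keep the lowest final
    validation loss.  Ties are broken toward the lower initial learning rate.
    """
    if not candidates:
        raise ValueError("need at least one candidate config")
    results = []
    for cfg in candidates:
        model = model_factory(cfg)
        _, history = train_model(model, train_samples, val_samples, cfg, augment_fn)
        results.append((min(history.val_loss), cfg.initial_lr, cfg))
    results.sort(key=lambda t: (t[0], t[1]))
    return results[0][2]
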