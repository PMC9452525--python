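"""Seeded experiment orchestration: phantom cohort -> preprocess -> train ->
predict -> evaluate, driven by a single configuration mapping (YAML-friendly)
with cross-validation fold generation.

The experiment config is intentionally small; everything defaults to the
phantom/tiny-network regime so a complete run is CPU-feasible.  Reports embed
the config and seed, making any run reproducible from its report alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import evaluate, pipeline, preprocess
from .augment import AugmentConfig, stacked_augment
from .network import UNetConfig, build_unet
from .phantom import PhantomSpec, generate_cohort
from .train import SegmentationModel, TrainConfig, train_model

__all__ = ["make_folds", "run_experiment", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_mice": 8,
    "split": [5, 1, 2],  # train / validation / test
    "phantom": {"shape": [96, 48, 32], "noise_sd": 0.02},
    "slice_size": [96, 48],
    "network": {"dims": 2, "depth": 3, "base_kernels": 8},
    "train": {"initial_lr": 4e-4, "batch_size": 8, "max_epochs": 10,
              "stop_patience": 15, "lr_patience": 10},
    "augment": {"p_apply": 0.5},
}

_ALLOWED_KEYS = set(DEFAULT_CONFIG) | {"dry_run"}


def make_folds(
    ids: list, n_folds: int, sizes: tuple[int, int, int], seed: int
) -> list[dict[str, list]]:
    """Random (non-exhaustive) folds: seeded shuffles split into disjoint
    train/validation/test id lists of the requested sizes."""
    if sum(sizes) > len(ids):
        raise ValueError(f"split sizes {sizes} exceed {len(ids)} ids")
    master = np.random.default_rng(seed)
    folds = []
    for _ in range(n_folds):
        fold_seed = int(master.integers(0, 2**31 - 1))
        order = np.random.default_rng(fold_seed).permutation(len(ids))
        a, b, c = sizes
        folds.append({
            "train": [ids[i] for i in order[:a]],
            "val": [ids[i] for i in order[a:a + b]],
            "test": [ids[i] for i in order[a + b:a + b + c]],
            "seed": fold_seed,
        })
    return folds


def _validate(config: dict) -> list[str]:
    problems = []
    unknown = set(config) - _ALLOWED_KEYS
    if unknown:
        problems.append(f"unknown config keys: {sorted(unknown)}")
    split = config.get("split", DEFAULT_CONFIG["split"])
    if len(split) != 3 or any(int(s) < 1 for s in split[:2]) or int(split[2]) < 1:
        problems.append(f"split must be three positive counts, got {split}")
    if sum(int(s) for s in split) > int(config.get("n_mice", DEFAULT_CONFIG["n_mice"])):
        problems.append("split sizes exceed n_mice")
    return problems


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_experiment(config: dict | str | Path, out_dir, dry_run: bool = False) -> dict:
    """Run the declared stages end to end; return (and write) the report.

    ``config`` may be a mapping or a path to a YAML file; missing keys fall
    back to :data:`DEFAULT_CONFIG`.  With ``dry_run`` the config is validated
    and the plan returned without any computation.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    merged = {**DEFAULT_CONFIG, **(config or {})}
    problems = _validate(merged)
    if problems:
        raise ValueError("invalid experiment config: " + "; ".join(problems))

    out_dir = Path(out_dir)
    plan = {
        "config": merged,
        "config_hash": _config_hash(merged),
        "stages": ["phantom", "preprocess", "train", "predict", "evaluate"],
    }
    if dry_run:
        return plan
    out_dir.mkdir(parents=True, exist_ok=True)

    seed = int(merged["seed"])
    spec = PhantomSpec(seed=seed, **{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in merged["phantom"].items()})
    cohort = generate_cohort(int(merged["n_mice"]), spec, seed)

    n_tr, n_va, n_te = (int(s) for s in merged["split"])
    train_mice = cohort[:n_tr]
    val_mice = cohort[n_tr:n_tr + n_va]
    test_mice = cohort[n_tr + n_va:n_tr + n_va + n_te]

    slice_size = tuple(merged["slice_size"])

    def slices_of(mice):
        out = []
        for vol, lab in mice:
            out += preprocess.filter_slices(preprocess.make_slices(vol, lab, slice_size))
        return [(s.image, s.label) for s in out]

    net_cfg = UNetConfig(seed=seed, input_size=slice_size, **merged["network"])
    train_cfg = TrainConfig(seed=seed, **merged["train"])
    model = SegmentationModel(build_unet(net_cfg), train_cfg)
    aug_cfg = AugmentConfig(**merged["augment"])

    def augment_fn(img, lab, rng):
        return stacked_augment(img, lab, aug_cfg, rng)

    _, history = train_model(
        model, slices_of(train_mice), slices_of(val_mice), train_cfg, augment_fn
    )

    metrics = []
    for vol, truth in test_mice:
        pred, _ = pipeline.predict_slices(model, vol, slice_size)
        metrics.append(evaluate.evaluate_case(pred, truth))
    summary = evaluate.summarize_cohort(metrics)
    summary.to_csv(out_dir / "metrics.csv", index=False, float_format="%.6f")

    report = {
        **plan,
        "seed": seed,
        "n_epochs": history.n_epochs,
        "best_epoch": history.best_epoch,
        "best_val_loss": min(history.val_loss),
        "median_dice": float(summary["dice_median"].median()),
        "metrics_csv": str(out_dir / "metrics.csv"),
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
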