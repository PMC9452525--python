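"""Train a small 2D U-Net on phantom slices and evaluate a held-out mouse.

A scaled-down version of the full experiment (three training mice, a few
epochs) that still exercises the complete chain: slicing, Dice-loss
training with plateau LR schedule, whole-mouse reconstruction, morphological
cleaning, and per-organ Dice/Hausdorff evaluation.  Runs a few minutes on
one CPU.
"""

from cryoseg.evaluate import evaluate_case
from cryoseg.network import UNetConfig, build_unet
from cryoseg.phantom import PhantomSpec, generate_cohort
from cryoseg.pipeline import predict_slices
from cryoseg.preprocess import filter_slices, make_slices
from cryoseg.train import SegmentationModel, TrainConfig, train_model

SLICE = (160, 64)
cohort = generate_cohort(5, PhantomSpec(), seed=11)
train_mice, val_mice, test_mice = cohort[:3], cohort[3:4], cohort[4:5]


def pairs(mice):
    out = []
    for vol, lab in mice:
        out += [(s.image, s.label)
                for s in filter_slices(make_slices(vol, lab, SLICE))]
    return out


config = UNetConfig(dims=2, depth=3, base_kernels=8, input_size=SLICE, seed=0)
schedule = TrainConfig(initial_lr=3e-3, batch_size=2, max_epochs=15, seed=0)
model = SegmentationModel(build_unet(config), schedule)
_, history = train_model(model, pairs(train_mice), pairs(val_mice), schedule)
print(f"trained {history.n_epochs} epochs, "
      f"loss {history.train_loss[0]:.3f} -> {history.train_loss[-1]:.3f}, "
      f"best epoch {history.best_epoch}")

vol, truth = test_mice[0]
pred, _ = predict_slices(model, vol, SLICE)
metrics = evaluate_case(pred, truth)
print(metrics.to_frame().to_string(index=False,
                                   float_format=lambda v: f"{v:.3f}"))
# Large organs (liver, stomach) converge first at this reduced budget; rows
# still at the Dice 0 / HD 30 mm fallback are organs the model has not yet
# captured -- with six training mice and 30 epochs (the budget used by
# scripts/acceptance.py) the median over the nine high-contrast organs
# exceeds 0.9.  The bladder stays poor regardless, because its color
# contrast is deliberately minimal: that is the case the cascade addresses.
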