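# cryoseg

Multi-organ segmentation for 3D color (RGB) whole-mouse volumes of the kind
produced by block-face cryo-imaging. The package implements the full
pipeline — preprocessing into three network input regimes, stacked
augmentation, 2D/3D U-Nets trained with a Dice objective, probability-volume
reconstruction with max-fusion of overlapping patches, morphological
cleaning, per-organ Dice/Hausdorff evaluation, a two-stage cascade for
small low-contrast organs, and learning-curve regression for sample-size
planning — together with a synthetic phantom generator so every stage can be
exercised end to end on one CPU, without any external data.

It is aimed at people building or studying whole-animal segmentation
pipelines: ten organs (brain, thymus, lung, heart, liver, stomach, spleen,
left/right kidney, bladder) plus background, volumes stored as NIfTI with
voxel spacing, organ volumes reported in mm³.

## The method in brief

Cropped, intensity-normalized volumes are converted into one of three
regimes: coronal **2D slices** (resampled to 768 × 256), a downsampled
**3D whole mouse** (384 × 128 × 64), or overlapping **3D patches**
(288 × 96 × 48 windows, 72 × 24 × 12 overlap, zero-padded tiling). A U-Net
(2D or 3D from one code path; encoder convolutions with batch norm,
channel count doubling from 16 per level, sigmoid output head with one
channel per class) is trained with the soft Dice objective

    Dice loss = 1 − 2 Σᵢ Σᵥ Rᵢᵥ Pᵢᵥ / Σᵢ Σᵥ (Rᵢᵥ + Pᵢᵥ),

where Rᵢᵥ is the one-hot truth and Pᵢᵥ the predicted probability of class
i at voxel v (n = 11 classes including background). The size-balanced
per-class mean of Dice complements is the default training gradient — see
`docs/methods.md` for why — while the joint form above is the reported
metric. Predictions are reconstructed to whole-mouse probability volumes
(per-class *maximum* across overlapping patches), labeled by argmax, and
cleaned per organ by 2D hole filling, 3D ball(1) closing, and
largest-component retention. Evaluation reports per-organ Dice and the
symmetric Hausdorff distance

    HD = max( max_{x∈BX} min_{y∈BY} d(x,y),  max_{y∈BY} min_{x∈BX} d(x,y) )

in millimetres over 6-connectivity boundary sets, with the convention that
a missing organ scores Dice 0 and HD 30 mm. A two-stage cascade re-segments
the bladder: the stage-1 prediction (or a pelvic prior box if stage 1 found
nothing) defines a local field of view, resampled to 64 × 64 × 16 and
refined by a depth-3 3D U-Net. Learning curves of Dice vs training-set size
are fitted by weighted nonlinear least squares (weights j/m) with an
exponential-log and a power-law form, selected by
AICc = 2p + 2C + 2p(p+1)/(n−p−1), and inverted for the sample size needed
to reach Dice 0.9.

## Worked example

`examples/` contains one short script per capability. Generating a phantom
and measuring its organs (`examples/01_generate_phantom.py`):

```
phantom shape (232, 82, 37), spacing (320.0, 320.0, 640.0) um
          brain:   5027 voxels =    329.4 mm^3
         thymus:    629 voxels =     41.2 mm^3
           lung:   4536 voxels =    297.3 mm^3
          heart:   2519 voxels =    165.1 mm^3
          liver:  12584 voxels =    824.7 mm^3
        stomach:   3761 voxels =    246.5 mm^3
         spleen:   1016 voxels =     66.6 mm^3
    left kidney:   1488 voxels =     97.5 mm^3
   right kidney:   1761 voxels =    115.4 mm^3
        bladder:   1009 voxels =     66.1 mm^3
```

The organ volumes span an order of magnitude — the size spread that makes
small-organ segmentation the hard part of the problem. Fitting learning
curves (`examples/05_learning_curves.py`):

```
design sizes: [63, 55, 47, 39, 31, 23, 15, 7]
easy organ: model=power, AICc=12.00, samples for Dice 0.9: 21
hard organ: model=power, AICc=12.00, samples for Dice 0.9: > 1000
```

The AICc picks the 3-parameter power law on both curves; the easy organ's
curve crosses Dice 0.9 at 21 training samples, while the hard organ's
plateaus below 0.9 and the requirement is reported as "> 1000".
`examples/04_train_and_evaluate.py` runs a scaled-down training experiment
and prints the per-organ Dice/HD table for a held-out phantom.

A thin CLI mirrors the library (`cryoseg phantom|predict|evaluate|
learncurve|experiment`); everything it does is equally scriptable through
the importable API.

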