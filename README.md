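# ki67seg

Two-stage analysis of breast diffusion-weighted MRI (DWI): an **improved
attention U-Net** segments the tumor, and a **polynomial-kernel SVM**
predicts the Ki-67 expression class (high vs low) from descriptors of the
segmented tumor and its peritumoral stroma.

Ki-67 is a nuclear proliferation antigen; a positive-cell fraction **≥ 14 %**
defines *high expression*, a marker of aggressive disease that normally
requires post-operative immunohistochemistry. Densely proliferating tumors
restrict water diffusion, so their apparent diffusion coefficient (ADC) is
lower — high-Ki-67 lesions cluster around `0.82e-3 mm²/s` versus
`0.98e-3 mm²/s` for low expression. That contrast is what makes a
non-invasive imaging prediction plausible, and what the package's phantom
generator encodes.

## What is inside

**Stage 1 — segmentation** (`ki67seg.nn`, `ki67seg.train`). A 2D U-Net
variant with:

* *recurrent-residual atrous blocks*: dilated 3×3 convolutions re-fed
  additively for `t` steps (shared weights), wrapped in an identity-mapping
  1×1 shortcut, regularized with DropBlock;
* *additive attention gates* on every skip connection,
  `α = σ(φ(SeLU(ωₓ·x + ω_g·g + b_g)) + b_φ)`, gating the skip feature `x`
  with the upsampling-path signal `g` and merging as `α⊙x + g`;
* a *residual multiscale pyramid pooling* bottleneck: adaptive pooling at
  grid scales (2, 4, 8, 16 by default), 1×1 channel reduction, bilinear
  upsampling, concatenated back onto the input features;
* encoder downsampling through two parallel branches (2×2 max-pool and a
  stride-2 convolution, summed); a sigmoid 1×1 head yields per-pixel tumor
  probabilities.

The network runs on a small in-package reverse-mode autodiff engine over
NumPy (`ki67seg.nn.autograd`) — no deep-learning framework required.

**Stage 2 — classification** (`ki67seg.classifier`). The predicted mask is
expanded by a physical **5 mm margin** (exact Euclidean distance transform,
`ki67seg.roi`) into three regions — tumor, stromal ring, combined. Each
case becomes a feature vector (per-region/per-b-value intensity statistics,
an ADC-like log-ratio `ln(S_b0/S_b850)/Δb`, shape descriptors) classified by
a soft-margin SVM with the kernel `K(x, xᵢ) = (x·xᵢ + 1)^d`.

**Evaluation** (`ki67seg.evaluation`): `DSC = 2TP/(FP+2TP+FN)`,
`PPV = TP/(TP+FP)`, `Sensitivity = TP/(TP+FN)`, macro and micro aggregation,
and improvement tables against baseline networks.

**Phantom data** (`ki67seg.synthetic`): two-b-value DWI slices
(b = 0 / 850 s/mm², mono-exponential signal `S_b = S₀·e^(−b·ADC)`) with
irregular star-convex lesions, class-conditional tumor ADC, smooth
background heterogeneity and additive noise — every stage is testable
without any clinical data.

## Worked example

```python
from ki67seg.pipeline import run_pipeline

run_dir = run_pipeline({
    "seed": 0,
    "data": {"n_high": 12, "n_low": 8, "matrix_size": 64},
    "network": {"depth": 2, "base_channels": 8, "pyramid_scales": [2, 4]},
    "train": {"epochs": 8, "batch_size": 4},
    "classifier": {"n_folds": 4, "use_true_masks": True},
}, out_dir="runs/demo")
print((run_dir / "log.txt").read_text())
```

```
[03:04:38] run start, master seed 0
[03:04:38] simulated 20 cases (12 high / 8 low)
[03:04:50] trained segmenter: best val DSC 0.9031 at epoch 7
[03:04:50] held-out segmentation: DSC 0.9031, PPV 0.8742, sensitivity 0.9390 on 4 cases
[03:04:50] Ki-67 classifier: 4-fold CV accuracy 0.9500 (majority rate 0.6000)
[03:04:50] run complete in 11.9 s
```

The held-out DSC of 0.90 means predicted tumor masks overlap the ground
truth at Dice 0.90 on the four validation cases; the classifier separates
high from low Ki-67 phantoms at 95 % cross-validated accuracy against a
60 % majority-class floor. `runs/demo/` also contains `metrics.json`
(macro and micro metrics with confusion counts), `predictions.csv`
(per-case SVM scores), and `delta_table.csv` (improvement over the
published baseline networks' metrics).

The same stages are available as a CLI:

```bash
ki67seg simulate --n-high 12 --n-low 8 --size 64 --seed 0 --out data/
ki67seg train-seg --manifest data/manifest.csv --epochs 8 --out model/
ki67seg evaluate --model model/segmenter.npz --manifest data/manifest.csv --out metrics.json
ki67seg run --config pipeline.yaml --out runs/full
```

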