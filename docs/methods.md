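# Methods

This note documents the models, defaults and design decisions behind
`ki67seg`, and states what the synthetic experiments do and do not show.

## Problem setting

Breast tumors with high Ki-67 expression (≥ 14 % positive cells) are more
proliferative, more cellular, and restrict water diffusion more strongly
than low-expressing tumors; on diffusion-weighted MRI this appears as a
lower apparent diffusion coefficient (ADC). The package implements a
two-stage pipeline: (1) segment the tumor on two-b-value DWI slices with an
attention U-Net variant; (2) predict the Ki-67 class from descriptors of
the segmented tumor and a 5 mm peritumoral stromal ring using a
polynomial-kernel SVM.

## Phantom generator

No public imaging cohort accompanies this problem, so all experiments run
on simulated phantoms that encode the study conditions:

* **Acquisition**: b = 0 and 850 s/mm², 256×256 matrix by default
  (64×64 in the desk-scale benchmarks). In-plane pixel spacing defaults to
  0.7 mm and is a free parameter — the matrix size alone fixes no physical
  geometry, and the 5 mm ROI expansion depends on it.
* **Signal model**: mono-exponential, `S_b = S₀·exp(−b·ADC)` per pixel.
* **Tumor ADC**: drawn per case from the class-conditional normals
  N(0.82e-3, 0.08e-3) for high Ki-67 and N(0.98e-3, 0.15e-3) mm²/s for
  low, clipped below at 0.1e-3 mm²/s to keep the signal model valid. These
  moments are the reported clinical contrast between the two expression
  groups; a Monte-Carlo test (500 cases/class, 3-standard-error band)
  pins the generator to them.
* **Background tissue**: ADC 1.8e-3 ± 0.2e-3 mm²/s varying as a smooth
  low-frequency random field; S₀ ≈ 60 with ±15 % smooth heterogeneity;
  tumor S₀ ≈ 85. Tumors are therefore markedly hyperintense at b = 850
  (signal ≈ 42 vs ≈ 13 for background), which is the physically expected
  DWI contrast.
* **Noise**: additive Gaussian (σ = 3 intensity units) on magnitude
  images. This is a simplification — real magnitude MRI noise is Rician —
  chosen because the downstream stages are insensitive to the difference
  at this SNR.
* **Lesion geometry**: star-convex masks — an ellipse (aspect 0.7–1.3,
  random rotation) radially perturbed by harmonics k = 2…5 with
  amplitudes up to 0.15. Area is driven into a configurable fraction of
  the image (default 1–8 %), and lesions stay clear of the border so the
  5 mm expansion fits. Nothing is claimed about real lesion shape; the
  construction only provides controllable irregularity.

What passing on phantoms does **not** show: robustness to real anatomy
(fibroglandular structure, bilateral breasts, chest wall), Rician noise,
coil inhomogeneity, motion, or inter-scanner variation. The benchmark
numbers below are properties of this generator, not clinical estimates.

## Segmentation network

* **Encoder**: `depth` groups (default 4; 3 in the benchmark) of a
  recurrent-residual atrous block followed by 2× downsampling as the sum
  of two parallel branches, 2×2 max-pool and stride-2 3×3 convolution.
* **Recurrent-residual atrous block**: a 1×1 identity-mapping shortcut
  plus a main branch with one recurrent unit per dilation rate (defaults
  (1, 2)); each unit re-feeds its output additively into the *same* 3×3
  convolution for t = 2 steps. DropBlock (block 5, keep-prob 0.9) acts on
  the main branch during training only. With all unit weights zero the
  block reduces exactly to its shortcut — a forcing property the tests
  exploit.
* **Bottleneck**: residual multiscale pyramid pooling — adaptive mean
  pooling to s×s grids (default scales 2, 4, 8, 16; mean pooling, max
  available), 1×1 reduction to C/4 channels per branch, bilinear
  upsampling, concatenation with the input features (output channels
  C + 4·C/4 = 2C). Scales must divide the bottleneck grid; configs for
  64×64 inputs at depth 3 use (2, 4, 8).
* **Attention gates**: `α = σ₂(φ(σ₁(ωₓx + ω_g g + b_g)) + b_φ)` with σ₁ =
  SeLU and σ₂ = sigmoid; the gated skip is merged additively with the
  (channel-matched, bilinearly resampled) gating signal, `x_out = α⊙x + g`.
  The printed formula's parenthesization is ambiguous; the implementation
  follows the standard additive-gate reading (1×1 maps into a common
  intermediate space, SeLU, 1×1 to one channel, sigmoid). The additive
  merge is unconventional (concatenation is the U-Net norm) but is what
  the two-term output equation states; `gate_merge: concat` is available.
* **Activations / normalization**: SeLU with LeCun-normal initialization
  throughout instead of batch normalization; self-normalizing activations
  keep the small networks trainable without running statistics, which also
  makes inference trivially deterministic.
* **Head**: 1×1 convolution + sigmoid; masks binarized at 0.5.

Channel widths, loss, optimizer and schedule have no canonical values for
this architecture family; the defaults here (base 16 channels — 8 in
benchmarks, dice+BCE loss equally weighted, Adam at 1e-3, no scheduler)
are this package's own choices. An optional
contour-weighted BCE term (off by default) up-weights boundary pixels,
since boundary contour labels are part of the data model.

The engine (`ki67seg.nn.autograd`) is a ~400-line reverse-mode autodiff
over float32 NumPy arrays: convolution is evaluated as k² shifted
tensordot contractions (BLAS-backed), bilinear resampling as two
interpolation-matrix contractions whose rows sum to 1 (constants are
preserved exactly), pooling by reshape. Gradients are checked against
finite differences in the test suite.

## Training protocol

Stratified split by Ki-67 class (default 20 % validation, ≥ 1 case per
class), random flips and 90° rotations as augmentation, per-image z-score
normalization (never dataset statistics, so inference is independent of
the training set). Every random draw — initialization, split, batch
order, augmentation, DropBlock — derives from one master seed through
named `SeedSequence` children; reruns are bit-identical. The checkpoint
with the best validation Dice is retained. A non-finite loss aborts with
the epoch number.

## ROI geometry

The peritumoral stroma is defined in physical units: all pixels whose
centre-to-centre Euclidean distance to the nearest tumor pixel is ≤ 5 mm,
minus the tumor. The implementation uses the exact Euclidean feature
transform and decides inclusion on squared distances computed from integer
pixel offsets, so it agrees *exactly* with a brute-force all-pairs oracle
(tested on hundreds of random masks, plus a 5 % analytic-annulus check).
Expansion is clipped at the image border only; excluding non-breast
background (air, chest wall) from the ring is not attempted.
Note a discrete-grid subtlety: composing a 2 mm and a 3 mm expansion is a
strict subset of a single 5 mm expansion, because intermediate points are
restricted to pixel centres; equality holds only in the continuum.

## Ki-67 classifier

What numeric representation of the "segmentation output" enters the SVM
is genuinely open; this package chooses an interpretable fixed-length
descriptor vector over flattened masks: per region (tumor / ring /
combined) × per b-value, five intensity statistics (mean, SD, 10th/50th/
90th percentiles); an ADC-like feature `mean(ln(S_b0/S_b850))/Δb` over the
tumor (exactly inverts the generator's signal model on noiseless input); a
missing-ring flag (ring features copy the tumor's when the ring is empty
at the image border); and tumor area (mm²), Crofton perimeter (mm) and
circularity 4πA/P². Features are standardized inside `fit_svm` (the
scaling is stored in the model) so kernel powers cannot overflow.

The SVM solves the usual soft-margin dual with kernel
`K(x, xᵢ) = (x·xᵢ + 1)^d`, d = 2 and C = 1 by default. The quadratic
program is delegated to scikit-learn's SVC configured to exactly this
kernel (gamma = 1, coef0 = 1); the decision function at predict time is
evaluated by this package's own kernel expansion over the stored support
vectors, and the two routes are cross-checked in the tests. Sign
convention: positive decision ≡ high Ki-67. At inference the ROIs come
from the predicted mask (the true two-stage pipeline); a ground-truth-ROI
mode isolates classifier quality, and an empty predicted mask falls back
to the reference mask (counted in the run log).

## Evaluation conventions

Undefined ratios (e.g. PPV of an empty prediction) are reported as 0 with
an explicit degenerate flag rather than dropped, keeping macro averages
total-n based. Macro (per-case mean) is the headline aggregate; micro
(pooled counts) is always attached. Improvement tables are computed in
decimal arithmetic on the printed values and rounded half-up to two
decimals, so e.g. 0.94 − 0.80 = 0.14 and 0.905 − 0.80 → 0.11.

## Benchmark sizes and expected results

The desk-scale configurations the tests and `scripts/acceptance.py` use:

* generator calibration: 500 cases per class at 32×32;
* segmentation benchmark: 200 cases (120 high / 80 low) at 64×64, depth-3
  base-8 network with pyramid scales (2, 4, 8), 30 epochs, batch 8 —
  held-out macro DSC ≈ 0.999 at seed 0 (the acceptance bar is ≥ 0.85);
* two-stage classification: a fresh 98-high / 66-low cohort segmented by
  the trained network, 5-fold CV — accuracy well above the 0.598
  majority rate (typically > 0.9 on phantoms, where the ADC contrast is
  the dominant, cleanly recoverable signal);
* pipeline determinism: a small run (14 cases, depth 2, 2 epochs)
  executed twice must produce byte-identical metric files.

These sizes were chosen so the whole suite runs in minutes on one CPU
while still exercising every stage end to end. Phantom accuracy being
near-ceiling reflects the generator's clean class signal, not expected
clinical performance — the clinical problem is far harder (overlapping
ADC distributions, annotation noise, scanner variation).

## Known limitations

* 2D slices only; no volumetric context.
* No Rician noise, bias fields, or anatomy in the phantoms.
* The NumPy engine is CPU-bound and sized for small images; it is not a
  general training framework.
* No probability calibration for the classifier; no Hausdorff or surface
  distance metrics; no significance testing between models.
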