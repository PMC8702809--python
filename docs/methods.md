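# Methods

This note records the model, the choices made where the design was open,
and what the synthetic data does and does not establish.

## Pipeline and assumptions

The system classifies every pixel of a color fundus photograph as vessel or
background.  It assumes: (i) an RGB image whose green channel carries the
best vessel/tissue contrast; (ii) a roughly disc-shaped field of view (FOV)
outside of which pixels are camera background; (iii) binary expert vessel
maps for training.  Inputs of any size are handled by padding and a sliding
window, so nothing in the model depends on the 584×584 / 605×700 benchmark
dimensions beyond the patch counts they produce.

### Preprocessing

green channel → Gaussian denoise → FOV-masked histogram equalization →
gamma transform.  Parameters and rationale:

| parameter | default | why |
|---|---|---|
| Gaussian kernel / σ | 3×3, σ = 1.0 px | smallest standard denoising kernel; larger kernels blur 1–2 px capillaries |
| gray levels L | 256 | 8-bit input |
| equalization rounding | half-up | fixed so the integer mapping is exactly reproducible |
| outside-FOV policy | set to 0 | keeps background out of the equalization statistics and out of patches |
| gamma γ, c | 1.3, 1 | γ > 1 deepens vessel contrast after equalization; applied on [0,1] intensities |

The FOV mask is taken from the dataset when present; otherwise it is
estimated by Otsu thresholding of the mean channel, keeping the largest
connected component and filling holes.  Equalization before/after ordering:
the channel is selected first, then smoothed, because denoising a single
channel is cheaper and equivalent for a channel-wise filter; this ordering
is a design choice, not externally fixed.

### Patching

Window 64, step 16.  Padding goes to the next multiple of the window; for
arbitrary sizes the grid is additionally closed so that `(dim − 64)` is a
multiple of the step (for multiples of 64 it already is, since 16 | 64).
Patch count per image is `((H_pad−64)/16 + 1)·((W_pad−64)/16 + 1)`; the
benchmark sizes give 1369 and 1517 patches per image (27,380 / 15,170 for
20 and 10 images).  Augmentation (per epoch, seeded): independent 50%
horizontal/vertical flips, rotation by a multiple of 90°, and a random crop
of ≥ 0.8 of the side resized back to 64, with labels re-binarized at 0.5.
Rotations are restricted to multiples of 90° to avoid interpolation
artifacts on binary labels; free-angle rotation was deliberately left out.
Inference reuses the training grid and averages overlapping patch
predictions before thresholding (default 0.5), which suppresses seams.

### Architecture

Encoder stages (default widths 64/128/256) each apply a residual block and
2×2 max-pool; the middle stage adds a residual attention block, the deepest
an ASPP with rates (1,2,3,4) × 128 kernels (512 channels out).  The decoder
mirrors with transposed-conv upsampling; each stage concatenates the
encoder skip *before* its residual block — with concatenation last the
decoder could not land on the 64×64×64 pre-head feature map that the design
pins down, so the standard U-Net order is used.  Three supervision heads
tap the encoder stages (scales 1, 2, 4) and upsample back to 64×64 with
transposed-conv chains that halve channels per step — the heads differ only
in chain depth, which is this package's reading of "different layers and
blocks" per head.  Weight init is He-normal; batch-norm momentum 0.1,
ε = 1e-5; dropout 0.2 between the residual convolutions; L2 (1e-4) applies
to convolution kernels only, added to the Adam gradient.

The attention mask branch is two max-pool/conv steps down and two
transposed-conv steps up, ending in a 1×1 conv and sigmoid; transposed-conv
upsampling was chosen over bilinear for consistency with the decoder.

### Loss and training

Per-batch class balance ∂ = X−/m (batch-level rather than dataset-level,
matching the per-input definition of m; dataset-level weighting is a
one-line change).  Total loss default is β·(L1+L2+L3) + L4 — weighting all
four terms by β would zero the entire loss at the final epoch and halt
learning, so the main loss keeps weight 1; a `beta-all` mode applies beta to
all four terms.  Adam β1 = 0.9, β2 = 0.999, ε = 1e-8; learning rate
0.001, batch 20; "iterates for 500 times" is read as 500 epochs, since the
β schedule indexes epochs.  A seeded 90/10 patch validation split is
available for monitoring (early stopping off by default to honor the fixed
epoch count); shuffling is global across source images each epoch.

### Numerical backend

No deep-learning framework is used: `retseg.nn` is a reverse-mode autodiff
on NumPy float32 arrays with exactly the needed operations.  Convolutions
are stride-1 "same" with odd kernels; forward uses im2col + GEMM, switching
to one-GEMM-per-kernel-tap accumulation when the im2col buffer would exceed
48 MB; the backward pass builds a single im2col of the output gradient and
reuses it for both weight and input gradients, so no forward buffers are
retained.  Interior gradients are freed as backpropagation consumes them,
bounding peak memory (≈ 1 GB for the reduced training runs).  Sigmoid
outputs are clamped to [1e-7, 1−1e-7] so probabilities stay strictly inside
(0, 1) in float32; the cross-entropy clamps at the same ε before logs.  All
gradients are validated against float64 central finite differences in the
test suite.

## Evaluation

Confusion counts, Acc/Se/Sp and ROC/AUC are computed inside the FOV mask by
default (background pixels otherwise inflate accuracy and specificity);
whole-image evaluation is available.  The ROC sweeps all distinct score
thresholds with trapezoidal integration (scikit-learn's curve), which the
tests verify equals brute-force pairwise concordance with ties counted ½.
Undefined metrics (empty class) are reported as absent rather than 0.

## Synthetic data: what it shows and what it does not

The generator emulates the geometric structure the pipeline depends on:
disc FOV on near-black background, green-dominant radially shaded tissue,
and a recursively branching tree of quadratic-Bézier vessels, 30–60% darker
than tissue in the green channel, widths decaying from ~6 px at the root to
1 px, truth re-binarized from anti-aliased stroke coverage at 0.5.  Default
(584×584) images have a vessel density of 7–9% of the FOV, within the range
of real fundus images.  It deliberately omits the optic disc, lesions,
exudates, illumination gradients beyond radial shading, and camera noise
structure — so passing tests demonstrate that the pipeline's mechanics
(preprocessing, patching, optimization, stitching, scoring) are correct and
that the network can learn curvilinear dark-on-bright structures, not that
benchmark-level accuracy transfers to real pathology-bearing
images.

## Problem sizes used in tests and the acceptance script

Reduced-scale runs use stage widths (8, 16, 32) — chosen so the full
architecture (attention, ASPP, supervision heads) is exercised end to end
on CPU — trained for 150 epochs on 50 patches cut from two 128×128
synthetic images, and evaluated on three held-out images.  The patch-count
checks generate the full 20×584×584 and 10×605×700 synthetic datasets.
Training descends from ≈ 0.97 to well below 0.1 weighted-BCE loss, and the
trained model out-ranks an untrained one by ≈ 0.3 AUC on held-out synthetic
images.

## Known limitations

* Single-class (vessel) output only; no multi-label pathology support.
* The NumPy backend is CPU-only and single-threaded beyond BLAS; full-scale
  500-epoch training of the default-width model is impractical on it — the
  default widths exist to honor the architecture contract, and full-scale
  runs would port the model spec to a GPU framework.
* Free-angle rotation augmentation and test-time augmentation are not
  implemented.
* The FOV estimator assumes a single bright disc; montage or cropped-FOV
  images would need a supplied mask.
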