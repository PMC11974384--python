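# Methods

## Problem setting

Volumetric electron microscopy (VEM) images tissue at nanometre resolution by
stacking serial 2D sections. The stacks are strongly anisotropic — in-plane
pixels of ~6–16 nm against section spacings of 15–50 nm — and carry
stack-level artifacts: per-section brightness differences, small per-section
misalignments, and noise. Dense organelle segmentation (mitochondria,
endoplasmic reticulum, lipid droplets, neurites) is the entry point to most
downstream analysis, and supervised 3D U-nets do it well but need large
manually labeled training sets that rarely exist for a new tissue.

`vemseg` implements the transfer-learning remedy as a complete, tested
pipeline: pretrain an anisotropic 3D residual U-net on a source task where
labels are abundant, fine-tune it on a scarce-label target task, and compare
against a from-scratch baseline across decreasing target-data fractions.
Because the real benchmark volumes are tens of gigabytes and the original
training runs need GPUs, the package ships a synthetic scene generator that
reproduces the *structure* of such data at desk scale, so every stage — and
the transfer experiment itself — runs on one CPU in minutes.

## Synthetic scenes

`synthetic.generate_scene` renders a grayscale stack plus one binary mask
per organelle class from a `SceneConfig`. Morphologies:

* **mitochondria-like** (`BlobClass`): ellipsoids at uniform random positions
  and orientations, default semi-axes 400×250×250 nm with ±25% size jitter,
  carrying a sinusoidal internal stripe texture (period 240 nm, contrast
  0.35) imitating cristae;
* **ER-like** (`TubuleClass`): sparse networks of persistent random-walk
  tubes of radius 60 nm;
* **neurite-like** (`TubeClass`): thick (180 nm) tubes spanning the volume
  in-plane.

Rendering follows the physics loosely but in the right order: flat per-class
intensities darker than background (heavy-metal stain convention; background
0.75, classes 0.30–0.42), texture, an isotropic-in-index-space Gaussian PSF
(sigma 0.7 voxels, hence physically broader along Z), per-slice brightness
offsets (±0.04), per-slice integer XY misalignment (±1 px, independent per
slice, applied identically to image and labels), and additive Gaussian noise
(sigma 0.05), clipped to [0, 1].

Default geometry is a (16, 96, 96) grid at (40, 32, 32) nm per voxel —
the working resolution regime that the real datasets are rescaled to before
patching (tens of nm in XY, coarser in Z), small enough that a full
train/evaluate cycle is a desk job. One master seed drives named
sub-streams (blobs, tubules, tubes, texture, drift, misalignment, noise), so
each stage is individually reproducible and scenes regenerate bit-for-bit.

What the generator does **not** emulate: membranes and cell boundaries,
instance identities, spatially correlated noise, focus gradients, and the
sheer morphological diversity of real tissue. Passing the desk-scale
transfer benchmark therefore demonstrates that the pipeline's mechanics are
correct and that the transfer protocol behaves as designed under controlled
domain shift — not that any particular IoU will be reached on real EM.

## Preprocessing

Per slice: CLAHE (clip limit 0.01, 8×8 tiles; delegated to
`skimage.exposure.equalize_adapthist`) then a 2D Gaussian blur (sigma 1 px,
none across Z); then one *global* affine standardization to zero mean and
unit variance. The standardization is global rather than per-slice because
CLAHE has already equalized local contrast; making it global keeps absolute
contrast differences between structures informative.

Resolution rescaling uses per-axis factors `src/dst` with linear
interpolation for images and nearest-neighbour for labels.

Patching uses half-open windows `[origin, origin+shape)` in (z, y, x) order,
default (18, 160, 160) — the network's native input, quoted as 160×160×18
in X-Y-Z order elsewhere. Border policy is `drop` (incomplete windows
discarded; this is what patch counts refer to) or `reflect` (volume padded
so every voxel is covered — used for whole-volume inference). Stitching
averages overlapping predictions voxelwise and refuses silently uncovered
voxels. Label scarcity is simulated by drawing a uniform random subset of
`round(fraction × n)` training patches without replacement.

## Network

A 5-level encoder/decoder with 28, 36, 48, 64, 80 channels. Each level is
one in-plane (1,3,3) convolution followed by two (3,3,3) convolutions, with
an additive residual connection from the output of the first convolutional
module to the output of the third (a 1×1×1 projection would be inserted if
channel counts differed; with this block layout they never do). Max pooling
(2×2) and the mirrored nearest-neighbour upsampling act in XY only, so the
Z extent is preserved through every stage — the architectural answer to
anisotropy. A single (1,5,5) boundary convolution enters the first level and
its mirror precedes the single-channel logit output. All convolutions use
"same" padding; XY input extents must be divisible by 2^(levels−1).

Unstated details were fixed as: ELU activations; optional instance
normalization (off by default — on these small, globally standardized
volumes it gave no stability benefit and it perturbs transfer by entangling
features with per-patch statistics); He initialization. Multi-organelle
segmentation is one trained network per class.

The implementation is plain numpy with hand-written backpropagation
(chunked im2col convolutions bounded to ~48 MB buffers, argmax-scatter
pooling, analytic loss gradients). Every gradient path is verified against
central finite differences in the test suite at float64. The desk-scale
`REDUCED_SPEC` preset (3 levels, 6/10/14 channels, (8, 32, 32) patches)
keeps a full transfer experiment within a CPU budget of minutes while
preserving all architectural contracts of the full network; the full-size
spec is exercised fully-convolutionally in tests.

## Training

DiceCE loss: `dice_weight · soft_dice + ce_weight · BCE` on sigmoid
probabilities, equal unit weights by default; Dice smoothing epsilon 1e−6,
BCE probability clipping 1e−7. Dice alone behaves poorly on balanced
labels, cross-entropy alone on strongly imbalanced ones; the sum is robust
across both regimes, which matters when one objective must serve every task
in the grid.

Optimizer: ADAM, constant learning rate 0.002 (no schedule), batch size 4,
up to 100 epochs with early stopping (patience 10) on a held-out validation
split of the training patches (20% by default; with too few patches for a
split, early stopping is disabled and the final weights are returned).
Augmentations per sampled patch: random flips on all three axes, 90°
rotations in XY only (the anisotropy-preserving subgroup), additive
brightness (±0.1) and multiplicative contrast (0.9–1.1) about the patch
mean on the image only. Divergence (non-finite loss) aborts with a
diagnostic rather than returning garbage.

Fine-tuning restarts the identical loop from pretrained weights with all
layers trainable — no freezing — on the subsampled target fraction. With
fraction 1.0 and random initialization it is bit-for-bit the scratch
baseline, which is how the baseline arm is implemented.

## Evaluation and the experiment grid

Logits are binarized at probability 0.5 (a logit of exactly 0 counts as
foreground). Metrics are computed over the whole stitched test volume, not
per patch: IoU, accuracy, PPV, TPR from voxel confusion counts, with the
IoU of two empty masks defined as 1. Misprediction analysis labels
26-connected components of the prediction and flags those whose overlap
fraction with ground truth is strictly below 0.5 (a component at exactly
the threshold is kept).

`run_experiment` executes the (pretrain task × target task × fraction ×
replicate) grid. Per (pretrain task, replicate) one model is pretrained and
reused across fractions; within a cell, baseline and transfer arms share
the seed and hence the identical target subset; replicates vary
initialization and pretraining. Failures are recorded per cell and the grid
continues. Everything derives deterministically from the plan's master seed.

## The desk-scale transfer benchmark

`orchestration.domain_shift_benchmark` freezes one canonical configuration
of the same-task/shifted-domain scenario: source and target scenes both
contain mitochondria-like blobs as the labeled class **plus unlabeled
ER-like and neurite-like distractor structures at similar intensities**.
The distractors are the load-bearing design choice: real target volumes
contain organelles that look locally similar to the target class, and
discriminating them is exactly what a model cannot learn from a couple of
patches but can inherit from pretraining. Without them the synthetic task
is so homogeneous that two patches already determine the solution and
scarcity never bites. The domain shift is in noise level, brightness
drift, misalignment, texture contrast and blob size — the task is shared.

Class content (counts, sizes, intensities) is kept identical across source,
target-train and target-test scenes, with the shift purely in imaging
conditions (noise 0.05 → 0.12, texture contrast 0.20 → 0.40, stronger
per-slice brightness drift, 1 px misalignment). This matters because the
preprocessing standardizes each volume globally: if scene composition
differed, the standardization itself would move class intensities between
volumes and cross-volume inference would measure that artifact rather than
the domain shift under study.

Benchmark sizes: target train volume (16, 96, 96) → 18 patches of
(8, 32, 32); 10% fraction → 2 patches; fixed 16 epochs without a validation
split (removing snapshot noise from the arm comparison); 3 replicate seeds;
evaluation on a held-out target test scene generated from an independent
seed (the synthetic analogue of separating train and test blocks of a real
volume with a discarded gap). The experiment arms run at learning rate
0.001 rather than the canonical 0.002: that rate is calibrated to the
full-size network, and on the ~40× smaller reduced preset it over-steps —
a few fine-tuning batches can erase the pretrained solution entirely, which
turns the arm comparison into optimizer noise. Pretraining keeps 0.002 with
a validation split and early stopping.

## Meshing

Marching cubes at iso-level 0.5 on the probability grid (equivalent to the
binarization boundary), run on a one-voxel zero-padded copy so surfaces
touching the stack border close. Vertices are scaled per axis by the voxel
size, giving metrically correct meshes despite anisotropy, and returned as
(x, y, z) nm. Zero-area faces are dropped. Export formats: PLY, OBJ, STL
(via trimesh).

## Numerical and degenerate-input choices

* Logit 0 / probability 0.5 → foreground (documented tie-break).
* Misprediction overlap exactly at threshold → not flagged (strict `<`).
* IoU, PPV, TPR of empty/empty → 1.
* Max-pool ties take the first (lowest-index) element, deterministically.
* Constant slices pass CLAHE unchanged; zero-variance volumes refuse to
  standardize.
* Volume smaller than one patch: `drop` tiling yields an empty list;
  `reflect` tiling pads and predicts everything.
* Training dtype float32; gradient checks run at float64.

## Known limitations

* CPU-only numpy training: minutes at the reduced preset, impractical at
  the full (18, 160, 160)×80-channel scale — the full spec is validated for
  correctness (shapes, gradients, transfer mechanics), not trained.
* Semantic (binary, per-class) segmentation only; no instance separation.
* The synthetic benchmark measures the transfer protocol under controlled
  shift; absolute IoUs have no quantitative relation to real-tissue scores.
* Slice misalignment is simulated but not corrected; no registration step.
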