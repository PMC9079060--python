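# Methods

## Problem and model

The package segments the maxillary sinus — an air-filled, roughly
pyramidal cavity in the maxilla — from cone-beam CT (CBCT) volumes, and
exports the result as a binary mask and a smoothed STL surface model.

Segmentation uses two 3D U-Nets in a coarse-to-fine arrangement:

1. **Coarse stage.** The scan is resampled to isotropic voxels
   (`target_spacing_mm`, default 0.4 mm) and downsampled to a fixed grid
   (default 32³). The first network produces a low-resolution probability
   map, which is upsampled back to the full grid.
2. **Patch proposal.** The bounding box of the thresholded coarse
   foreground (p ≥ 0.5) is tiled with full-resolution patches (default
   32³, stride 16³); only patches intersecting the foreground are kept.
   Patch origins at the grid edge are shifted inward, never shrunk.
3. **Fine stage.** The second network segments each patch independently;
   overlapping voxels receive the arithmetic mean of the contributing
   probabilities, voxels outside all patches get probability 0. Averaging
   probabilities before thresholding (rather than voting on labels) makes
   the combination order-independent and smooth.
4. **Post-processing.** Binarization at 0.5, then only the largest
   26-connected component is kept. An empty result is flagged as a failed
   prediction (the clinical "class E: could not predict anything"). Ties
   between equal-sized components break to the component whose first voxel
   comes first in raster order.
5. **Surface model.** Marching cubes at iso-level 0.5 with vertices mapped
   to mm world coordinates, followed by 10 iterations of Taubin smoothing
   (λ = 0.5, ν = 0.53), which smooths without the volume shrinkage of
   plain Laplacian smoothing (verified to change enclosed volume by < 2 %
   on a 10³-voxel cube). A mask touching the grid boundary produces an
   open surface and is flagged.

Both networks share one architecture: 4 encoder blocks and 3 decoder
blocks, each block two 3×3×3 convolutions followed by group normalization
(8 groups) and ReLU; 2×2×2 max pooling (stride 2) between encoder levels,
so resolution halves three times (inputs must be divisible by 8); decoder
levels use trilinear upsampling plus convolution (avoiding transposed-
convolution checkerboard artifacts) with channel-concatenated skip
connections; a single 1×1×1 convolution and a logistic squashing produce
the per-voxel probability. Channel widths per level are
`base_channels × (1, 2, 4, 8)` with a CPU-friendly default
`base_channels = 8`. Intensities enter the network through a fixed HU
window, [−1000, 1000] → [0, 1], which keeps inference deterministic
across scans (no per-scan statistics).

The final 1×1×1 convolution is zero-initialized: an untrained network
outputs exactly 0.5 everywhere, and training grows the decision function
from the logistic midpoint. With the small fixed learning rate used here
this reaches sign-correct (thresholdable) decisions much sooner than a
randomly initialized head, whose initial misclassifications first have to
be unlearned. The head *bias* initialization is exposed
(`NetworkSpec.head_bias_init`, default 0): the fine network of the
reproduction protocol starts it at +0.5, i.e. from an over-inclusive
prior. With an unweighted loss and mostly-background patches, a
zero-started head spends most of a short training budget with interior
probabilities just *below* 0.5 — the binarized output is empty until the
threshold crossing, which at this learning rate happens late and
unpredictably. Starting above the threshold makes the 0.5-level set
non-empty throughout training and lets it shrink monotonically onto the
true boundary; asymptotically the two initializations agree.

## Training

The loss is the voxel-wise binary cross-entropy with a multiplicative
weight *w* on the positive-class term,

    L = −mean_n [ w·y_n·log(p_n) + (1−y_n)·log(1−p_n) ],

with probabilities clamped to [1e−7, 1−1e−7] before the logarithms (the
training path evaluates the identical quantity from logits with stable
softplus forms). By default *w* is the negative/positive voxel ratio of
each batch, capped at 100 so nearly-empty patches cannot produce extreme
weights. Optimization is ADAM (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) at a fixed
learning rate of 1.25e−4.

Random spatial augmentations are applied to every training example each
epoch: rotation (± 10° per axis), isotropic scaling (0.9–1.1), and elastic
deformation (4³ control grid, displacement SD 0.5 voxels, linearly upsampled
to a dense field). The image is warped with linear interpolation, the
mask with nearest-neighbour so it stays binary; all ranges admit the
identity transform.

Early stopping monitors the unweighted validation BCE: training halts
when it has failed to improve for `patience` consecutive epochs
(patience 0 stops at the first non-improving epoch) or at `max_epochs`,
and the weights of the best validation epoch are restored. The coarse
network trains on (downsampled volume, downsampled mask) pairs; the fine
network on full-resolution patches sampled around foreground voxels
(foreground-guaranteed sampling by default, ratio configurable).

The two stages have different error economics, and the reproduction
protocol weights them differently. The coarse network only proposes
patches: over-segmentation is harmless, a miss is fatal, so it trains
with the inverse-frequency positive weight (recall-oriented). The fine
network's output is binarized at the fixed threshold 0.5, and a positive
weight w > 1 provably shifts the learned decision boundary outward
(thresholding a w-weighted posterior at 0.5 admits voxels whose true
positive probability is only 1/(1+w)); empirically this produced a
systematic one-voxel false-positive shell around the cavity. The fine
stage therefore trains with w = 1, which calibrates the 0.5 threshold at
the air/mucosa intensity midpoint and removed the shell. `TrainConfig`'s
default remains the inverse-frequency weight (capped at 100) for
standalone use.

Patch sampling for the fine stage mixes two origins: per training volume,
two patches centred (with jitter) on foreground voxels — the boundary
signal — plus half a uniform-origin patch on average. The uniform patches
matter more than their number suggests: they show the patch network
sinus-free anatomy, in particular the nasal airway, which a loose
proposal stage will sometimes hand it at inference. A network trained
only on sinus-containing patches labels nasal air as sinus (it is air,
and air was always foreground in its training patches), and because the
nasal cavity connects to the sinus through the ostium channel, that
mistake survives the largest-component filter.

Batch size (1 in the reproduction protocol — with ADAM's fixed
per-coordinate step size and a small fixed learning rate, more optimizer
steps per epoch converge faster in wall-clock time than larger batches),
epoch budgets (12 coarse / 26 fine) and augmentation magnitudes are
engineering defaults of this package, chosen for single-CPU training of
the desk-scale networks; they are not reconstructions of any clinical
training run.

## The network engine

The networks are implemented directly on numpy arrays with explicit
forward/backward passes. 3×3×3 convolutions run through numba-jitted
direct kernels (z-slice-blocked accumulation) on large grids and through
BLAS-backed im2col matrix products on the small deep-level grids; the
backward pass uses the exact adjoint (spatially flipped,
channel-transposed kernel). A pure-numpy float64 reference convolution
is routed automatically for float64 inputs; it serves as the independent
oracle for the jitted kernels and enables full-precision gradient checks
(the test suite verifies backprop against finite differences in float64).
Everything is single-threaded and uses fixed reduction orders, so
training and inference are bit-reproducible from their seeds — which is
what makes the pipeline's test–retest determinism an exact property
rather than a statistical one.

## Synthetic phantoms

The generator renders the anatomy the task cares about, on a desk-scale
grid (default 64³ at 0.4 mm):

* **Sinus cavity**: a rotated superellipsoid (exponent ~2–2.6, semi-axes
  ~4.6–5.2 mm jittered ±15 %), chosen over an anatomical atlas because it
  captures pyramidal-shape variability cheaply and has a closed-form
  volume for oracle tests (voxelized volume matches (4/3)πabc within 5 %
  for exponent 2).
* **Bone shell** (+1000 HU, 1.2 mm) around the cavity; **soft-tissue
  background** (+40 HU); cavity **air** at −1000 HU. Only the air window
  (−1024..−200 HU) is anatomically constrained (it is the threshold used
  in the labelling convention); the remaining levels are standard CT
  values chosen to make that window discriminative.
* **Mucosal lining** (+30 HU) of configurable thickness on the inner
  wall, *excluded* from the ground truth — thickened mucosa narrows the
  air space, and the truth is the air cavity. Clinical thickening grades
  (> 2 mm shallow, > 4 mm moderate) refer to sinuses ~3× larger than the
  desk-scale cavity, so the generator's default lining range is scaled to
  0.8–1.6 mm; half the samples in a generated dataset carry a lining.
* **Ostium and nasal airway**: a narrow air channel (radius 0.8 mm)
  connects the cavity to a flattened air slab near one grid face
  (standing in for the nasal cavity at the edge of a CBCT field of view,
  with its own bone wall). The ground truth stops at the channel mouth:
  channel and nasal air are excluded even though they are air and
  26-connected to the cavity. This is the geometric encoding of the
  labelling rule that the segmentation ends at the early start of the
  ostium — and it is what makes the task non-trivial: plain HU
  thresholding captures all connected air and would badly over-segment,
  so the networks must learn the anatomical cut.
* **Noise**: additive Gaussian, SD 30 HU (CBCT-like), seeded per sample.
  Beam-hardening streaks, scatter, partial-volume blur and HU-calibration
  bias are *not* modelled.

Intensity is assigned by voxel-centre membership, so on a noiseless
phantom the geometry and the air window agree exactly; this gives the
generator sharp, testable invariants (truth voxels are exactly air; the
air mask equals the truth when there is no ostium).

What passing tests on phantoms do and do not show: they validate the
pipeline's mechanics (training dynamics, patch logistics, determinism,
metrics) and its ability to learn an anatomical exclusion rule from
context; they do not demonstrate clinical accuracy on real CBCT, whose
artifacts, soft-tissue ambiguity and anatomical variability the phantom
deliberately simplifies.

## Metrics

Overlap metrics come from exact voxel confusion counts: DSC =
2TP/(2TP+FP+FN), IoU = TP/(TP+FP+FN), linked by DSC = 2·IoU/(1+IoU)
(asserted to 1e−12 in tests). Two empty masks score 1 by convention, with
a warning, so batch statistics can exclude them.

The 95 % Hausdorff distance is computed on mask boundary voxels (a
foreground voxel with ≥ 1 background 6-neighbour — the thinnest boundary
shell; grid edges count as background) scaled to mm: the two directed
closest-point distance sets (a→b and b→a) are pooled and their 95th
percentile taken with linear interpolation between order statistics. The
pooled-symmetric construction makes the number order-independent. Meshes
(vertex sets) are accepted as an alternative surface representation;
masks are the default and the choice is recorded in the report.

The RMS surface distance is computed between meshes: for each vertex of
one mesh, the exact closest-point distance to the other *surface*
(vectorized point-to-triangle, not vertex-to-vertex), then
sqrt(mean(x²)); the two directed values are averaged. Distance metrics
raise on empty inputs rather than returning a sentinel.

## Numerical choices and degenerate inputs

* Probability clamp 1e−7 before logarithms; the logistic is evaluated in
  float64 and never returns exactly 0 or 1.
* Binarization threshold 0.5 everywhere (canonical for a logistic
  output); exposed in `PipelineConfig`.
* 26-connectivity for components (permissive 3D default; configurable).
* Mask resampling is nearest-neighbour, image resampling linear; a
  volume already at the target spacing is returned unchanged.
* A mask that fills the entire grid (possible with untrained weights,
  which output exactly 0.5) is meshed by padding one background voxel so
  marching cubes has an iso-crossing; the surface is the boundary-clipped
  box.
* Max-pool ties break to the first window element; equal-sized component
  ties to raster order — both fixed so reruns are bit-identical.

## Known limitations

* The phantom is a geometric stand-in, not a CBCT physics simulation.
* Networks are desk-scale (base width 8) and trained for minutes on a
  CPU; clinical-grade accuracy would need realistic data and GPU-scale
  training, which this package deliberately does not attempt.
* HD95 on very small structures is quantized by the voxel grid.
* DICOM reading normalizes orientation to the nearest axis-aligned
  right-handed frame; strongly oblique acquisitions are reoriented with a
  warning rather than resampled along their true axes.
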