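# Methods

This note records the model, its parameterization, the numerical choices made
in this implementation, and its limitations. Problem sizes (grid sizes,
network widths, training schedules) given here are this package's own
choices, sized so that everything runs on a single CPU core in minutes.

## Landmarking as heatmap regression

Each of the 46 landmarks of the clinical schema is represented by one output
channel of the network. The training target for a present landmark is a
truncated Gaussian sphere on the output grid,

    H(v) = exp(-||v - v0||^2 / (2 sigma^2)),   sigma = 1.5 voxels,

set to zero beyond 3 sigma from the landmark's (fractional) voxel position
`v0`. Channels of absent landmarks are all-zero and masked out of the loss.
Decoding thresholds each channel at 50% of its peak, reports the center of
mass of the surviving activation in world millimetres, and declares the
landmark absent when the peak is below `min_peak` (0.1). Absence is data,
not an error: it propagates through measures and evaluation explicitly.

On a 1.6 mm grid the encode–decode round trip recovers interior landmarks to
well under half a voxel (max ≤ 0.8 mm over 100 random positions; typically
≈0.25 mm).

## Network

A single-stack 3D hourglass operating on `(1, D, H, W)` volumes:

- **Stem**: 3D convolution, 256 features, kernel 7, stride 2 (clinical
  defaults), then group normalization (8 groups) and ReLU. The stem halves
  resolution; the hourglass below is internally symmetric, so the output grid
  is `ceil(input/2)` per axis with doubled voxel spacing and preserved origin
  (output voxel `j` is centred on input voxel `2j`).
- **Contracting path**: `depth` residual blocks, each followed by 2×2×2 max
  pooling. A residual block is three convolutions (features 64/64/128,
  kernels 1/1/3), the first two followed by GN+ReLU, the third by GN only;
  the identity shortcut (1×1×1-projected when channel counts differ) is
  summed before the block's final ReLU.
- **Expanding path**: `depth` stages of 2× trilinear upsampling, elementwise
  summation with the equal-resolution skip, then a residual block.
- **Head**: 1×1×1 convolution to 46 channels and a sigmoid, so outputs are
  strictly inside (0, 1).

Input spatial dimensions must be at least `2^depth * stem_stride` and
divisible by `2^(depth+1)` so pooling and upsampling stay aligned;
`predict()` pads volumes at the high end with the minimum intensity to
satisfy this and the padding never moves the origin.

The network is implemented in numpy with hand-written reverse-mode
gradients: im2col+GEMM convolutions, group-norm backward in closed form, max
pooling by argmax routing, trilinear upsampling as a cached sparse matrix
applied per axis (its backward is the transpose). All layers compute in
float32; gradients are verified against central finite differences in the
test suite. The heatmap head is initialized with small weights
(sd 0.01) and bias −4, so initial activations match the sparse-target prior
(sigmoid(−4) ≈ 0.018) and stay away from the saturated ends of the sigmoid —
a package design choice that keeps the output strictly inside (0, 1) in
float32 and speeds early BCE convergence.

## Training

- Volumes are resampled to 1.6 mm isotropic spacing (trilinear) and z-score
  normalized per volume (normalization is a package choice, applied
  identically at train and predict time).
- Loss: voxelwise binary cross-entropy averaged over the voxels of present
  target channels; predictions are clamped to `[1e-7, 1 − 1e-7]`. Absent
  channels contribute exactly nothing (adding one never changes the loss).
- Optimizer: AdamW, learning rate 0.001, decoupled weight decay 0.01
  (clinical defaults; the toy experiments use lr 0.003 with a short schedule).
- Batch size is one full volume; an epoch is a seeded random permutation of
  the training set.
- Augmentation (applied jointly to image and landmarks, all seeded): random
  crops retaining 25–100% per axis, rigid rotation ±15° and translation ±10%
  of the extent about the volume centre in world mm, a coarse elastic
  deformation (knots every 8 voxels, ±2 voxels, landmarks transported by the
  first-order inverse displacement), and contrast/brightness jitter.
  Landmarks leaving the field of view become absent. With every range zero
  the augmentation is exactly the identity (`TrainConfig.without_augmentation()`).
- Model selection: after each epoch the mean validation Euclidean distance
  over present landmarks is computed; the best-scoring parameter vector is
  kept, and training stops after `patience` epochs without improvement.
  Predicted-absent validation landmarks are counted as misses, not given a
  penalty distance.
- Everything is deterministic given the two seeds (network init, training
  order/augmentation): repeated runs produce bitwise-identical parameters
  and predictions.

## Cephalometric analysis

The 46-landmark schema comprises 16 bilateral pairs and 14 midline points,
partitioned into dental (12), facial-surgery (9), and skeletal (25) groups.
The anatomical frame derives from the **Frankfort horizontal plane**, fitted
by total least squares (smallest-eigenvector of the scatter matrix) through
whichever of the two Porions and two Orbitales are present (≥ 3 required).
The superior axis is the plane normal signed toward Nasion; the anterior
axis is the in-plane direction from the Porion midpoint toward the Orbitale
midpoint; the lateral axis completes the right-handed triad.

Sixteen characteristic measures are computed: five point-to-point distances
(anterior facial height, effective mandibular/midfacial lengths left and
right), six signed components along the anterior axis (Nasion-perpendicular
offsets of A and Pogonion, incisor positions), and five angles (SNA, SNB,
their difference, the mandibular plane angle against Frankfort, and the
angle between the Frankfort plane and the scanner's true horizontal). All
measures except the last are invariant to rigid motion of the head; the
Frankfort-to-true-horizontal angle is, by definition, measured against the
fixed scanner vertical.

## Evaluation and statistics

Landmark accuracy is summarized by mean ± SD (sample SD, ddof = 1) of
Euclidean distances and the SDR (percentage of distances ≤ 2 mm, inclusive;
measures use ≤ 2 mm / 2° on the absolute signed error). Cases above 10 mm
are flagged for manual review but never auto-excluded; predicted-absent
landmarks are tallied as misses. Two-cohort comparisons use the two-sided
Mann-Whitney U test (exact p by enumeration when both samples are ≤ 8 and
tie-free, otherwise the tie/continuity-corrected normal approximation) with
Benjamini-Hochberg correction across the per-landmark family; significance
is called at adjusted p < 0.05. Under a true null (identical cohorts), the
empirical discovery proportion over 200 simulated replicates is ≈0.4%.

## Phantom generator

The phantom exists so the full pipeline is trainable and testable on one CPU
with no external data. Each case is a dark background plus:

- two bright **ellipsoidal shells** (intensity 0.6) standing in for the
  cranial vault and mandibular body,
- one **Gaussian blob** per landmark (sd = 2 mm) with per-landmark amplitude
  evenly spaced in [1.0, 1.5], so channels are distinguishable by local
  appearance,
- additive Gaussian intensity noise (sd 0.05).

Landmarks vary across cases by per-landmark Gaussian jitter (sd 2 mm) and a
shared per-case rigid perturbation (≤ 3°, ≤ 2 mm) applied identically to
image content and coordinates; cohort "B" may additionally shift the
template to emulate a population difference. Cases are pure functions of
(spec, case index, cohort) via seeded `SeedSequence` streams, and a
landmark-only fast path produces exactly the coordinates of the rendered
case. Two templates ship with the package: `toy8` (8 midline/mandibular
landmarks, 48³ at 1.6 mm) and `full46` (the complete schema, 96³ at 1.6 mm).

**What the phantom does emulate**: bright bone-like structures, per-landmark
local appearance, anatomical variation, patient pose variation, cohort
shifts, image noise, and the exact geometry conventions (world coordinates,
spacing, origin) of clinical volumes.

**What it does not emulate**: real CT intensity statistics (Hounsfield
units, beam hardening, metal artifacts), soft tissue, true anatomical shape
variation and covariation between landmarks, pathology, or scanner-specific
geometry such as gantry tilt. Accuracy numbers on phantoms do not transfer
to clinical scans; they validate the pipeline, not the clinical claim.

## Reference experiment sizes

The acceptance experiments (see `scripts/acceptance.py` and
`tests/test_acceptance.py`) use a reduced "toy" configuration chosen by this
package: hourglass with stem 8, blocks (8, 8, 16), 4 GN groups, depth 2;
toy8 phantoms; training on 40 cases with validation on 10 and testing on 10
held-out (lr 0.003, ≤ 60 epochs, patience 12, no augmentation). This reaches
≈2.0 mm mean held-out error with SDR@3.2 mm ≥ 80% in ≈4 minutes of CPU
training, and held-out error improves monotonically with training sets of
10 → 20 → 40 phantoms (3-seed medians ≈5.2 → 3.2 → 2.6 mm). The shape
contract of the full-depth network is exercised with a thin depth-4
configuration (stem 16, blocks 16/16/32), since the clinical widths at 64³
are unnecessarily slow for a shape test.

## Limitations

- The numpy network is a reference implementation: correct and
  deterministic, but orders of magnitude slower than a GPU framework; the
  clinical-width configuration (stem 256, blocks 64/64/128, depth 4, 46
  channels at 96³+) is out of CPU reach here.
- Elastic-augmentation landmark transport uses the first-order inverse of
  the sampling displacement; it is exact for rigid transforms and
  approximate (sub-voxel error for the default magnitudes) for elastic ones.
- The decoder returns one position per channel; it cannot represent
  multi-modal uncertainty, and a secondary activation lobe can drag the
  center of mass (mitigated by the 50% relative threshold).
- Phantom realism is deliberately minimal (see above); no claim about
  clinical accuracy is made or tested.
- Exact Mann-Whitney p-values are enumerated only for small tie-free
  samples; larger or tied samples use the corrected normal approximation.
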