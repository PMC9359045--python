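# Methods

This note records the modeling and numerical choices behind `hdaunet`: what
is computed, which knobs matter, what the synthetic phantoms do and do not
emulate, and where the design was genuinely open.

## Data model and preprocessing

A case is a CT-like scalar volume, named binary structure masks, a
reference dose in Gy, and a prescription, all on one `(x, y, z)` voxel grid
(z cranio-caudal, 0-based indices, masks stored as unsigned bytes). The
network input is a channel stack: channel 0 the min-max normalized CT,
then one binary channel per structure in a cohort-wide fixed order.
Structures missing from a case become all-zero channels and are excluded
from that case's per-structure losses and metrics — the only consistent way
to keep a fixed channel count across cohorts with partial structure
coverage.

Normalization scopes: CT per volume; dose per case with bounds
`(0, max dose of the case)`. The bounds travel with the volume so
evaluation always happens in Gy. The alternative dose scope (prescription
as the upper bound) is available by denormalizing with explicit bounds; the
per-case maximum is the default because it makes the normalized target
exactly span [0, 1] for every case.

In-plane downscaling (e.g. 512×512 → 128×128, factor 4) uses cubic
b-spline interpolation for scalar volumes. Masks are downscaled by linear
interpolation followed by thresholding at 0.5, which keeps them binary and
approximates a majority vote over the footprint. Resampling targets
`ceil(n/factor)` with no source padding; the cranio-caudal axis is left
untouched.

## Architectures

Three variants share the encoder-decoder skeleton with `levels` resolutions
(default 5, i.e. four 2× downsamplings; 128×128×96 inputs bottom out at
8×8×6):

* **hd** — dense convolutions (3×3×3 conv + ReLU concatenated onto the
  incoming features; growth rate 16) twice per encoder hierarchy, dense
  downsampling (stride-2 conv branch + ReLU concatenated with 2× max
  pooling), four dense convolutions at the bottom; the decoder per level:
  trilinear upsampling to the skip's grid, a 3×3×3 convolution compressing
  to 64 channels, concatenation with the skip, then two dense convolutions;
  a final 1×1×1 convolution to one channel.
* **hda** — hd plus batch normalization after each convolution
  (conv → BN → ReLU) and an additive attention gate on every skip: skip and
  gating maps are projected by 1×1×1 convolutions to 64 features, summed,
  ReLU'd, projected to one channel and squashed by a sigmoid into per-voxel
  coefficients α ∈ [0, 1] that rescale the skip (broadcast across
  channels). The gating signal is the decoder's post-upsample convolution
  output at that level.
* **attention** — a standard U-net baseline with base width 32 doubling per
  level and the same attention gates.

The decoder compression width and the attention-gate intermediate width are
one parameter (64 by default): the features entering each gate after
upsampling and convolution. This single choice pins the parameter totals at
the reference configuration to 3,404,950 (hd) and 3,455,386 (hda) — 3.4M
and 3.5M — with the attention baseline at 26.0M; alternative readings
(keeping or halving the decoder width) miss these totals by more than 1M
parameters. Batch normalization is placed between convolution and ReLU and
is not applied to the output head or inside the gate projections; with
batch size 1 it normalizes over the spatial axes and uses running
statistics at inference, so prediction is deterministic.

Odd spatial extents are handled by ceil-mode pooling/striding on the way
down and by resampling to the skip's exact grid on the way up, so any
extent ≥ 2^(levels−1) works.

All tensors are `(channels, x, y, z)`; training uses batch size 1
throughout, so there is no batch axis. The networks run on a small
reverse-mode autodiff engine written for this package (numpy + BLAS;
convolution as one matrix product per kernel offset on strided views).
Every backward rule is verified against central finite differences in the
test-suite.

## Losses

The exact DVH of structure *s* at threshold *dₜ* is the fraction of masked
voxels with dose ≥ dₜ. The differentiable relaxation replaces the
indicator with `σ((m/βₜ)(D − dₜ))` (steepness m = 1, bin width βₜ = 1 Gy,
thresholds 0..80 Gy inclusive — 81 values). The DVH loss averages the
squared curve discrepancies over structures and thresholds; only nonempty
masks count toward the structure average. The training objective is
`w₁·MSE + w₂·L_DVH`, (w₁, w₂) = (1, 0.1).

The MSE is computed on normalized doses while the DVH term is evaluated in
Gy by rescaling the prediction with the case's normalization bounds — one
threshold grid serves training and evaluation, and the two loss components
keep comparable magnitudes.

The sigmoid argument is scaled as m/βₜ (steepness per bin width), the form
that makes m dimensionless; with m → ∞ the relaxed curve converges
pointwise to the exact one wherever no voxel sits exactly on a threshold
(a voxel exactly on a threshold contributes ½).

## Training protocol

Adam with lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7; batch size 1; a fixed epoch
budget (200 by default) with per-epoch reshuffling; no augmentation,
no schedule, no early stopping. The returned weights are from the epoch
with the lowest validation loss (ties → earliest). Fractional cohort
splits are 70/15/15 with val/test sizes `round(n·f)` and the remainder to
training; explicit id lists pass through untouched. Weight initialization
(He) and shuffling derive from one seed via independent seed-sequence
streams, so runs are bit-reproducible.

## Synthetic phantoms

Each case: an ellipsoidal head (air/tissue/bone CT bands + mild noise),
a randomly placed and sized PTV ellipsoid with CTV and GTV scaled copies
(0.7 / 0.45) nested inside, and spherical OARs placed inside the head but
at least two voxels clear of the PTV. The reference dose is

    D(x) = Rx · h · σ( (4τ − d(x)) / τ ) · (1 − sparing · soft(x) · ramp(x)) + ε

with d the signed Euclidean distance to the PTV surface (negative inside),
τ the falloff scale (4 mm default), h = 1.02 a small deliberate hotspot,
`soft` the Gaussian-blurred OAR union (σ = 3 voxels), `ramp` a short ramp
that disables the sparing dip inside and immediately around the PTV (so
organ sparing never degrades target coverage), and ε Gaussian noise
(1 Gy default), clipped at zero. The 4τ interior margin puts the PTV
surface at σ(4) = 0.982 of the plateau: interior voxels stay above 95% of
prescription for any τ, the dose 10τ out is below 1% of prescription, and
with the default noise the cohort ground truth sits at D95 ≈ 0.99,
H1 ≈ 0.06, Dmax ≈ 1.06 — the clinical ground-truth regime. With zero noise
the dose is a deterministic function of the masks, which gives training a
trivially learnable regime used by the overfit oracle.

What the phantoms do **not** emulate: beam-shaped dose trajectories and
delivery physics, CT Hounsfield calibration, inter-observer delineation
variability, multiple prescription levels per case, and anatomical
realism beyond "nested targets + disjoint organs". Tests passing on
phantoms therefore demonstrate the correctness and trainability of the
machinery, not clinical-grade accuracy on real patients.

## Metrics

Percentile convention: Dp is the dose exceeded by p% of the structure —
descending sort, rank `ceil(p/100 · n)`, voxels equally weighted. Dmax is
the single maximum voxel over the whole volume. The conformity index is
reported as the target coverage fraction |PTV∩V100|/|PTV| (no universal CI
formula exists; this one is consistent with CI ≥ van't Riet, which holds
identically since van't Riet = CI × selectivity) and is configurable in the
reporting layer. The van't Riet number is defined as 0 when no voxel
reaches the prescription isodose. Method comparison uses the classic
equal-variance two-tailed Student's t-test (Welch available via option);
two zero-variance samples with equal means give p = 1 by convention.

## Scaled-down study conditions

Desk-scale (single CPU) problem sizes used by the heavier tests, chosen as
the smallest sizes at which the respective phenomenon is stable:

* overfit recovery: one noise-free 32³ phantom, tiny HDA (3 levels, growth
  4, gate width 8), 200 epochs, MSE loss;
* DVH-loss benefit: twenty 16³ phantoms with strong OAR sparing (0.5),
  same tiny HDA, 12 epochs, three seeds, evaluated by mean absolute
  held-out exact-DVH-curve error;
* reproducibility: a six-case 16³ experiment run twice and compared byte
  for byte.

At these sizes the DVH-loss benefit reproduces directionally on every seed
tried; statistical significance at desk scale is not expected (test sets of
2–3 cases).

## Known limitations

* CPU-only: full-resolution clinical training (128×128×96, 200 epochs,
  hundreds of cases) is out of reach; the architecture and losses are
  exact at any scale, but headline clinical numbers require GPU training.
* Batch normalization with batch size 1 normalizes spatially; this matches
  the training protocol but differs from large-batch BN statistics.
* The OpenKBP reader implements the sparse-CSV voxel-list layout on a
  fixed 128³ grid; DICOM-RT is out of scope.
* Attention-variant base width (32) is a documented choice; only its
  parameter total (~26M) is externally constrained.
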