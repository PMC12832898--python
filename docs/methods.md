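# Methods

## Problem and model

`sphtract` performs voxel-wise segmentation of white-matter tracts from
diffusion MRI, taking as input the *full* fiber orientation distribution
function (fODF) of every voxel rather than a handful of extracted peak
vectors. An fODF is a non-negative, antipodally symmetric function on the
sphere; expressed in the real even-order spherical-harmonic (SH) basis up to
order `lmax = 8` it is a 45-vector per voxel. Keeping all 45 coefficients
preserves the weak secondary lobes that peak-based inputs discard — exactly
the information needed in crossing-fiber voxels (several differently oriented
populations in one voxel) and bottleneck corridors (distinct tracts merging
along one shared orientation before diverging).

Segmentation is *single-class*: one independent binary 2D U-Net per tract.
Voxels that belong to several tracts in the reference are positive for every
relevant tract's model, so overlap carries no inter-tract competition. A
multi-label mode (one model, C sigmoid channels, per-channel BCE) exists for
the multi-class comparison; a softmax "one label per voxel" formulation is
deliberately not offered because tract masks overlap.

At inference a volume is sliced along all three anatomical planes, each 2D
slice is segmented independently, the three restacked 3D probability maps
are averaged voxel-wise, and the average is thresholded strictly above 0.5.
Ties at exactly 0.5 are negative; strictness was an open choice and is pinned
so behaviour is bit-stable. No connected-component cleanup or hole filling is
applied.

## Spherical-harmonic layer

Convention (pinned, matching MRtrix-style 45-channel fODF files): orthonormal
real symmetric basis, flat index `j(l, m) = l(l+1)/2 + m` over even `l`,
with `m < 0 → √2·Im(Y_l^|m|)`, `m = 0 → Y_l^0`, `m > 0 → √2·Re(Y_l^m)`.

* **Projection** is weighted least squares on a deterministic Fibonacci
  hemisphere (N = 724 by default) — stable, dependency-light, and exact (to
  round-off, < 1e-8) for band-limited inputs.
* **Orthonormality checks** use a Gauss–Legendre × uniform-azimuth product
  grid, which integrates products of basis functions exactly, so the Gram
  matrix is identity to machine precision.
* **Peak extraction** finds grid local maxima on the hemisphere, refines each
  by up to 10 steps of projected gradient ascent (finite-difference tangent
  gradient with a backtracking step, undoing the ~5° grid quantization),
  merges peaks closer than 10°, discards peaks below 0.1 of the global
  maximum (suppresses noise lobes without hiding genuine secondary fibers),
  and returns at most K = 3 amplitude-sorted peaks. A constant fODF has no
  local structure and yields zero peaks. Recovery accuracy is ≪ 2° for
  Watson lobes with κ ≥ 15 crossing at ≥ 45°.

## Synthetic phantom

The generator emulates the study inputs (4D SH fODF volume + overlapping
binary tract masks) with tubes of configurable radius around 3D polylines.
Each tract contributes a **Watson-kernel** lobe `C(κ)·exp(κ(u·μ)²)` along its
local segment direction — antipodally and axially symmetric, representable at
`lmax = 8` with small truncation error, and normalized to unit mass via the
confluent hypergeometric function. Coefficients are obtained by sampling the
kernel on the projection grid, so arbitrary orientations need no rotation
machinery. Where `n` tracts cover a voxel, each contributes with fraction
`1/n`; an isotropic background (constant fODF value, default 0.02) is present
everywhere.

Scenarios:

* **crossing** — two orthogonal straight tubes through the centre; their
  intersection carries two ~90° peak pairs;
* **bottleneck** — two U-shaped tubes whose middle segments coincide along a
  central corridor: inside the corridor both lobes point along the corridor
  axis, so a clean fODF shows *one* dominant orientation while both masks are
  positive — the assignment ambiguity the single-class formulation targets;
* **single** — one straight tube.

Defaults: volume side 48 (desk scale; 144 supported to mirror full-resolution
grids), tube radius 3 voxels, κ = 20, noise σ = 0. Noise is i.i.d. Gaussian
added **in coefficient space** (the representation the model consumes), not
to a simulated diffusion signal. Everything derives from the spec seed;
identical specs give bit-identical datasets.

What the phantom does *not* emulate: anatomy-shaped tract geometry, partial
volume with grey matter/CSF, Rician signal noise, spatially varying fODF
amplitude. Passing tests therefore demonstrate that the pipeline's mechanics
(representation, training, fusion, metrics) are correct and that the network
can exploit orientation structure; they do not certify segmentation accuracy
on real acquisitions.

## Preprocessing

* Central crop to a uniform shape (e.g. 145×174×145 → 144³) with offset
  `floor((dim − target)/2)` per axis — deterministic, leftover voxel on the
  high side.
* Normalization divides all 45 channels by the mean j=0 coefficient over
  foreground voxels (j=0 > 0), making inputs invariant to the arbitrary
  global scale of fODF reconstructions. (Input scaling was an open choice;
  this is the package's.)
* Tri-plane slice extraction; one network sees slices from all three views
  (per-view-specialized networks would triple parameters without a stated
  benefit). Slice/stack round trips are exact.
* No spatial flips/rotations as augmentation: rotating an fODF image without
  reorienting its SH coefficients corrupts the representation. Empty-label
  slices are kept — negatives teach background suppression.
* Subject-wise splits are disjoint and exhaustive; 105 subjects at
  (0.6, 0.2, 0.2) give 63/21/21.

## Network and training

The 2D U-Net is implemented directly in numpy with hand-derived
backpropagation (3×3 stride-1 same-padding convolutions via im2col, leaky
ReLU slope 0.01, 2×2 max pooling, 2×2-stride-2 transposed convolutions,
skip concatenation at equal resolution, dropout after each encoder block,
1×1 sigmoid head). Gradients are verified against central finite differences
in float64 (agreement ~1e-7). Default width/depth (base 64, depth 5, two
convolutions per level) put the full-fODF model near 31 M parameters; the
exact per-layer filter counts of the reference architecture are not
recoverable, so width and depth are configuration knobs. Switching the
9-channel peak input to the 45-channel fODF input changes only the first
convolution: +9·64·36 = 20 736 weights.

Training: per-channel binary cross-entropy (predictions clipped at 1e-7),
Adam, batch size 200 (desk runs use smaller), cosine annealing from
lr₀ = 0.002 with `T_max = max_epochs` and `eta_min = 0` (no warm restarts),
up to 400 epochs, dropout 0.4, early stopping when validation Dice has not
improved for 50 evaluations. Validation Dice is computed on **fused,
thresholded 3D volumes** — the quantity reported at test time — not
per-slice; the best-validation checkpoint is returned. Runs are
bit-reproducible for a fixed seed and platform (weight init, shuffling and
dropout masks all derive from the seed). Non-finite losses abort with a
diagnostic rather than training through NaNs.

## Metrics and statistics

From confusion counts (TP, FP, FN, TN): Dice, volumetric overlap
VOP = TP/|G|, volumetric overreach VOR = FP/|G|, specificity, precision,
Jaccard. VOR is measured relative to the *reference* volume (the tractometry
convention): relative to the prediction it would equal 1 − precision and be
redundant. The identity `dice = 2·vop/(1 + vop + vor)` holds whenever
|G| > 0 and is asserted in tests. Undefined metrics on an empty reference are
NaN sentinels, never silently 0 (phantom tracts can be absent in edge
configurations); aggregation excludes them and reports the excluded count.
Spread is reported as the sample (n−1) standard deviation.

Method comparison: two-sided Wilcoxon signed-rank on paired per-tract scores
with zero differences dropped, exact null for ≤ 25 remaining pairs and the
continuity-corrected normal approximation above, Bonferroni-adjusted
`p = min(1, m·p_raw)`. Identical score vectors give p = 1 by convention.

## Problem sizes used in tests

The automated suite exercises the full pipeline at desk scale: S = 16
phantoms for unit tests and S = 32 for the end-to-end check, where a reduced
network (depth 3, base 8, ~120 k parameters) trained for 60 epochs per tract
reaches fused 3D Dice ≥ 0.90 on the seeded crossing phantom and keeps the
tract-overlap voxels positive in both single-class models. These sizes were
chosen so the whole suite runs in minutes on one CPU while still covering
every stage; they are not claims about full-resolution behaviour.

## Known limitations

* The numpy backbone is single-threaded BLAS-bound; full-resolution
  (144³, depth-5/base-64) training is out of its intended scope.
* Peak refinement uses finite-difference ascent; analytic SH gradients would
  be faster but add no accuracy at the 2° tolerance tested.
* The phantom's tract geometry is piecewise linear; curvature effects on
  slice statistics are not modelled.
* No test-time augmentation, ensembling, or morphological postprocessing.
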