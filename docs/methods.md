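# Methods

This note records the model, the numerical choices, and the reasoning
behind the design decisions in `corthick`, in the spirit of a methods
appendix.

## Model

Cortical thickness is defined in the Laplace sense: the GM ribbon is the
domain of the harmonic potential ψ with Dirichlet boundaries ψ = 0 on WM
and ψ = 256 on everything beyond the GM–CSF surface. The level sets of ψ
form nested, non-intersecting intermediate surfaces; the streamlines of
∇ψ connect the two boundaries exactly once, so the streamline length
through a voxel is a well-defined, fold-respecting thickness. This is a
voxel-based formulation: no surface meshes are reconstructed.

Detection rests on the assumption that, after spatial normalization into
a common space (upstream of this package), the thickness at a voxel is
approximately Gaussian across healthy subjects, so (t − μ)/σ is an
interpretable z-score and a fixed threshold (3) controls false positives.
The cluster-extent filter (> 3 voxels) removes isolated supra-threshold
voxels produced by segmentation noise.

## Numerical procedure

**Solver.** Plain Jacobi (simultaneous update from the previous iterate),
each GM voxel replaced by the arithmetic mean of its six face-neighbours.
All non-GM, non-WM voxels (CSF *and* background) are clamped to 256:
with discrete tissue labels there is no way, nor any need, to distinguish
"CSF adjacent to cortex" from "outside the head". GM is initialized to
128, the boundary midpoint; the fixed point is initialization-independent
and this halves the iteration count relative to a zero start. The
per-sweep change ε is aggregated over GM voxels by the **maximum**
(strictest reading of a per-voxel stopping rule; configurable to mean)
and iteration stops at ε < 0.1 by default. The update is a convex
combination of neighbour values, so the discrete maximum principle holds:
ψ stays in [0, 256] after every sweep, and the test suite asserts it.
GM components that do not touch both boundary classes are detected
up front (6-connected component analysis), warned about, and excluded
from thickness.

**Gradient and tangent.** Central differences
[ψ(x+1) − ψ(x−1)]/2 per axis, one-sided at grid edges (`numpy.gradient`
implements exactly this). The tangent is the gradient divided by its
**Euclidean norm**. A formulation that divides by the *squared* norm
while calling the result a unit vector is internally inconsistent —
tracing geometry requires |T| = 1 — so the square root is taken; this is
treated as the corrected form of the printed expression. Voxels with
gradient norm below `gradient_floor` (default 1e-6, plateaus of ψ) are
flagged undefined instead of divided.

**Tracing.** From every GM voxel centre, forward Euler along +T and
backward along −T with step size 0.1 voxel. Tangent components are
trilinearly interpolated at fractional positions and renormalized;
tricubic interpolation was not evaluated. A continuous position carries
the tissue class of its **nearest voxel** (round-to-nearest), and a trace
terminates on the first non-GM sample; positions are clamped to the grid.
Thickness = (forward + backward steps) × step × voxel size. The step cap
defaults to 10 × grid diagonal / step; capped traces are flagged
truncated and their voxel invalid. Expected discretization error is one
voxel of boundary quantization plus O(step) integration error — the test
contract is ±(2 × step × voxel + 1 voxel) per voxel and 1 voxel on
phantom means.

**Smoothing.** A 4³ box kernel has no centre voxel; the window is
anchored to offsets {−2, −1, 0, +1} per axis (configurable to the mirror
image). Smoothing is **mask-normalized**: weights are renormalized over
valid GM voxels, so ribbon-edge values are averages of real neighbours
rather than being diluted toward zero. An unnormalized convolution would
bias edge thickness low in every subject and patient alike, and the bias
would not cancel in the z-score because patient and template GM masks
differ. Consequence: with a renormalized even kernel the global mean is
preserved only approximately (edge windows are re-weighted); the suite
asserts stability to 1%, not exactness. Output values are convex
combinations of inputs, hence never leave [min, max].

## Template and detection

Voxel-wise mean and **sample SD (n − 1)** over controls. The n − 1 choice
is pinned by the reporting convention the published summary tables
follow: the three-patient recall set {74.34, 67.71, 60.32} has sample SD
7.01 (population SD would be 5.73), and 7.01 is the printed value. A
voxel enters the template only if ≥ 75% of controls (and ≥ 2) are valid
there, since independently processed GM masks disagree at the ribbon
edge. SDs below `sd_floor` (default 1e-3 mm) mark the voxel invalid
rather than producing huge z-scores from numerically degenerate variance.

Both detection comparisons are strict: a lesion voxel has z **>** 3, and
a reported cluster has **more than** 3 voxels (i.e. ≥ 4). "Larger than
three" is ambiguous between > 3 and ≥ 3; the strict reading is the
default and `strict_cluster_rule=False` selects the inclusive one.
Connectivity defaults to 6 (face adjacency), configurable to 18/26.

All seven evaluation metrics are on the percent scale. The Youden index
"recall + specificity − 1" is interpreted as − 100 on that scale, which
the published per-patient values confirm (74.34 + 99.86 − 100 = 74.2).
The AUC is the single-threshold form 1 − (FPR + FNR)/2 — algebraically
(specificity + recall)/2 — not an integrated ROC sweep. Zero-denominator
metrics are reported as explicitly undefined, never silently 0 or 100.
The evaluation domain (whole grid vs brain vs GM mask) strongly drives
specificity and accuracy under class imbalance and is therefore an
explicit parameter with no claimed equivalence to any published choice.

## Phantoms

The generator emulates exactly what the pipeline consumes: tissue-label
geometry. Slabs test the parallel-plate limit (straight field lines,
thickness = width); spherical shells test curvature (radial field lines,
thickness = r2 − r1, potential matching the closed-form
256·(1/r1 − 1/r)/(1/r1 − 1/r2)). Cohort variability is injected by
jittering the **boundary parameters** (N(0, 0.2 voxels) per boundary by
default, 32 subjects), not by voxel-wise noise, so each subject retains
an exact analytic thickness — the property that makes SD-recovery tests
possible (two independent boundaries give thickness SD = jitter·√2).
Lesions displace the GM–CSF boundary outward inside a spherical patch
with a 2-voxel cosine taper at the rim (avoiding single-voxel staircase
rims); implementation is geometry-agnostic via the Euclidean distance
transform to the existing ribbon, and the ground-truth mask is the new
GM ribbon inside the patch sphere.

What phantoms do **not** emulate: cortical folding and sulcal partial
voluming, segmentation error correlated with anatomy, registration
residuals, and non-Gaussian between-subject variation. Passing tests
therefore demonstrate correctness of the numerics and the detection
logic under the model's assumptions, not clinical sensitivity on real
FLAIR-negative MRI.

## Problem sizes and defaults

Unit and property tests run on 10³–36³ grids; analytic-recovery checks
use 64³ grids (the slab and shell studies) and the synthetic control
study uses 32 subjects on 48³ shells — sizes at which every reported
quantity is stable to well within its test tolerance while the whole
suite stays interactive (seconds, not minutes). Reference parameter
defaults: solver tolerance 0.1 (max statistic), trace step 0.1 voxels,
smoothing kernel 4³, z threshold 3, cluster extent 3, connectivity 6,
`sd_floor` 1e-3 mm, `gradient_floor` 1e-6.

## Known limitations

- Isotropic grids only: thickness multiplies a step count by a single
  resolution, so anisotropic inputs are rejected at ingest (resample
  upstream).
- Discrete labels only: no partial-volume or probabilistic-segmentation
  handling beyond user-side thresholding.
- Forward Euler with trilinear tangents under-resolves field lines in
  very high-curvature ribbons; step 0.1 voxel keeps the error below the
  voxelization floor on the geometries tested.
- The cluster rule suppresses true lesions smaller than 4 supra-threshold
  voxels after smoothing; lesions in cortex that is normatively thick
  (high μ and σ) can stay below z = 3 entirely — the classic missed-TLE
  failure mode this family of methods shares.
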