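# Methods

This note documents the models, parameters, and numerical choices behind
`fetatlas`, and what the synthetic phantoms do and do not establish.

## Temporal model

The atlas's temporal axis is gestational age in integer days
(week-labelled groups sit at `7·week` days). A session contributes to a
group through a truncated Gaussian kernel with standard deviation
σ = 3 days, cut off at 3σ = 9 days; the inclusion window and the kernel
support therefore coincide, and the window predicate is inclusive
(`|ΔGA| ≤ 9`). σ = 3 days makes `[−σ, σ]` span roughly the one-week
spacing of the atlas. Groups must have at least three members before
flip augmentation and must contain ages strictly above and strictly
below the target; a member exactly at the target counts as neither
(the bracketing wording refers to "higher and lower" ages, and the
equality case is not specified elsewhere, so strictness is the
conservative reading).

## Coordinate conventions

All rasters are reoriented to canonical RAS on load; the first axis is
left→right, so the "central sagittal plane" is the physical mid-plane of
the grid along axis 0, halfway between the first and last voxel centres.
The mirror operator `S` reverses axis 0; it is an involution voxelwise.
Landmark mirroring reflects coordinates about the plane and swaps
left/right identities through the registry's mirror-partner table;
midline landmarks keep their identity.

## Weighted generalized Procrustes

The alignment problem is

  min over {M_i, t_i}, {g_k} of ½ Σ_{i,k} w_{i,k} ‖M_i x_{i,k} + t_i − g_k‖²

with `M_i` diagonal (anisotropic scaling), `w_{i,k}` the temporal weight
zeroed for missing landmarks, and two gauge-fixing constraints: the
consensus centroid equals the centroid of the weighted per-landmark
means `x̄_k`, and the consensus "size" (mean squared deviation about its
centroid) equals that of the `x̄_k`.

Numerics:

* **Transform step** — separable: per sample and axis, a weighted simple
  linear regression of (scale, offset) against the current consensus.
  Degenerate axes (fewer than two positively weighted landmarks, or no
  spread) fall back to scale 1 with the weighted mean residual as
  offset. The previous iterate is always kept as a candidate, so the
  step never increases the objective.
* **Consensus step** — the constrained weighted least-squares problem is
  solved exactly: stationarity gives `g_k = c + (W_k a_k − μ)/(W_k + λ)`
  with `μ` enforcing the centroid and `λ` the root of a one-dimensional
  secular equation (bracketed Brent). Both alternation steps are exact
  block minimizations, so the objective trace is non-increasing by
  construction; a final exact projection removes residual float error
  (constraint residuals below 1e-8).
* **Polish** — alternation alone creeps along a very flat valley on
  realistic instances. Since the constrained-optimal consensus is
  available in closed form, the transforms' reduced objective is smooth
  and unconstrained apart from the scale box, and L-BFGS-B finishes the
  convergence. Multi-start (identity first, then seeded local and
  box-wide random initializations) guards against local minima; the run
  is deterministic for a fixed seed.
* **Scale box** — scales are confined to [0.5, 2]. The pooled size
  constraint prevents total collapse of the consensus but not partial
  collapse along one axis (all scales on an axis → 0, another axis
  inflated), which can be the unconstrained global optimum yet is
  anatomically meaningless; within a ±9-day group, true relative
  scalings are within a few percent of 1, so the box is generous.
* Convergence: relative objective change below 1e-10 or 200 iterations
  (60 before polish in the test configuration).

## Averaging and normalization

Intensities are mapped linearly so that the in-mask mean and standard
deviation are exactly 2000 and 500; the same affine map applies outside
the mask. The symmetric time-weighted average
`(1/2N) Σ w_i (I_i + S(I_i))` preserves the intensity scale only when
`Σ w_i = N`; the weights are therefore renormalized to sum to `N`,
making the operator a convex combination of symmetrized volumes (whether
the original formulation renormalizes is unstated; without it the atlas
intensity would drift with group size). The output is re-symmetrized
(`(x + S(x))/2`) to force bit-exact mirror invariance against float
rounding. Probability maps average per class — all eight tissue classes
are bilaterally self-symmetric, so no class permutation is needed — and
argmax parcellation breaks ties toward the lowest class index.

## Registration

The transform maps fixed (subject) physical points to moving (atlas)
physical points: `φ(x) = A x + u(x)`, with `A` an affine initialization
and `u` a cubic B-spline displacement on a 3 mm control lattice that
covers the fixed grid plus one control-cell margin.

* **Affine initialization** — per-axis least-squares scaling+translation
  on shared landmarks (≥ 4 required), else moment matching of the brain
  masks (centroids and per-axis second-moment ratios). This replaces an
  external block-matching tool; the initializer is a means, not part of
  the method's substance.
* **Similarity** — LNCC: the mean over in-mask fixed voxels of the
  squared local correlation coefficient. Local moments use
  window-normalized Gaussian smoothing (`S(x) = K(x)/K(1)` with `K`
  zero-padded, 6 mm sd), which keeps the statistic exactly invariant
  under affine intensity rescaling even near the grid boundary. A
  1e-6 guard on local variances handles flat windows. Values lie in
  [0, 1] up to the guard.
* **Regularization** — bending energy (mean squared second spatial
  derivatives, mixed terms counted twice) and linear energy (mean
  squared Frobenius norm of the symmetric displacement Jacobian), both
  evaluated by interior finite differences on the control lattice;
  translations have zero energy and infinitesimal rotations have zero
  linear energy. Weights α_BE = 0.1, α_LE = 0.3, α_LMKS = 0.001,
  α_LNCC = (1−α_LMKS)(1−α_BE−α_LE) ≈ 0.5994 — the published tuned
  values; α_LNCC is always derived, never set.
* **Optimization** — three pyramid levels (×4, ×2, ×1 downsampling of
  the fixed grid with matched smoothing of the moving image; control
  spacing 12/6/3 mm), L-BFGS-B per level with analytic gradients for
  the landmark and regularization terms and an analytic LNCC gradient
  chained through sampled central-difference gradients of the moving
  image. Line search guarantees the cost is non-increasing across
  accepted steps; the procedure contains no randomness (the seed
  argument exists for interface uniformity). Coarse coefficients seed
  the finer lattice by evaluating the displacement at the new control
  points.
* **Direction conventions** — label propagation pulls the atlas
  parcellation onto the subject grid through `φ` (nearest neighbour), so
  no numerical inversion is needed. During refinement the atlas serves
  as the fixed domain and each member as moving, which directly yields
  members resampled onto the atlas grid for re-averaging. Consensus
  landmarks stay fixed at the Procrustes solution across refinement
  (whether they should be re-estimated is unspecified; keeping them
  fixed keeps the landmark term anchored).

The atlas grid is the consensus frame voxelized at the input spacing on
the bounding box of the transformed masks padded by 5 voxels, with the
x-range symmetrized about the consensus midline so the grid's central
sagittal plane coincides with it. Mask averages are thresholded at 0.5.
Refinement default is 2 iterations (the iteration count is not pinned by
the method; it is configurable and logged). Diffeomorphism is not
guaranteed.

## Atlas-based segmentation and evaluation

Segmentation picks the time point with matching operation status and
nearest target age (ties to the younger), registers without landmarks —
prospective subjects have none — propagates the parcellation by nearest
neighbour, and merges the corpus-callosum label into white matter,
leaving seven evaluated tissue classes plus whole brain. Dice is
`2|A∩B|/(|A|+|B|)` (two empty masks score 1); HD95 is the larger of the
two directed 95th-percentile distances between boundary-voxel surfaces,
in mm, via KD-trees.

Reliability analysis fits a Gaussian to Euclidean repeat-annotation
distances (sample sd, ddof 1). The Gaussian can put mass below zero for
non-negative distances; that is the model's stated assumption, kept as
is. Percentiles are `mean + z_q·sd`. The agreement probability uses a
radius of √3 × voxel size by default — the circumscribed sphere of the
3×3×3-voxel agreement cube. The cube predicate (a box) and the Gaussian
distance model (a sphere) are not mutually consistent, so the radius is
an explicit parameter and the empirical cube-agreement rate is reported
alongside the model-based probability. A landmark's missing ratio counts
volumes where it is absent in either session; landmarks with fewer than
two doubly-present pairs are flagged without a category.

## Synthetic phantoms

The phantom is a nested-ellipsoid brain: a white-matter interior inside
cortical-grey and extra-axial-CSF rims, two enlarged lateral-ventricle
lobes (the severity parameter scales them by up to 1.8×), a deep-grey
core, a corpus-callosum bridge, a posterior cerebellum, and a brainstem
cylinder — the eight parcellation classes. The brain scales linearly
with gestational age (factor 1.0 at 21 weeks to 1.8 at 34), tissue
intensities are constant means plus Gaussian noise and an optional
low-order polynomial bias field, and the seven retained landmarks sit at
closed-form loci (ventricle anterior tips, posterior tectum pole,
cerebellar-brainstem junctions, deep-grey lateral borders) that are
exact mirror pairs in the base shape. Perturbations apply a known
scaling+translation about the grid centre plus an optional smooth random
warp; images are pulled back through the fixed-point-inverted forward
map and landmarks are mapped forward exactly, so recovery errors can be
measured against ground truth. Cohorts draw per-subject severity and
per-session anatomical jitter; operated subjects are only imaged after a
surgery age of about 25 weeks.

What the phantoms do not emulate: anatomical detail (gyrification,
tissue-boundary complexity), acquisition physics, motion or
reconstruction artifacts, and real inter-subject shape variability
beyond affine-plus-smooth-warp. Passing tests therefore establish the
correctness of the algorithms and their implementations — exact
symmetry, constraint satisfaction, recovery of known transforms,
self-consistency of propagation — not clinical segmentation accuracy on
real fetal MRI.

## Problem sizes

Tests and examples run on 48³ grids at 1 mm spacing with three-subject
groups (six members after flip augmentation) and one refinement
iteration; the registration recovery study uses warps of at most
2.5–3 mm over five seeds. These are the smallest configurations that
keep all eight tissue classes resolvable and every pipeline stage
non-trivial.

## Known limitations

* The registration similarity gradient is exact only up to the sampled
  image-gradient approximation; L-BFGS may terminate early rather than
  at a strict stationary point.
* The Procrustes solver is a multi-start local method; agreement with a
  multi-restart black-box optimizer is verified on small instances, not
  proven globally.
* The FFD is not constrained to be diffeomorphic; strong warps can fold.
* The 4 cavum-septi-pellucidi landmarks are registry members for
  reliability analysis only (`retained=False`); no phantom locus is
  generated for them.
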