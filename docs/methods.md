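# Methods

This note records the models, conventions and numerical choices behind
`dendromorph`, in the order the pipeline applies them, together with what
the synthetic-data generator does and does not emulate.

## Tree-graph model

A skeleton is a directed tree `T = (V, E, r)` embedded in ℝ³: edges point
away from the root, each edge carries its Euclidean length (µm), and the
total cable is `W(T) = Σ w(e)`.  Out-degree 0 marks leaves, ≥ 2 branch
nodes.  The *reduced* tree contracts every maximal run of pass-through
nodes (in- and out-degree 1) into a single *section* whose weight is the
summed cable; a section ending at a leaf is *external*, otherwise
*internal*.  Node depth `h(v)` is the **unweighted** step count of the
root path; the cable distance to the root is exposed separately
(`root_cable_distance`) because the two are easy to conflate and only the
integer depth is used for depth-binned profiles.  An edge inherits the
depth of its distal node.

SWC is the interchange format (7 whitespace-separated columns, parent −1
at the root); coordinates default to µm with an `nm_to_um` flag.
Zero-length edges (duplicate coordinates) are merged at parse time with a
warning because they break all downstream angle computations.
Resampling inserts/merges pass-through nodes at a fixed arc-length step by
linear interpolation on the original polyline; branch and leaf coordinates
are preserved exactly, and cable shrinks only by corner-cutting when the
step exceeds the native spacing.

## Dendrite annotation

Each branch node is scored with `Φ(v) = 1 − W(T_v)/W(T) + L_v/L`
(cable fraction down, leaf fraction up; `Φ ∈ [0, 2]`).  Ties break by
higher leaf fraction, then smaller node id, for reproducibility.  The root
is a candidate only when it branches.  Manual review is replaced by an
`override` argument (honoured even for non-branch nodes, with a warning)
plus the attached score table for inspecting low-margin cases.  A tree
whose root already carries the `dendrite_root` label is a fixed point of
annotation: for an isolated dendrite `Φ(root) = 1` exactly while a
leaf-dense proper subtree can score higher, so re-running the argmax would
wrongly strip cable from an accepted dendrite.

## Alignment and scaling

Global alignment per population: least-squares algebraic sphere fit
(linear in centre and squared radius — closed-form and deterministic;
residuals are reported so a bad fit is visible), origin moved to the
centre, pooled principal axes rotated so PC1 → y (dorsal–ventral),
PC2 → x (anterior–posterior), PC3 → z (depth).  The four remaining
half-turn ambiguities are resolved with dorsal/anterior anchor landmarks
(dorsal must map to y > 0, anterior to x > 0); anchors replace an external
column-annotation database.

Per-dendrite alignment uses a robust covariance so a single outreaching
section cannot swing the eigenvectors: Huber weights
`w(r) = min(1, c/r)` on Mahalanobis radii normalized to median 1 under
normality, `c = 1.345` (the standard 95%-efficiency constant; the source
procedure names only a "Huber-type" function, so the constant is a package
choice and configurable).  The location update uses `w`, the scatter
`w²` — the standard Huber M-scatter, whose per-point influence on the
covariance is bounded by `c²`; a linear-in-`w` scatter has influence
growing with the outlier radius and provides almost no protection.  A
Gaussian consistency factor (computed by quadrature, cached) makes clean
data reproduce the classical estimate.  Eigenvectors are flipped toward
their positive target axes ("minimal rotation"); if the flips leave an
improper basis the least-aligned axis is flipped back so the rotation
stays proper.  Aligned dendrites are centred on their root.

Two scalings: `population_sd` divides all coordinates by `μ + 3σ` of the
leading eigenvalue over the type population (the literal reading — SD of
λ₁, not of √λ₁ — is the default; both interpretations are a parameter away
since the population statistics are passed in by the caller);
`unit_variance` divides each axis by its standard deviation, producing
spherical dendrites with untouched topology.

PC1-vs-DV angles are reported two ways: unsigned in [0°, 90°] (eigenvector
sign is arbitrary, so the axis angle is what is defined) and signed in
(−90°, 90°] in the AP–DV plane for symmetry checks about zero.

## Layer surfaces and depth

Layers are reconstructed from the pooled node cloud of all same-type
dendrites: bounding box padded 2 µm, 2 µm voxels, two iterations of
morphological **closing** (dilation then matching erosion, full 3×3×3
structuring element, 26-connectivity), largest connected component,
marching cubes, mesh cleaning (degenerate faces, unreferenced vertices,
hole filling, outward normals) and Taubin band-pass smoothing (λ = 0.5,
pass-band 0.01, 20 iterations — a band-pass smoother of the same family as
windowed-sinc, which trimesh provides natively).  Dilation alone would
thicken a thin layer by ~2 voxels per side and inflate every volume by a
factor ≈ 2 on a 10 µm sheet; the matching erosion keeps gap-filling
without the bias, and spherical-shell fixtures then reconstruct within 15%
of the analytic volume at the native voxel size.

Faces are classified by the dot product of their outward normal with the
unit ray from the population sphere centre to the face centroid: ≥ 0.3
outer, ≤ −0.3 inner, in-between tangential faces excluded.  Depth queries
use nearest inner/outer **face-centroid** distances (KD-trees), giving
`d_norm = d_inner/(d_inner + d_outer)`, inverted for T5 because it
innervates its layer from the opposite side of curvature; the T4/T5
complementarity `d_norm(T5) = 1 − d_norm(T4)` is exact by construction.
For the depth-vs-root-distance analysis, x is the Euclidean root distance
normalized by the per-dendrite maximum, and the endpoints x = 0 and x = 1
are excluded.

## Root nearest neighbours

Subtype-specific nearest neighbours use KD-trees per type–subtype cell,
self excluded.  The global subtype-agnostic pairing is the
maximum-cardinality matching of minimum total Euclidean distance over all
same-type roots; pairs are classified opposite (a–b, c–d), same, or
orthogonal (chance levels 0.25/0.25/0.5 under shuffled labels).  Up to 200
roots the matching is solved exactly with the blossom algorithm on the
complete geometric graph; beyond that (the blossom solver is O(n³)) a
greedy k-nearest-neighbour matching refined by local 2-opt pair rewiring
is used — never worse than greedy, within ~5% of the exact optimum in
benchmarks at n = 120, and immaterial for label-randomisation checks,
whose chance levels do not depend on the pairing.  The crossover is a
parameter (`exact_max`).  Odd n leaves one root unmatched.

## Section and bifurcation geometry

Angles between 3-D vectors are measured in a plane by rejecting both
vectors from the plane normal and taking `atan2(signed sine, cosine)`,
range (−π, π] (−π is mapped to +π).  Circular summaries report the mean
direction, the squared resultant `(Σcos)² + (Σsin)²` (the printed
dispersion statistic of the source formulation, kept verbatim as
`variance_stat`) and the conventional normalized circular variance
`1 − R/n`.  Radial section angles are signed angles between a section and
the ray from the dendrite root to the section source, with a per-dendrite
consistently oriented plane normal; sections sourced at the root are
excluded (the ray is undefined).

Bifurcations are extracted only at out-degree-2 branch nodes of the
0.1 µm-resampled skeleton, from unit vectors to points 0.1 µm of cable
away on each side.  The parent direction points **up-stream** (from the
branch node toward the root side).  This convention is what makes the
planar symmetric case read γ = ω = 3π/4, θ = π/2 and the angle sum 2π —
the down-stream convention would put the planar peak at π instead.  γ, ω,
θ are unsigned angles via clamped arccos.  Branch nodes with less than
0.1 µm of cable to the root are skipped and counted; child walks that hit
a leaf or the next branch first are truncated at that endpoint.
Trifurcations are preserved in the topology tables but excluded from
bifurcation geometry.

The dihedral angle β ∈ [0, π] is the angle between the children's bisector
`b = (ĉ₁ + ĉ₂)/‖·‖` and the parent direction, measured in the plane with
normal `(c₁ × c₂) × b`: π means a planar bifurcation opening away from
the parent, 0 one folded back onto it.  Degenerate bisectors (antiparallel
children) return NaN.

The null model draws triples of uniform unit vectors (normalized
Gaussians), rejection-resampled so the parent has negative and both
children positive x-components, then multiplies z-components by the cube
root of the mean PC3 variance-explained fraction (flattening to the
occupied space) and renormalizes.  All randomness is seeded.

## Topology metrics

With no pass-through nodes, `n = L + I` and `1 ≤ I ≤ (n−1)/2` (star and
full binary tree at the extremes); the bounds are asserted on every tree
and verified exhaustively over all 42 reduced topologies with n ≤ 9.
Weighted partition asymmetry at a branch node with k ≥ 2 children averages
over the C(k,2) child pairs
`|L_p − L_q| / (L_p + L_q − 1) · (W_p + W_q) / W(T)`, where a child
subtree's leaf count includes the child itself and its cable excludes the
connecting edge (this is what reproduces the hand-worked caterpillar
profile {0.25, 0}).  The normalizer is the whole-tree cable as printed; a
`local_norm` flag switches to the subtree-at-v cable.  Section records
carry kind, distal-node depth, cable length, chord, and within-section
curvature as unsigned angles between raw edges and the section chord
(deviation magnitude, no plane projection).

## Distribution selection

Six positive-support families, no location shifts: Wald (inverse
Gaussian; closed-form MLE μ̂ = x̄, λ̂ = n/Σ(1/x − 1/x̄)), log-normal
(moments of ln x), exponential (θ̂ = x̄), and numerically fitted gamma,
log-logistic and minimum Weibull (scipy MLE with the location pinned at
zero, method-of-moments starts).  `BIC = k ln n − 2ℓ(θ̂)` with k = 2
(1 for exponential); lower wins, ties within 1e-6 go to fewer parameters,
non-converging fits are excluded with a warning.  Model identification at
n = 5000 exceeds 90% for every family against the other five; the
exponential-vs-gamma pair is resolved by the penalty.  Groups below 50
observations are skipped.

## Effect statistics

OLS with full factorial structure and **sum-to-zero contrasts** (without
which Type-III sums of squares depend on level ordering), Type-III ANOVA/
ANCOVA via statsmodels.  Partial η² = SS_effect/(SS_effect + SS_error);
benchmarks 0.01/0.06/0.14 for small/medium/large.  Cohen's
d = (μᵢ − μⱼ)/s_pooled with s_pooled = √((σᵢ² + σⱼ²)/2); benchmarks
0.2/0.5/0.8.  Uncertainty comes from stratified percentile bootstrap
(1000 resamples by default, strata = the design cells, 95% level — the
level is an assumption exposed as a parameter).  The decision rule: an
effect is *meaningful* iff the point estimate and the entire CI clear the
small threshold (for signed d, applied to the magnitude with a
sign-consistent interval).  p-values are computed but drive nothing, and
no multiplicity correction is applied — the threshold rule, not
significance, is the filter; with many contrasts this is deliberately
conservative about direction, not about family-wise error.

Empirical probability mass functions are unsmoothed histograms on bin
edges shared across compared groups.  Pooled mode attaches a bootstrap CI
per bin; per-dendrite mode reports the mean of per-dendrite epmfs (which
sums to 1) with asymmetric MAD error bars around the per-bin median:
`MAD_low = median{|xᵢ − x̃| : xᵢ < x̃}` and correspondingly above.  An
empty side contributes 0.

## Synthetic populations

The generator's job is to plant exactly the signatures the analysis
measures, under one seed, so recovery can be asserted:

- **Lattice** — axial hex coordinates mapped to a spherical cap (radius
  200 µm, pitch 5 µm) by azimuthal equidistant projection, cropped to a
  DV-elongated ellipse so the population PC order is DV > AP > depth.
- **Roots** — four per column; the a–b pair and the c–d pair each
  co-locate (0.5 µm within-pair offset) with 2 µm between pairs, so
  opposite < orthogonal < same in nearest-neighbour distance, as the
  matching analyses expect.
- **Growth** — a tip-branching process (branch probability 0.8 per
  section, depth cap 7, trifurcation rate 0.04) run in an isotropic unit
  envelope and mapped affinely through the anisotropic envelope
  (semi-axes 10 × 7 × 2 µm, DV-elongated; per-dendrite elongation jitter
  plants the PC1–PC2 anticorrelation).  Each section's **final** length is
  drawn from the configured family — gamma(2.5, 0.52 µm) internally
  (mean 1.3 µm, with a 0.874 scale for T5), log-normal(0, 0.5) externally
  — and converted to unit-space length by the direction-dependent scale,
  so the planted families survive the map exactly.  Planarity of
  bifurcations also survives (affine maps preserve coplanarity), while
  the out-of-plane noise (0.08 rad) sets the spread of the 2π peak.
  Cardinal subtype headings (a:+AP, b:−AP, c:+DV, d:−DV, 0.15 rad jitter)
  are fixed points of the anisotropic warp.
- **Depth** — roots at 25% of a 4 µm layer with a planted outward tilt
  (deeper away from the root), plus a small depth wander.
- Randomness flows from `SeedSequence([seed, type, column, subtype])`, so
  populations are byte-for-byte reproducible and dendrites independent.

What it does **not** emulate: reconstruction noise and proofreading
artifacts, synapses, true column-map curvature gradients, soma and axon
compartments (dendrites are generated already isolated), and any
biophysics of growth.  Passing recovery tests therefore demonstrates that
the *estimators* are correct and calibrated on data with the assumed
statistical structure — not that real connectome data satisfy that
structure.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path: populations of 8–24 columns (64–192 dendrites), 100,000
null-model bifurcations, n = 5000 samples for family identification with
50 replicates, 200 null datasets for false-positive calibration, and
exhaustive enumeration at n ≤ 9.  All stochastic stages take explicit
seeds; reruns with the same configuration reproduce outputs exactly.

## Known limitations

- The large-n matching heuristic is near-optimal, not optimal; exact
  matching is available (and default) up to the configurable crossover.
- Depth uses face-centroid distances, slightly overestimating distances
  for coarse meshes relative to exact point-to-triangle distance.
- The bootstrap for η² refits the OLS per resample; at very large n and
  1000 resamples this dominates runtime (reduce `reps` or stratify less).
- The robust scatter tolerates but does not fully reject extreme
  contamination (bounded, non-redescending influence); with 5% gross
  outliers the smallest eigenvalue can still inflate by ~25%.
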