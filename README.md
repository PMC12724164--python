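# dendromorph

Population morphometrics of dendritic trees, built for the *Drosophila*
motion-detector neurons T4 and T5: skeletons in, effect sizes out.

T4 and T5 are the first direction-selective neurons of the fly visual
system.  Each comes in four subtypes (a–d), one per cardinal motion
direction, with four dendrites per visual column — T4 in Medulla layer 10,
T5 in Lobula layer 1.  Given a population of skeletonised dendrites, this
package asks whether their morphology differs by type or subtype at all
levels of description: spatial envelope, layer depth, root placement,
section orientation, bifurcation geometry, graph topology and
section-length statistics.

## What it computes

A neuron skeleton is modelled as a rooted, edge-weighted directed tree
`T = (V, E, r)` with Euclidean edge weights `w(e)` and total cable
`W(T) = Σ w(e)`.  On top of that core the library provides:

- **Dendrite annotation** — every branch node `v` is scored with
  `Φ(v) = 1 − W(T_v)/W(T) + L_v/L`; the argmax isolates the dendritic
  subtree (many leaves, little cable), replacing synapse-based
  axon/dendrite splits.
- **Alignment and scaling** — sphere-fit origin, principal axes mapped to
  the dorsal–ventral (y) and anterior–posterior (x) axes with anchor
  landmarks fixing the signs; per-dendrite alignment uses a Huber-type
  robust covariance; isotropic `1/(μ+3σ)` and per-axis unit-variance
  scaling.
- **Layer geometry** — voxel/marching-cubes reconstruction of the neuropil
  layer from pooled node clouds, inner/outer face partition by normal
  direction, and normalized depth
  `d_norm = d_inner/(d_inner+d_outer)` (inverted for T5).
- **Root neighbours** — subtype-specific nearest neighbours and the
  minimum-total-distance maximum-cardinality pairing of all same-type
  roots, classified opposite (a–b, c–d) / same / orthogonal.
- **Section & bifurcation geometry** — signed planar angles, circular
  statistics, radial section angles, the angular components γ, ω, θ of
  each bifurcation (planar outward bifurcations sum to 2π), the dihedral
  flatness angle β, and a seeded random-bifurcation null model.
- **Topology** — branch-count bounds `1 ≤ I ≤ (n−1)/2`, out-degree and
  leaf-depth profiles, weighted partition asymmetry
  `A_v ∈ [0, 1]`, per-section length/chord/curvature records.
- **Distribution selection** — maximum-likelihood fits of six right-skewed
  families (Wald, log-normal, gamma, exponential, log-logistic, minimum
  Weibull) ranked by `BIC = k ln n − 2ℓ(θ̂)`.
- **Effect statistics** — Type-III ANOVA/ANCOVA with sum-to-zero
  contrasts, partial η², Cohen's d, group slopes and Δβ, stratified
  bootstrap CIs, and the decision rule: an effect is *meaningful* only if
  the point estimate and its entire CI clear the small-effect threshold.
- **Synthetic populations** — a seeded generator that plants every
  signature above (column lattice on a spherical cap, co-located opposite
  roots, DV-elongated envelopes, near-planar bifurcations, known
  section-length families), so the whole pipeline is testable without any
  connectome download.

## A worked example

```sh
python examples/full_pipeline.py
```

generates a 12-column population (96 dendrites) and runs every stage:

```
dendrites analysed : 96
PC1 vs DV axis     : median |angle| = 22.8 deg (signed mean +6.3 deg)
variance explained : PC1 0.70, PC2 0.30, PC3 0.000
root pairing       : opposite-subtype fraction = 1.00 (chance 0.25)
bifurcations       : median angle sum = 360.0 deg (planar = 360)

section-length family winners per group:
type     kind         scaling    family  delta_bic_runner_up
  T4 external             raw lognormal            10.726476
  T4 external variance_scaled lognormal             7.724462
  T4 internal             raw     gamma            57.746141
  ...
```

Reading it: dendrites elongate along the dorsal–ventral axis (PC1 hugs DV
and carries ~70% of the variance), the nearest root of any dendrite is its
opposite subtype far above the 0.25 chance level, bifurcation angular
components sum to the planar 360°, and the BIC ranking recovers the
planted section-length family in every (type, kind, scaling) group with a
decisive margin.

The other scripts in `examples/` each demonstrate one capability
(tree metrics, annotation, the bifurcation null model, distribution
selection, effect sizes) and print a line on what the numbers mean.
There is also a thin CLI: `dendromorph synth --seed 1 --columns 30 --out
data/` and `dendromorph run --data data/ --out results/`.

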