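# Methods

This note documents the model implemented by `fmindreg`, the parameters
that matter, the numerical choices made where the design was open, what
the synthetic generator does and does not emulate, and the package's known
limitations.

## Foveated descriptors

A foveation operator is a bank of 2D blur kernels over a patch support S
(default 5×5, in the axial plane; the `plane_axis` option selects the
plane). The kernel at the patch centre is an isotropic Gaussian with
σ₀ = 1/(2π) voxel — effectively a delta on the integer grid (≥ 99% of its
mass at the central tap). For an offset u ≠ 0 the kernel is an elliptical
Gaussian with scale σ(u) = σ₀(1 + |u|), major axis (std √ρ·σ) along the
radial direction ∠u rotated by θ, minor axis std σ/√ρ, truncated at three
major-axis stds and L1-normalized. Defaults ρ = 2, θ = 0.

*Discretization floor.* A continuous Gaussian with sub-voxel std aliases
badly when point-sampled on the integer grid: the discrete covariance of a
kernel with minor std 0.22 voxel is dominated by the grid itself and the
designed elongation ratio ρ is destroyed. The across-axis std is therefore
floored at 0.5 voxel (the along-axis std scales with ρ accordingly). With
this floor the discrete covariance reproduces the designed axis ratio
within ~10% and the principal axis within 5° for every offset of a 7×7
support, verified numerically at build time of the design.

Patch values follow the foveation sum `value(u) = Σ_t I(x+u+t)·v_u(t)`;
`d_FOV(x₁, x₂)` is the squared L2 distance of the two foveated patches;
`V_FOV(x)` is the mean of `d_FOV(x, x+m)` over all m ∈ S. Boundaries are
mirror-padded (reflection without edge repetition; axes of length 1
replicate their single slice). Volumes are rescaled to [0, 1] before
descriptor computation so thresholds transfer across modalities, and
`V_FOV` is floored at 10⁻⁶·(intensity range)² to remain usable as a
denominator on flat regions. The exponent `d/V` is capped at 700 so
channels stay strictly positive in float64.

The descriptor channel for search offset r is `exp(−d_FOV(x, x+r)/V_FOV(x))`
normalized by the per-voxel maximum (so each voxel's largest channel is
exactly 1 — a per-voxel guarantee, not a global one). The search window is
the 3D six-neighborhood; patches stay 2D. During optimization the float
image's descriptors are computed once and resampled trilinearly
channel-by-channel through candidate displacements; they are not
recomputed on warped intensities (the standard choice for this descriptor
family, and the cheap one).

## Transform model

Cubic B-spline free-form deformation on a lattice with
`ceil(shape/spacing) + 3` vertices per axis (one margin ring before the
volume, two after), spacing default 8 voxels. Coordinates are 0-based
voxel indices; displacements are in voxels; warping is backward (pull)
with trilinear interpolation and nearest-edge clamping. The densified
field is the tensor-product B-spline interpolation of vertex
displacements and is C² by construction; unit tests verify the closed
form at sampled voxels.

`invert_displacement` computes the fixed-point inverse
`D(y) = −T(y + D(y))` (30 iterations), which converges for the smooth
warps used here and underpins the synthetic ground-truth construction.

## MRF energy and optimization

The energy is `E(l) = (1/|G|) Σ_p [V_p(l_p) + λ Σ_{q∈N(p)} ‖T_lp − T_lq‖₁]`
with λ = 0.01 and N(p) the 6-neighborhood of the vertex lattice (each
undirected edge therefore appears twice, once per endpoint).

*Data term scale.* `V_p` is the **basis-weighted sum** (a discretized
integral) of `SAD_F` between the reference descriptors and the float
descriptors resampled through the candidate displacement, over the
vertex's 4-cell support — not a weighted mean. The distinction matters:
the stated λ = 0.01 is calibrated against integral-scaled data terms
(~interior support weight ≈ spacing³ ≈ 512 times the mean SAD). With a
normalized mean the smoothness term dominates by two orders of magnitude
and the optimizer accepts almost no moves; with the integral the method
behaves as intended. A `normalize=True` flag retains the mean variant for
analysis. The candidate displacement is applied as a constant over the
support when scoring (first-order approximation, standard for discrete
FFD registration).

Labels are axis-aligned: {0} ∪ {±k·quantum·e_axis, k ≤ max_steps}
(defaults: 2 steps, quantum 2 voxels, so 13 labels reaching ±4 voxels).
Three outer iterations halve the quantum each time (2 → 1 → 0.5);
off-axis displacements emerge by composition across iterations. Within an
iteration, α-expansion visits labels in order of increasing L1 magnitude
(ties: lower index) for up to `max_cycles` sweeps. Each expansion move is
a min-cut problem — the L1 pairwise cost is a metric, so every move is
submodular — solved by `scipy.sparse.csgraph.maximum_flow` on
integer-scaled capacities (×10⁹), with the source side recovered by BFS
on the residual graph. A proposal is accepted only if the *exactly
recomputed* float energy strictly decreases, which makes the energy trace
non-increasing by construction and immune to capacity rounding. An ICM
fallback (`solver="icm"`) exists for debugging. Static vertices stay at
label 0 permanently but keep their smoothness edges, so the static region
regularizes the dynamic boundary; their (constant) zero-label data costs
are included in reported energies.

On enumerable instances (2×2×2 vertices, 7 labels, uniform random costs,
λ = 0.01) the solver matches the exhaustive minimum in ≥ 90% of cases and
is never worse than twice it (the metric-expansion bound); both facts are
asserted in the test suite and recomputed by the acceptance script.

## Vertex partition (spatial constraint)

For each vertex, the cube of radius `R_LP = 7` around its voxel position
is inspected in the voxelwise similarity map: `con` counts voxels with
`1 − SAD_F > δ` (δ = 0.8), and the vertex is static iff
`con/|LP| > ε` (ε = 0.9), both inequalities strict. Two boundary choices:
the patch size in the ratio is the *clipped* voxel count, so border
vertices are not biased toward dynamic; and margin vertices outside the
volume are clamped to the nearest in-volume voxel before clipping, so
every vertex sees a non-empty patch (identical images then freeze the
whole lattice, and fully dissimilar ones free it, as expected). The
partition is computed once from the initial similarity map;
`refresh_partition=True` recomputes it per outer iteration from the
currently warped float. Raising δ or ε (weakly) grows the dynamic set —
both monotonicities are property-tested. The registration mask is the
union of the dynamic vertices' (half-open) B-spline support boxes.

## Pipeline

rescale → descriptors for both volumes → SAD map → partition → per outer
iteration: per-label similarity volumes (float descriptors resampled
through current field + label), vertex cost tensors, α-expansion over the
dynamic vertices, vertex update → densify → warp. Identity initialization;
everything is deterministic given inputs and configuration (the config
seed is only recorded in the report). An optional 2-level Gaussian
pyramid (auto-enabled above 64³) registers at half resolution first and
composes the upsampled coarse field with the fine-level correction. If
every vertex is static the pipeline returns the identity with a warning
in the report rather than failing.

TRE compares displacement *vectors* sampled trilinearly at fixed landmark
positions (voxel units by default, mm with a spacing argument); a
point-mapping variant was considered and rejected as the default because
the synthetic ground truth is expressed in exactly the same
fixed-position convention.

## Synthetic generator

`make_phantom` sums smooth Gaussian blobs and sharp-edged (lightly
smoothed) ellipsoids — default 12 structures at 64³ — over a 0.1
background, rescaled to [0, 1]. `remap_modality` applies `identity`,
`invert`, `gamma` (exponent 2.2), or `nonmonotone-bands` (piecewise-linear
transfer through knots (0, .25, .5, .75, 1) → (.9, .2, .8, .1, .6), which
folds the intensity axis so no monotone mapping relates the two
modalities), then adds Gaussian noise (default σ = 0.02 on the [0, 1]
scale, ~2% — typical of modern MR) and clips. Both volumes of a generated
case carry independent noise realizations: a noise-free volume has a
collapsing `V_FOV` and saturated descriptors, which no real acquisition
exhibits.

The ground-truth warp is a linear combination of Gaussian RBFs (default
10 centers, width 24 voxels at 64³, i.e. organ-scale smooth deformation)
scaled so the peak displacement magnitude equals `amplitude` (default 4
voxels); with these defaults the mean displacement is roughly half the
peak, so the stated amplitude is representative of the deformed region.
The float image is the remapped phantom warped by the *inverse* of this
field, making the RBF field itself the exact recovery deformation at
every voxel — the TRE ground truth is exact, not approximate. Landmarks
are sampled from the top decile of the clean phantom's gradient
magnitude, ≥ 3 voxels apart, ≥ 4 voxels from the boundary.

What the generator does *not* emulate: anatomy, partial-volume effects,
bias fields, ultrasound speckle, resolution differences between
modalities, or rigid misalignment (volumes share a grid and need no
pre-alignment). Passing tests therefore demonstrate the machinery —
descriptor invariance to nonlinear intensity remapping, warp recovery at
the stated noise level, solver optimality — not clinical-grade accuracy.

## Problem sizes and defaults used in checks

The test suite and acceptance script run at 64³ for end-to-end studies
(five seeds, 30 landmarks, 4-voxel warps), 16³ for oracle equivalences
against literal transcriptions of the definitions, and 2×2×2-vertex
lattices for exhaustive solver enumeration — sizes at which every
reference computation is exact and the full suite completes in minutes.

## Known limitations

- Axis-aligned label sampling recovers oblique displacements only through
  iteration; a dense 3D label grid would converge faster at much higher
  cost.
- The transform is not guaranteed diffeomorphic; large labels with a
  coarse grid can fold the field.
- The data term's constant-displacement approximation over a vertex
  support degrades for warps that vary quickly within one grid cell;
  choose the grid spacing below the warp's correlation length.
- Registration assumes same-grid volumes; resampling/pre-alignment is out
  of scope.
- The partition inherits the sensitivity of its δ threshold to the noise
  level: at high noise, aligned regions of genuinely different modalities
  can exceed `SAD_F = 1 − δ` and the static set collapses (everything is
  optimized — slower, not wrong).
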