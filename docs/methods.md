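# Methods

This document describes the models, algorithms, numerical choices, and known
limitations of `dermafiber`. Units throughout: micrometre (um), micronewton
(uN), megapascal (MPa); 1 MPa x um^2 = 1 uN. The coordinate frame follows the
imaging convention: **Y is the skin surface normal and the compression axis**;
X and Z span the horizontal plane.

## 1. Scientific model

Aged skin loses firmness. The working hypothesis implemented here is that the
3D architecture of the dermal elastin fiber network — not just its amount —
controls the mechanical response of the dermis to compression. Aged dermis
shows more, smaller fiber clusters (a fragmented network), slightly thinner
fibers, and a loss of vertically oriented fibers; all of these should reduce
the force the tissue returns under a fixed compression.

The package represents this causal chain end to end:

1. **Synthetic architecture** (`synthetic`, `presets`): seeded random fiber
   networks with controllable count, diameter distribution, length
   distribution, vertical-fiber fraction, waviness, connectivity, and
   fragmentation. Nine presets reproduce the architecture of a nine-donor
   cohort (ages 38–78) by construction.
2. **Imaging emulation and processing** (`synthetic.voxelize_network`,
   `imaging`): rasterization to a grayscale confocal-like stack with blur and
   noise, then a standard segmentation chain back to measured fibers.
3. **Architecture quantification** (`fibers`): the six descriptors — mean
   fiber diameter, fiber count, elastin volume fraction, number of fiber
   clusters, maximum cluster size, vertical fiber proportion.
4. **Mechanics** (`mechanics`): an embedded-beam finite-element compression
   test of the fiber-plus-matrix composite; the reaction force under 20%
   compression is the firmness surrogate.
5. **Statistics** (`stats`): correlations, Welch group comparisons, and
   regressions linking architecture to firmness.
6. **Orchestration** (`pipeline`, `cli`): reproducible studies with
   manifests, checksums, and per-stage artifacts.

## 2. Fiber representation and architecture metrics

A fiber is a polyline with a per-point radius. A `FiberNetwork` is the graph
obtained by single-linkage merging of all polyline points within a tolerance
(default 0.5 um) into shared nodes; consecutive points become 2-node
segments. Choices:

- **Clusters** are connected components of the node graph, counted at the
  fiber level via breadth-first search. Two fibers belong to one cluster iff
  they are connected through shared nodes.
- **Vertical fibers** are those whose end-to-end chord makes an angle
  strictly below 45 degrees with the Y axis. Using the chord (not per-segment
  tangents) makes the classification insensitive to waviness.
- **Volume fraction** sums per-segment cylinder volumes over the domain
  volume. Overlap at junctions is not de-duplicated; at the volume fractions
  of interest (2–5%) the induced bias is small compared with the
  segmentation uncertainty.
- **Mean fiber diameter** is the mean over fibers of each fiber's mean
  diameter (not the segment-length-weighted mean), matching how per-fiber
  measurements are typically tabulated.

## 3. Synthetic network generator

Fibers are sampled as wavy polylines: a start point, a direction from a
two-component polar mixture (a cos-uniform polar cap below 45 degrees for the
vertical component, the 45–90 degree band otherwise, so the classified
vertical proportion matches the target in expectation), a truncated-normal
length and diameter, and smooth perpendicular perturbations scaled by
`waviness`. Polylines are clipped to the domain box about an interior anchor
point. With `attach_fraction > 0`, that fraction of fibers starts at the
existing network vertex nearest a uniformly sampled target, producing
connected growth; the presets use `attach_fraction = 1` to grow a single
connected tree and then sever it.

**Fragmentation** (`fragment_network`) removes a gap-length interior piece of
a randomly chosen fiber, splitting it in two. This models enzymatic
degradation: material volume strictly decreases, the cluster count never
decreases. The preset builder accepts only severings that raise the cluster
count by exactly one, so cluster targets are met exactly.

**Presets**: each donor-age preset fixes fiber count and cluster count
exactly by construction, matches the mean diameter exactly via a uniform
radius shift, and calibrates the mean fiber length (damped fixed-point
iteration, same seed per iterate) until the volume fraction is within 8% of
target. Vertical proportion is matched in expectation. Firmness is *never* a
preset input; it is an output of the simulation. `scale` shrinks the box
linearly and the fiber/break counts by `scale^3`, keeping individual fiber
sizes and number density realistic while making fast study variants.

Realism limits: fibers are independent apart from attachment growth (no
exclusion volume, no bundling), diameters are constant along a fiber at
generation, and the domain is a homogeneous box (no papillary/reticular
layering). These do not affect the architecture descriptors the study
manipulates.

## 4. Imaging emulation and segmentation

`voxelize_network` marks a voxel foreground when its center lies within the
local fiber radius of any centerline segment (so fibers get hemispherical end
caps), assigns fiber/background intensity levels, then applies Gaussian blur
(in voxels) and seeded additive Gaussian noise — a minimal confocal forward
model.

`segment_stack` runs: 3D median filter → single-threshold segmentation
(Otsu by default, standing in for an interactive per-stack choice) →
morphological opening and closing with a spherical structuring element →
binary surface smoothing → centerline extraction → local diameter
estimation.

### Centerline extraction

The mask is skeletonized and the skeleton voxel graph is traced into fiber
polylines. Details that matter:

- **Upsampled skeletonization.** The 3D thinning implementation used by
  `skimage.morphology.skeletonize` can annihilate tube cross-sections with
  even voxel extents (no unique central voxel). The mask is therefore
  upsampled 2x with a one-sided shift-OR growth, which makes every local
  extent odd; skeleton voxel indices map back to physical coordinates as
  `phys = idx * (spacing / 2) + origin`, which cancels the half-fine-voxel
  shift exactly.
- **Graph cleaning.** 26-connectivity triangle chords are removed (longest
  edge first, only while it still closes a surviving triangle); short
  dead-end spurs (below `min_branch_length`) are pruned on the graph.
- **Junction clustering.** Adjacent junction voxels (degree >= 3) collapse
  into one junction node represented by the member voxel nearest their
  centroid (guaranteed to stay inside the mask).
- **Straightest-continuation pairing.** At each junction, incident branch
  tangents are estimated over a 2 um arc after skipping one local radius from
  the junction (so the tangent is not polluted by junction blobbing). Branch
  pairs continuing within `junction_max_turn_deg` (default 60 degrees) of a
  straight line are merged, most collinear first. This traces a fiber
  *through* a crossing instead of cutting it into four stubs.
- **Artifact filters**, all with radius-adaptive thresholds derived from the
  Euclidean distance transform (EDT): dead-end stubs shorter than 1.5x the
  local radius are dropped before pairing (skeleton twigs from end-cap
  forking); unpaired junction-to-junction "rungs" not longer than the sum of
  the two endpoint radii are dropped after pairing (webs at grazing fiber
  contacts); and duplicate parallel rails — traced fibers with >= 80% of
  their points within the local radius of a longer fiber — are removed last.
- **Smoothing and resampling.** Each traced polyline is Laplacian-smoothed
  and resampled at 1 um arc-length steps. The resampling step is chosen above
  the network-building merge tolerance (0.5 um) so that a traced fiber's own
  points never collapse into a single node.

### Local diameter estimation

Inside an ideal tube the EDT is a cone peaking on the axis:
`EDT(v) = r - d(v, axis)`. Interpolating the EDT at a centerline point clips
this cone tip and reads up to half a voxel low. The estimator instead takes
the median over the foreground corners of the enclosing voxel cell of
`EDT(corner) + d(corner, tangent line)`, which is exact on the continuous
tube model. Near fiber tips the nearest surface is the end cap, not the
lateral wall, so points whose arc distance to an end is below their local
radius inherit the nearest interior estimate. A floor of a quarter voxel
keeps radii positive.

## 5. Mechanics

### Model

The dermal matrix is a Saint Venant–Kirchhoff (SVK) hyperelastic continuum,
E = 0.08 MPa, nu = 0.48 (near-incompressible soft tissue), meshed with
linear tetrahedra (each structured hex cell split into 6 consistently
oriented tets). Elastin fibers are linear-elastic circular beams
(E = 0.5 MPa) with geometrically nonlinear (co-rotational, rotation-vector)
kinematics: axial, two bending, and torsional modes.

**Embedding**: each network node snaps to the nearest matrix mesh node;
segment endpoints share the matrix translational DOFs while rotations belong
to the beams alone. Zero-length beams (both ends snapping to one node) are
dropped and reported. This is a discrete embedded-fiber approach: no
conforming meshing around fibers, which keeps arbitrary networks tractable,
at the cost of a snap error bounded by half a cell diagonal.

**Boundary conditions** model a compression platen test: the bottom face is
fixed in Y, the top face is displaced downward by `compression_ratio x
height`, both platen faces are laterally constrained (no slip), and the four
lateral faces are traction-free but kept planar via master-slave ties (each
face moves rigidly in its normal direction). The planarity ties make the
fiber-free problem homogeneous, which gives a closed-form verification
solution on any mesh.

### Solution

Incremental Newton iteration on the reduced system (fixed/prescribed/tied
DOFs eliminated), sparse Cholesky-like direct solves via SciPy, adaptive
increment bisection on non-convergence (minimum step 1/64 of the base
increment, regrowth x1.5 after success). Internal forces are exact energy
gradients; the tangent is Gauss-Newton plus geometric terms for beams and
exact for SVK tets.

**Rotational regularization.** A straight embedded fiber has an exact zero-
energy mode: spin about its own axis (translations are pinned to the matrix;
twist is ungrounded). Grounded rotational springs with stiffness
`1e-6 x median(E_fiber I / L)` on all beam rotational DOFs remove the
singularity. They are applied consistently in both the force and the
tangent, so they perturb the converged solution only at the 1e-6 relative
level, far below all verification tolerances.

**Outputs**: top/bottom platen reaction forces (they balance to round-off),
nominal top traction, per-beam signed axial forces (tension positive), and
the per-element von Mises equivalent strain of the Green–Lagrange tensor.
Matrix elements with equivalent strain below 0.1 at 20% compression are
classified "low-strain" — the stress-shielding signature of a load-bearing
fiber cluster.

### Verification

- Fiber-free 20% compression matches the closed-form homogeneous SVK
  solution (lateral stretch 1.08296, nominal traction -0.01152 MPa, uniform
  equivalent strain 0.1776) to < 0.1% on every mesh, because the exact
  solution is linear in the reference coordinates.
- Beam and tet internal forces match central finite differences of their
  element energies to <= 1e-6 relative.
- A rigidly rotated beam produces zero force (objectivity).
- An 8-element cantilever tip deflection matches P L^3 / (3 E I) to < 0.1%.

### Limitations

There is no arc-length continuation: long, stiff, near-vertical fibers
pinned near both platens can reach a buckling limit point before 20%
compression, in which case the solver reports non-convergence honestly
rather than returning a wrong equilibrium. Matrix self-contact and fiber
plasticity/damage are out of scope; 20% compression of a matrix at these
stiffnesses stays well inside the SVK model's useful range.

## 6. Statistics

All standard deviations are sample (n-1) estimates. Group comparison between
younger (age <= 49, n = 4) and older (age >= 58, n = 5) donors uses Welch's
unequal-variance t-test; correlation p-values use the exact t-distribution
transform of Pearson's r; regressions are ordinary least squares and are
reported both raw and with min-max-normalized predictors (the basis of
published standardized slopes is otherwise ambiguous). Under the null, the
Welch test's 5% rejection rate calibrates to 5% +- 1% over 10,000 replicates
(verified in the test suite). Skin firmness is min-max normalized across the
cohort.

## 7. Reproducibility

Every random draw flows from explicit integer seeds in [0, 2^31). The
pipeline derives per-sample seeds as `(seed + 13 * age) mod 2^31` and the
voxelization seed as that plus one, so adding or removing samples never
shifts the randomness of the others. Each study writes per-stage artifacts,
a `report.json`, a log, and a `manifest.json` with package/NumPy versions,
all seeds, and SHA-256 checksums of every artifact. Rerunning a study with
the same configuration reproduces every checksum.
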