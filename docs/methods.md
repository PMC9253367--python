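# Methods

## Geometric model

The myocardial wall of the looping heart tube is modelled as a bilayer
surface pair: an outer (epicardial) and an inner (endocardial) node layer,
each carrying a bicubic Hermite patchwork on a cylinder topology, blended
linearly through the wall. Local coordinates follow the tube: ξ₁ runs
circumferentially, ξ₂ longitudinally, ξ₃ transmurally. Each node stores four
parameter vectors — position, ∂u/∂s₁, ∂u/∂s₂ and ∂²u/∂s₁∂s₂ — with
derivatives taken with respect to arc length. A per-node, per-direction scale
factor S (the local ds/dξ) converts them to the ξ-derivatives of the
tensor-product interpolation. Because the scale factors are nodal (shared by
every element meeting at a node), position and arc-length first derivatives
are continuous across element boundaries; cross-derivatives involving ξ₃ are
identically zero for the bicubic-linear basis and are not stored.

**Scale-factor iteration.** Arc lengths depend on scale factors and vice
versa, so both are solved by fixed-point iteration: first-derivative vectors
are normalized to unit length, each edge's arc length is computed by 16-point
Gauss-Legendre quadrature of ∫‖∂u/∂ξ‖dξ, nodal factors are set to the mean
adjacent edge length per direction, and the cycle repeats until the largest
relative change falls below 1e-9 (at most 50 iterations; failure raises with
the residual). The tight tolerance matters: at a 1e-6 tolerance the ~200 μm
scale factors still drift by ~2×10⁻⁴ μm per reconvergence, visible as ~1e-6 μm
of noise in self-fit residuals.

A consequence of the unit-arc-length-derivative convention worth knowing: a
four-node Hermite ring constrained to tangent magnitude = arc length
represents a circle with ~0.5% radial ripple, so the irreducible fit RMS of a
150 μm tube is about 1 μm. That is the honest noise floor of the coarse
mesh, well inside the sub-3 μm accuracy the fitting stage targets.

## Surface fitting

Fitting is linear least squares in the outer-layer nodal parameters with the
projections and scale factors frozen, iterated to self-consistency:

1. project every data point onto the current outer surface (see below);
2. assemble the normal equations of the weighted data term plus the Sobolev
   penalty ∫ α(‖u_ξ₁‖²+‖u_ξ₂‖²) + β(‖u_ξ₁ξ₁‖²+‖u_ξ₂ξ₂‖²+2‖u_ξ₁ξ₂‖²) dξ
   (4×4 Gauss points per element); the same matrix serves all three
   coordinates;
3. solve with symmetric Jacobi equilibration and a relative Tikhonov jitter
   of 1e-10 (positions and derivative parameters live on very different
   scales);
4. re-place the inner layer at the template's per-node wall thickness along
   the inward surface normal, reconverge scale factors, and re-project.

Iterations stop when the RMS projection distance changes by less than
`rms_tol` (default 1e-3 μm) or after `max_iters`. Landmark nodes are hard
constraints: their position parameters are eliminated from the system (their
derivatives stay free). Defaults α = 1e-3, β = 1e-4 were chosen as the
weakest smoothing that keeps the end rings stable under 0.5 μm cloud noise;
both are configuration parameters.

**Projection.** Each element face is sampled on a 9×9 ξ grid; a KD-tree over
all samples returns, per data point, up to four candidate elements with the
nearest sample as the Newton seed, and a projected Gauss-Newton iteration
(steps clamped to the unit square, at most 30 iterations) refines each
candidate. The smallest distance wins; distances are quantized at 1 nm so
exact ties deterministically go to the lowest element id. Grid seeding was
preferred over blind multi-start Newton because the seeds are already within
one grid cell of the optimum, which both accelerates and robustifies the
search.

**Template placement.** The initial template is a constant-radius tube swept
along the circular arc through three centerline landmarks (the
cranial/caudal attachment points and one interior point); the radius is
estimated as the median point-to-centerline distance. A fourth, surface
landmark anchors the circumferential origin so that ξ₁ = 0 marks the same
material line at every time point — without it the azimuth convention of the
arc construction is arbitrary and material correspondence between time
points (hence the deformation analysis) silently breaks by a constant
rotation.

## Cell morphometry

Connected components (26-connectivity) are split by watershed on the
Euclidean distance transform, seeded at local maxima of the Gaussian-smoothed
(σ = 1 voxel) distance map; the moderate smoothing and a 3-voxel minimum peak
separation avoid over-separation of single cells. Per-cell features come
from the population covariance of the voxel world coordinates with the cube
second moment (voxel_size²/12 per axis) added to the diagonal: voxels are
extended cubes, not points, and without that term flat or linear voxel sets
report a zero smallest eigenvalue and an anisotropy of exactly 1, outside
the meaningful [0, 1) range. Eigenvalues are reported as standard deviations
in μm (descending); anisotropy is 1 − λ₃²/λ₁² on the covariance
(squared-length) scale, which maps a 4:1 ellipsoid to 0.9375 and reproduces
the 0.5–0.95 range typical of elongated myocardial cells. Single-voxel cells
report zero eigenvalues and zero anisotropy by convention. Eigenvector signs
are fixed to the first positive component in z, then y, then x order.

## Mapping and fields

Cell centroids are projected to the outer surface only: the wall is two cell
layers thick, so transmural position carries no useful spatial signal. Bins
are ξ-uniform (5×5 per element, each spanning 0.2 in ξ₁ and ξ₂); they differ
in physical size, which downstream density measures normalize away. A
projection that clamps at an open tube end with a residual along the
longitudinal tangent is not a normal projection; such cells are flagged
unassigned and excluded. Bin tissue volume is attributed by projecting the
myocardium mask voxels the same way (optionally on a subsampled lattice,
counts rescaled by step³). Feature fields are fitted on the 2×2-refined mesh
with the identical normal-equation machinery, unknowns being nodal field
parameters (value, two arc-length derivatives, mixed derivative per
component); vector features share the system matrix and are solved
componentwise.

Neighbor variance is the population variance (divide by n = 10) over each
cell and its nine nearest neighbors by centroid distance, following the
"variance = sd²" convention; its units are the squared feature units.

## Kinematics

Material correspondence between time-point meshes is by shared
(element, ξ) — meshes are constructed with identical topology and numbering,
so no point matching is performed. F is evaluated at each 5×5 bin center at
mid-wall (ξ₃ = 0.5) from the two meshes' 3×3 ξ-Jacobians,
F = (∂x/∂ξ)(∂X/∂ξ)⁻¹; the reference bin volume is |det ∂X/∂ξ|/25. The SVD
decomposition makes U and V proper rotations (for det F > 0 both determinant
signs flip together, leaving singular values positive), stretches are the
descending singular values and the polar rotation is R = UVᵀ. Bins with a
singular reference Jacobian or non-positive J are flagged degenerate and
carry no decomposition. No attempt is made to separate growth from elastic
deformation — the two are not distinguishable from geometry alone — and
twist about the tube axis is unobservable from a circularly symmetric
surface, so twist-induced shear is invisible to the fitted-mesh pipeline
(volume measures such as J are unaffected).

Cell-axis rotations treat eigenvectors as axial (sign-free): the later
vector is flipped into the hemisphere of the earlier one before the
axis-angle construction, so rotation angles never exceed π/2. The rotation
matrix is the standard Rodrigues form
R = cosθ·I + sinθ·[a]× + (1−cosθ)·aaᵀ, verified by the property that R maps
the earlier direction onto the later one. Cell-tissue alignment is the
absolute cosine between corresponding columns of the cell and tissue
rotation matrices.

## Statistics

Templeton's two-step transformation uses fractional ranks p = rank/(n+1)
(mean rank for ties) followed by the inverse standard normal; dividing by
n+1 rather than n avoids infinite endpoints. The output is standardized
N(0,1) with no back-matching of the original moments, is invariant under any
strictly monotone input transform, and maps an all-constant input to zeros.
Regional contrasts are two-sided Mann-Whitney U tests (normal approximation
with tie correction, as implemented in scipy) with Bonferroni adjustment
p_adj = min(1, m·p) over the m pairwise comparisons and significance stars
at 0.05/0.01/0.001. The growth model is a Gaussian identity-link linear
model built by step-up selection: starting from the intercept, the candidate
whose addition lowers AIC the most is accepted, stopping when no candidate
lowers it; factors are dummy-coded, the Time×Region interaction becomes
admissible only when both main effects are in, the collinear pair
(ΔN_cell, Δρ_cell) never co-occurs, and rank-deficient candidate designs are
skipped with a note. The default region factor is the four-region
segmentation (OFT, dorsal, ventral, lateral).

## Tiling

Slicing crops the volume at the trailing end of each axis (origin-anchored)
to the largest length with (length − window) a multiple of stride, then
walks the stride lattice in axis order; overlap per axis is window − stride
(50 voxels for the standard 128/78 setting). Merging reconstructs the
cropped volume exactly; overlaps resolve last-writer-wins in lattice order,
with a logical-OR mode for binary prediction maps. The Dice coefficient is
2|A∩B|/(|A|+|B|) on binarized masks with the both-empty case defined as 1;
the multi-class soft Dice loss averages per-class soft overlaps of the raw
prediction scores and negates the result (a perfect prediction scores −1).

## Phantom generator

The phantom emulates the study conditions of a looping chick heart tube:
outer radius 150 μm, wall 25 μm, centerline length 1 mm, four pseudo-time
points with bends 0/30/60/90°, twists 0/10/20/30°, global growth
1.00/1.05/1.10/1.15, ~2000 ellipsoidal myocardial cells with lognormal
volumes (median 80 μm³, σ_log 0.8, clipped to 10–700 μm³), anisotropy
uniform in 0.5–0.95, a multiplicative volume gradient toward the outer
curvature, and 0.24 μm isotropic voxels. Material coordinates (θ, s, ρ) are
mapped per time point by an analytic bend-twist-growth map, so deformation
gradients, Jacobians, landmarks and per-cell ground truths are exact (map
Jacobians are evaluated by central differences). Surface clouds are sampled
uniformly in area by rejection against the numeric area element and
perturbed with isotropic Gaussian noise (default σ = 0.5 μm). Cells are
packed greedily with a non-overlap rejection rule; axes follow the local
tissue frame (long axis circumferential, short axis radial) and co-rotate
with the map.

A full-tube voxel grid at 0.24 μm would be ~4000³ voxels, so labeled
volumes are rasterized on demand for a requested bounding box — exactly how
such volumes are handled in practice, one tile at a time — and the
`PhantomSpec.desk()` preset (radius 18 μm, length 90 μm, ~260 cells, 0.5 μm
voxels) provides a whole-tube rasterizable phantom for the voxel-level
stages. Tests and the demonstration pipeline run at these reduced sizes; the
geometry-level stages (clouds, meshes, deformation) always run at the
full study scale.

**What the phantom does not emulate:** microscopy point-spread blur, channel
crosstalk, segmentation errors (cells are perfect ellipsoids with exact
labels), non-circular cross-sections, the dorsal mesocardium opening, and
biological variation between subjects. Passing the recovery tests therefore
demonstrates correctness of the numerics and bookkeeping, not robustness to
real imaging artifacts.

## Numerical choices and degenerate inputs

- Quadrature: 16-point Gauss-Legendre for arc lengths, 4×4 for Sobolev and
  volume integrals.
- Projection ties are broken toward the lowest element id after quantizing
  distances at 1 nm.
- Degenerate edges (coincident nodes, zero derivatives) have zero arc
  length; scale factors are floored at 1e-12.
- The two-landmark rigid alignment fixes the free roll by the minimal
  rotation between segment directions; three or more landmarks use the
  Kabsch SVD with a determinant sign fix (reflections never enter).
- Mesh JSON is written with 9-significant-digit quantization and fixed key
  order, making write → read → write byte-identical.

## Known limitations

- The fit accuracy floor (~1 μm on a 150 μm tube) is set by the coarse
  4-node circumferential ring under the arc-length derivative convention;
  refining the template raises accuracy at the cost of smoothing stability.
- Volume change attribution assumes the wall thickness used to place the
  inner layer; thickness errors bias J through the transmural term.
- Bin-level deformation is mid-wall only (no ξ₃ resolution), matching the
  two-cell-layer wall it describes.
- The step-up GLM reports associations; nothing in the pipeline supports
  causal claims about what drives tissue growth.
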