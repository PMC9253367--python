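# loopkin

Multi-scale kinematic analysis of early heart-tube looping (C-looping), for
developmental biologists and biomechanics groups who want to connect cellular
growth features to tissue-level deformation in tubular organs.

During C-looping the straight embryonic heart tube bends ventrally and
rotates rightward. `loopkin` re-implements the computational chain needed to
quantify that process from 3D imaging:

1. **Geometry** — the myocardial wall is represented by a coarse
   bicubic-linear finite-element tube mesh (cubic Hermite in the
   circumferential ξ₁ and longitudinal ξ₂ directions, linear through the wall
   ξ₃; 56 nodes, 24 elements by default). Nodal derivatives are stored with
   respect to arc length and converted with nodal scale factors
   `∂u/∂ξ = (∂u/∂s)·S`, which keeps the surface C¹ across elements.
2. **Fitting** — surface point clouds are projected onto the mesh and the
   nodal parameters solve the Sobolev-regularized least-squares problem
   `F(u) = Σ_d γ_d ‖u(ξ_d) − z_d‖² + ∫ α(‖u_ξ₁‖² + ‖u_ξ₂‖²) +
   β(‖u_ξ₁ξ₁‖² + ‖u_ξ₂ξ₂‖² + 2‖u_ξ₁ξ₂‖²) dξ`,
   iterating projection → linear solve → scale-factor update until the RMS
   projection distance `√(Σ d²/N)` stabilizes.
3. **Cell morphometry** — labeled cell volumes yield per-cell centroid,
   volume, covariance eigen-system (principal axis lengths in μm) and shape
   anisotropy `A = 1 − λ₃²/λ₁²`; touching cells are split by watershed on the
   distance transform.
4. **Mapping** — cells are projected onto the fitted surface and aggregated
   in 5×5 ξ-aligned bins per element (cell count, mean volume, tissue volume,
   inter-cellular space `V_ICS = V_tissue − ΣV_cell`, density, orientation);
   smooth feature fields are fitted on a 2×2-refined mesh; local
   heterogeneity is the variance of a feature over each cell and its nine
   nearest neighbors.
5. **Kinematics** — between consecutive time-point meshes the deformation
   gradient `F = (∂x/∂ξ)(∂X/∂ξ)⁻¹` is evaluated at every bin center;
   `J = det F` gives the local volume ratio and `ΔV = dV(J − 1)` the bin
   volume change; the sign-corrected SVD `F = UΣVᵀ` separates principal
   stretches from the tissue rotation `R = UVᵀ`. Cell-axis rotations use the
   axis-angle (Rodrigues) construction and are compared with tissue rotations
   through `|cos θ|` of corresponding rotation-matrix columns.
6. **Statistics** — per-bin changes are normalized with Templeton's two-step
   (rank → inverse-normal) transformation, regions are compared with
   Mann-Whitney U tests under Bonferroni correction, and
   `ΔV_tissue ~ Time + Region + ΔN_cell + ΔV_cell + ΔA_cell + ΔV_ICS (+ Time×Region)`
   is built by step-up AIC selection.
7. **Tiling** — large stacks are sliced into overlapping windows on a stride
   lattice (overlap = window − stride), merged back losslessly, masked to the
   myocardium, and segmentations are scored with the Dice coefficient and the
   multi-class soft Dice loss.

Everything is testable without any imaging data: the `phantoms` module
generates bent-twisted-growing tube phantoms with packed ellipsoidal cells,
known feature gradients and an analytic deformation map, so every stage has a
ground truth.

## Worked example

```python
import numpy as np
from loopkin.phantoms import PhantomSpec, fit_time_point, sample_point_cloud
from loopkin.fitting import FitConfig
from loopkin.kinematics import deformation_gradient_field, records_to_frame

spec = PhantomSpec(seed=1)            # ~1 mm tube, 90-degree bend at stage 4
cloud = sample_point_cloud(spec, 3, n=5000, noise_sigma=0.5, seed=42)
res = fit_time_point(spec, 3, cloud=cloud, cfg=FitConfig(max_iters=8))
print(res.summary())

meshes = [fit_time_point(spec, t, cfg=FitConfig(max_iters=6)).mesh
          for t in (0, 1)]
df = records_to_frame(deformation_gradient_field(meshes[0], meshes[1]))
print(f"J over 600 bins: mean {df['J'].mean():.3f}, "
      f"min {df['J'].min():.3f}, max {df['J'].max():.3f}")
```

prints

```
Mesh fit result
  nodes: 56, elements: 24
  iterations: 5 (converged: True)
  initial RMS: 2.06157 um
  final RMS:   1.34345 um
J over 600 bins: mean 1.156, min 1.051, max 1.258
```

The final RMS of 1.34 μm means the fitted 56-node mesh tracks the noisy
(σ = 0.5 μm) phantom surface to about a micron — on a heart-sized tube this
is an accurate fit. The Jacobian field between the first two stages (5%
global growth plus the onset of bending) averages 1.156 ≈ 1.05³: local
tissue volume grew by ~16%, more on the outer curvature (max 1.26) than the
inner (min 1.05).

A command-line interface mirrors the library
(`loopkin simulate|fit-mesh|extract-cells|map-cells|variance|kinematics|glm|slice|merge|run`);
`loopkin run --out dir --seed 1` executes the whole phantom pipeline and
writes a manifest with content hashes.

## Documentation

`docs/methods.md` describes the model, its assumptions, the phantom
generator, numerical choices and known limitations.
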