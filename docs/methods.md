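# Methods

## Problem and model

`anricp` registers a deformable source point cloud onto a target recorded by
a time-of-flight (ToF) depth camera. The motivating application is tracking
the abdominal skin surface across breathing phases for image-guided
interventions: the surface changes from convex (exhale) to concave (inhale),
so a rigid alignment cannot follow it, and the camera's localization error
is strongly anisotropic — roughly σ_z = 10 mm along the viewing ray versus
σ_x = σ_y = 0.02 mm across it — so Euclidean nearest-neighbour matching is
dominated by range noise.

Every source vertex v_i = [x y z 1] carries its own 4×3 affine block X_i
(rows 1–3 linear part, row 4 translation); the blocks stack into the 4N×3
unknown X. Each iteration solves the sparse linear least-squares problem

```
E(X) = ‖ [ α(M⊗G) ]     [  0  ]
         [   W D   ] X − [ W U ] ‖²   ( + landmark rows [βD_L | U_L] )
```

where D holds the homogeneous source vertices block-diagonally, U the
matched target coordinates, W a diagonal per-vertex weight, M the node-arc
incidence matrix of the mesh (−1 at the arc start, +1 at the end; arcs run
start < end in row-major order) and G a 4×4 weighting of the transform
components (identity by default; `gamma` scales its fourth diagonal entry).
The stiffness rows penalize transform disagreement across mesh arcs; the
stacked form is taken literally, so α multiplies the rows and contributes
α² to the objective (the prose form of the stiffness cost writes α outside
the norm — the stacked system is what the normal equations minimize, and
with β = 1 the same question for the landmark rows is moot). The minimizer
is applied to the source, the correspondences and the source covariances are
recomputed from the moved points, and the loop repeats.

### Matching metric

Each point carries a covariance Σ = V S² Vᵀ with S = diag(σ_x, σ_y, σ_z)
and V the principal-axis frame. Candidate pairs are ranked by

```
d(x, y) = ‖W_xy (x − y)‖,   W_xy = w (Σ_x + Σ_y)^(−1/2),
```

the Mahalanobis-type distance of the pair's summed covariances; w is a free
normalization (default 1 — it cannot change an arg-min). The production
backend evaluates d² through the closed-form 3×3 adjugate of the symmetric
cross-covariance, which is pure elementwise numpy over source×target blocks
and agrees with the literal inverse-square-root path to better than 1e−8
(tested). Ties break to the lowest target index. The per-iteration
covariance update recomputes V from the moved point positions; the literal
rotation propagation Σᵏ = R Σᵏ⁻¹ Rᵀ is kept as `propagate_by_rotation` for
callers that do have a rigid rotation estimate, since the non-rigid solve
yields no single R.

### Frame conventions for the noise model

Two readings of "the error's z axis" are supported (`NoiseModel.frame`):

* `per_point_ray` (default): V's third column is the unit ray from the
  camera origin to each point — the physically faithful ToF model.
* `camera_axis`: the camera's optical axis for every point — the
  surface-level description, exact for a fronto-parallel surface.

For clouds a few millimetres apart (the clinical situation) the two
conventions give identical assignments. They differ sharply in one synthetic
situation: matching two flat meshes 100 mm apart along z. There the
per-point rays fan out by the projective factor 1200/1100, so the
ray-perpendicular metric maps the source grid onto a laterally expanded
image of the target grid; the mesh rim double-assigns and about 29% of
targets lose their unique correspondent no matter how the registration
proceeds. The artificial-protocol results this package reproduces (uniformly
single correspondences under anisotropic matching of the noisy flat pair)
are attainable only under the camera-axis convention, so the flat-pair
experiment in the acceptance checks uses `frame="camera_axis"`; the
per-point-ray default is asserted separately for the directional claim
(anisotropic strictly better than isotropic), which holds under both.

### Variants

* `isotropic` — Euclidean matching; optional separate landmark term
  β‖D_L X − U_L‖² over registration-landmark pairs.
* `anisotropic` — covariance-weighted matching, same cost stack.
* `anisotropic_landmark` — no separate landmark term: registration
  landmarks are excluded from the search, their U rows are pinned to the
  target landmark coordinates in every iteration, and W carries 4.0 on
  landmark vertices versus 0.25 elsewhere. The 16:1 weight ratio is what
  lets 9 landmarks outweigh ~600 free vertices in the data term.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| α (`alpha_start`) | 100 | stiffness; halved (`alpha_decay` 0.5) every `alpha_period` = 20 iterations |
| β (`beta`) | 1 | separate landmark-term weight (variants A/B) |
| G (`gamma`) | identity (γ = 1) | per-component transform weighting |
| `max_iterations` | 100 | artificial protocol; clinical-like runs use 200 |
| `tol` | 1e−6 mm | stop when the mean per-vertex displacement falls below it |
| `connectivity` | 4 | grid arcs per vertex neighbourhood (4 or 8) |
| σ_x, σ_y, σ_z | 0.02, 0.02, 10 mm | ToF localization sigmas, shared by both clouds |
| `camera_origin` | (0, 0, 0) | rays emanate from here; clouds sit ~1.1–1.2 m along +z |
| landmark weights | 4.0 / 0.25 | registration-landmark vs free-vertex diagonal of W (variant C) |

## Numerical choices

* **Solve.** The stacked system is solved through its normal equations with
  a sparse LU factorization after symmetric diagonal equilibration, which
  keeps pivoting stable across the α² dynamic range (α = 1e6 is a supported
  operating point). If the factorization fails or the relative
  normal-equation residual exceeds 1e−8 — perfectly planar clouds make the
  data term rank-3 in the global-affine subspace, so AᵀA can be exactly
  singular — a ridge εI is added on the equilibrated system, escalating
  ε ∈ {1e−12, 1e−10, 1e−8, 1e−6} until the solve is usable, with a logged
  warning. The ladder starts below the conventional 1e−10·(mean diagonal)
  because at α = 1e6 the larger ridge already biases recovered translations
  by ~1e−2 mm, an order of magnitude above the accuracy this package
  promises for rigid-translation recovery.
* **Solve frame.** The coordinates entering the linear system are centred on
  the source centroid each iteration (`center_coordinates`, default on).
  In raw camera-frame coordinates the homogeneous vertices are dominated by
  the ~1.1 m standoff, so a linear-part difference of 0.01 between
  neighbouring transforms moves a point ~11 mm at negligible stiffness cost:
  α stops acting as a rigidity knob, and landmark weighting cannot drag the
  mesh. Centring restores the coupling (early iterations are near-affine,
  as the annealing intends) while leaving the matching metric — always
  evaluated in camera frame — and the fixed points of the iteration
  unchanged; reported transforms are conjugated back to camera frame. With
  centring, the annealed schedule shows both behaviours the artificial
  protocol exhibits: rigid early dragging by weighted landmarks, and exact
  late collapse onto assigned targets (final assigned-pair distances reach
  the 1e−7…1e−11 mm round-off floor).
* **Inverse square root.** `weight_matrix` floors covariance eigenvalues at
  1e−12 before inverting, so degenerate inputs stay usable.
* **Ties and determinism.** Lowest-index tie-breaks in matching; grid points
  ordered row-major; generators are pure functions of (spec, seed); the
  brute-force matching backend is the default, with a kd-tree backend for
  Euclidean matching tested assignment-identical on generic inputs.
* **Degenerate inputs.** A point at the camera origin has no ray frame and
  raises; empty target clouds, mismatched shapes and invalid variants raise
  typed errors (`InvalidInputError`, `ConfigError`,
  `DegenerateGeometryError`); a non-finite cost aborts with the diagnostic
  trace attached (`DivergenceError`).

## Quality measures

* **M1** (mm): mean Euclidean distance from each deformed source point to
  its closest target, recomputed with plain Euclidean neighbours whatever
  metric the registration used; the companion `m1_assigned_mm` reads the
  registration's own assigned pairs instead.
* **M2** (grid units): for each held-out evaluation landmark, the Manhattan
  distance |Δrow| + |Δcol| between the grid position of the target nearest
  its deformed location and that of its true correspondent, averaged —
  "sum of columns and rows of misalignment" read as a per-case mean.
* **M3** (%): share of target points with exactly one source correspondent
  in the final assignment.
* Correspondence maps/histograms count correspondents per target (0
  allowed); distance histograms use 1-mm left-closed bins, bin 0 meaning
  "closer than 1 mm"; map values conserve the source count, histogram mass
  the target count (both tested).

## Synthetic fixtures

The generators replace clinical recordings that are not distributable:

* **flat_pair** — two 25×25 meshes, x, y ∈ [−125, 125] mm, z = 1100 mm
  (source) and 1200 mm (target), with ToF noise drawn independently for both
  clouds in each point's principal-axis frame (enabled by default for this
  kind only). This is the matching-quality demonstration geometry.
* **step_pair** — the noiseless flat pair with the source drawn away by
  (dx, 0, dz) = (50, 20) mm so the surfaces overlap partially; 9
  registration landmarks on a 3×3 interior subgrid plus 16 evaluation
  landmarks on a disjoint 4×4 subgrid (the evaluation set is this package's
  addition so the landmark error is measurable on held-out points). The
  printed description of the original step experiment under-determines its
  offsets; these defaults reproduce its qualitative regime (a band of
  starved targets and a multiply-assigned rim under uniform weighting) and
  are flagged as an interpretation.
* **breathing_pair** — one base plane at z = 1150 mm bent by ±A·exp(−r²/2s²)
  (A = 20 mm, s = 60 mm): source convex, target concave, central point
  moving 2A between phases and a mean initial separation of ~7 mm, the
  scale of the clinical inhale/exhale pairs. A 3×3 grid of 15 mm square
  markers (centres at ±75 mm pitch) contributes 4 corners each, snapped to
  grid points: 36 landmarks, the first corner of each marker flagged for
  registration (9) and the rest held out (27).

What the generators do **not** emulate: camera amplitude images, wiggling
and multipath artefacts, marker detection (corner indices are exact by
construction), surface folding, and the irregular sampling of real depth
maps. Passing tests therefore demonstrate the algorithmic claims —
covariance-weighted matching recovers lateral structure under ray noise,
landmark weighting propagates through the mesh, the solver is exact at its
fixed points — not clinical accuracy.

## Problem sizes and runtime

All end-to-end checks run at the study scale of 625 points per cloud
(25×25, 1200 arcs). The flat-pair experiment uses 10 independent noise
draws in the test suite and 3 in the acceptance script; a full 100-iteration
registration of a 625-point pair takes roughly 0.5–2 s on one core.

## Known limitations

* Correspondence search is one-way (source → target) and brute-force
  O(N_s·N_t) per iteration; fine to a few thousand points, not for raw
  depth maps.
* The landmark-variant weights (4/0.25) are fixed constants of the method;
  no data-driven weighting is attempted.
* M2 requires the target to be a regular grid; for non-grid targets only
  M1/M3 and the histograms are available.
* The per-point-ray metric is asymmetric in a geometric sense: matching
  across large depth gaps acquires a projective distortion (see frame
  conventions above). This is a property of the model, not a bug, but users
  registering surfaces far apart in depth should prefer `camera_axis` or
  expect rim effects.
* Clinical ToF recordings are out of scope; nothing here validates against
  real patient data.
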