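"""Non-rigid ICP: cost assembly, sparse solve, and the iteration loop.

Every iteration stacks one sparse linear least-squares problem

    ‖ [ α(M⊗G) ]       [  0  ]
      [  W D    ]  X −  [ W U ] ‖²   (+ optional landmark rows [βD_L | U_L])

over the 4N×3 per-vertex transform stack X:  D holds the homogeneous source
vertices block-diagonally, U the assigned target coordinates, W a diagonal
per-vertex weight, M the node-arc incidence matrix of the mesh and G a 4×4
weighting of the transform components.  The stiffness rows penalize transform
disagreement across mesh arcs; α anneals on a fixed schedule (halved every
20 iterations by default) so the deformation is near-affine early and
increasingly local later.

Three variants are supported:

* ``isotropic`` — Euclidean matching, optional separate landmark term (β).
* ``anisotropic`` — ToF-covariance-weighted matching, same cost stack.
* ``anisotropic_landmark`` — no separate landmark term; registration
  landmarks are pinned inside the distance term (their U rows hold the target
  landmark coordinates every iteration) and the weight matrix carries 4.0 on
  landmark vertices versus 0.25 elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from . import metrics as _metrics
from .aniso import Correspondences, NoiseModel, covariance_field, find_correspondences
from .core import (
    ConfigError,
    DivergenceError,
    GridTopology,
    InvalidInputError,
    LandmarkSet,
    PointCloud,
    TransformStack,
    apply_transform_stack,
    build_grid_topology,
    make_homogeneous,
)

logger = logging.getLogger("anricp")

VARIANTS = ("isotropic", "anisotropic", "anisotropic_landmark")

LANDMARK_WEIGHT = 4.0
NON_LANDMARK_WEIGHT = 0.25


def landmark_weights(n: int, registration_indices) -> np.ndarray:
    """Per-vertex weights with 4.0 on registration-landmark vertices, 0.25 elsewhere."""
    w = np.full(n, NON_LANDMARK_WEIGHT)
    w[np.asarray(registration_indices, dtype=np.int64)] = LANDMARK_WEIGHT
    return w


@dataclass
class RegistrationConfig:
    """Knobs of the iteration loop; defaults follow the artificial-data protocol.

    alpha_start=100 halved every alpha_period=20 iterations, β=1, G=identity
    (``gamma`` scales its 4th diagonal entry, weighting the translation row),
    100 iterations, and a mean per-vertex displacement stop of 1e-6 mm.

    ``center_coordinates`` (default on) subtracts the source centroid from
    the coordinates fed into the linear system each iteration.  In raw
    camera-frame coordinates the homogeneous vertices are dominated by the
    ~1 m standoff along z, so tiny differences in the linear part of
    neighbouring transforms produce centimetre displacements at negligible
    stiffness cost and α loses its meaning as a rigidity knob; centering
    restores the intended coupling while leaving the model, the matching
    metric (always evaluated in camera frame) and the fixed points of the
    iteration unchanged.
    """

    variant: str = "anisotropic"
    alpha_start: float = 100.0
    alpha_decay: float = 0.5
    alpha_period: int = 20
    beta: float = 1.0
    gamma: float = 1.0
    max_iterations: int = 100
    tol: float = 1e-6
    connectivity: int = 4
    normalization: float = 1.0
    center_coordinates: bool = True
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.alpha_start <= 0:
            raise ConfigError("alpha_start must be > 0")
        if self.max_iterations < 1:
            raise ConfigError("max_iterations must be >= 1")
        if self.tol < 0:
            raise ConfigError("tol must be >= 0")
        if self.alpha_period < 1:
            raise ConfigError("alpha_period must be >= 1")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")

    @property
    def G(self) -> np.ndarray:
        return np.diag([1.0, 1.0, 1.0, self.gamma])

    def alpha_at(self, iteration: int) -> float:
        return self.alpha_start * self.alpha_decay ** (iteration // self.alpha_period)


@dataclass
class RegistrationResult:
    """Deformed cloud, cumulative transforms, diagnostics, and final measures."""

    cloud: PointCloud
    transform: TransformStack
    trace: list[dict]
    correspondences: Correspondences
    m1_mm: float
    m1_assigned_mm: float
    m3_pct: float
    m2_units: float | None = None
    converged: bool = False

    @property
    def iterations(self) -> int:
        return len(self.trace)

    def quality_report(self, target: PointCloud, landmarks: LandmarkSet | None = None):
        return _metrics.build_quality_report(self.cloud, target, self.correspondences, landmarks)


def assemble_D(points) -> sparse.csr_matrix:
    """Block-diagonal N×4N matrix with row i = v_iᵀ = [x y z 1] in columns 4i..4i+3."""
    pts = points.points if isinstance(points, PointCloud) else np.asarray(points, dtype=np.float64)
    hom = make_homogeneous(pts)
    n = hom.shape[0]
    indptr = np.arange(0, 4 * n + 1, 4)
    indices = np.arange(4 * n)
    return sparse.csr_matrix((hom.ravel(), indices, indptr), shape=(n, 4 * n))


def assemble_DL(points, vertex_indices) -> sparse.csr_matrix:
    """L×4N landmark rows: row l holds v_{i_l}ᵀ in the columns of vertex i_l."""
    pts = points.points if isinstance(points, PointCloud) else np.asarray(points, dtype=np.float64)
    idx = np.asarray(vertex_indices, dtype=np.int64)
    hom = make_homogeneous(pts[idx])
    L = idx.size
    rows = np.repeat(np.arange(L), 4)
    cols = (4 * idx[:, None] + np.arange(4)[None, :]).ravel()
    return sparse.csr_matrix((hom.ravel(), (rows, cols)), shape=(L, 4 * pts.shape[0]))


def distance_cost(D: sparse.spmatrix, X, U: np.ndarray, weights=None) -> float:
    """E_d = ‖W(DX − U)‖² (squared Frobenius norm)."""
    Xs = X.stacked if isinstance(X, TransformStack) else np.asarray(X, dtype=np.float64)
    U = np.asarray(U, dtype=np.float64)
    res = D @ Xs - U
    if res.shape != U.shape:
        raise InvalidInputError("shape mismatch in distance cost")
    if weights is not None:
        res = np.asarray(weights, dtype=np.float64)[:, None] * res
    return float(np.sum(res**2))


def build_incidence(topology: GridTopology, n: int) -> sparse.csr_matrix:
    """E×N node-arc incidence matrix: −1 at the arc start, +1 at the arc end."""
    e = topology.edges
    if e.size and (e.min() < 0 or e.max() >= n):
        raise InvalidInputError("topology index out of range")
    ne = e.shape[0]
    rows = np.repeat(np.arange(ne), 2)
    cols = e.ravel()
    data = np.tile([-1.0, 1.0], ne)
    return sparse.csr_matrix((data, (rows, cols)), shape=(ne, n))


def stiffness_block(M: sparse.spmatrix, G: np.ndarray, alpha: float) -> sparse.csr_matrix:
    """α(M⊗G): 4E×4N stiffness rows of the stacked system."""
    G = np.asarray(G, dtype=np.float64)
    if G.shape != (4, 4):
        raise InvalidInputError("G must be 4×4")
    return (alpha * sparse.kron(M, G)).tocsr()


def landmark_block(DL: sparse.spmatrix | None, UL: np.ndarray | None, beta: float):
    """Landmark rows (βD_L, U_L) for the stacked system; empty set → no rows."""
    if DL is None or DL.shape[0] == 0 or beta == 0.0:
        return None, None
    return (beta * DL).tocsr(), np.asarray(UL, dtype=np.float64)


def assemble_system(
    variant: str,
    alpha: float,
    Mmat: sparse.spmatrix,
    G: np.ndarray,
    D: sparse.spmatrix,
    U: np.ndarray,
    weights: np.ndarray,
    DL: sparse.spmatrix | None = None,
    UL: np.ndarray | None = None,
    beta: float = 1.0,
):
    """Stack the variant's full sparse system (A, B).

    Variants "isotropic"/"anisotropic" stack [α(M⊗G); WD; βD_L] against
    [0; WU; U_L]; "anisotropic_landmark" stacks [α(M⊗G); WD] against [0; WU]
    with the landmark rows of U already pinned to the target landmark
    coordinates and the 4/0.25 weights inside W.
    """
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}")
    S = stiffness_block(Mmat, G, alpha)
    w = np.asarray(weights, dtype=np.float64)
    WD = sparse.diags(w) @ D
    WU = w[:, None] * np.asarray(U, dtype=np.float64)
    rows = [S, WD.tocsr()]
    rhs = [np.zeros((S.shape[0], 3)), WU]
    if variant == "anisotropic_landmark":
        if DL is None or DL.shape[0] == 0:
            raise ConfigError("anisotropic_landmark variant requires registration landmarks")
    else:
        BL, UL_rows = landmark_block(DL, UL, beta)
        if BL is not None:
            rows.append(BL)
            rhs.append(UL_rows)
    return sparse.vstack(rows).tocsr(), np.vstack(rhs)


# ridge ladder (× mean diagonal of AᵀA); includes the conventional 1e-10 level
_RIDGE_LADDER = (1e-12, 1e-10, 1e-8, 1e-6)
_RESIDUAL_TOL = 1e-8


def solve_step(A: sparse.spmatrix, B: np.ndarray) -> TransformStack:
    """Minimize ‖AX − B‖² for the stacked transform X.

    Solves the normal equations with a sparse LU factorization after symmetric
    diagonal equilibration (which keeps pivoting stable across the α² dynamic
    range).  If the factorization fails or the relative normal-equation
    residual exceeds 1e−8 — e.g. for rank-deficient AᵀA from perfectly planar
    clouds — a ridge εI is added, escalating ε until the solve is usable, with
    a logged warning.
    """
    B = np.asarray(B, dtype=np.float64)
    if A.shape[0] < A.shape[1]:
        raise InvalidInputError("stacked system must have at least 4N rows")
    if A.shape[0] != B.shape[0]:
        raise InvalidInputError("A and B row counts differ")
    AtA = (A.T @ A).tocsc()
    AtB = A.T @ B
    diag = AtA.diagonal()
    scale = np.sqrt(np.where(diag > 0, diag, 1.0))
    Dinv = sparse.diags(1.0 / scale)
    As = (Dinv @ AtA @ Dinv).tocsc()
    bs = AtB / scale[:, None]
    b_norm = max(np.linalg.norm(bs), 1e-300)

    def attempt(mat):
        try:
            y = splu(mat).solve(bs)
        except RuntimeError:
            return None, np.inf
        if not np.all(np.isfinite(y)):
            return None, np.inf
        rel = np.linalg.norm(As @ y - bs) / b_norm
        return y, rel

    y, rel = attempt(As)
    if y is None or rel > _RESIDUAL_TOL:
        mean_diag = float(diag.mean()) if diag.size else 1.0
        for level in _RIDGE_LADDER:
            eps = level  # equilibrated system has unit diagonal
            y2, rel2 = attempt((As + eps * sparse.identity(As.shape[0], format="csc")).tocsc())
            if y2 is not None and (y is None or rel2 < rel):
                y, rel = y2, rel2
            if y is not None and rel <= _RESIDUAL_TOL:
                logger.warning(
                    "solve_step: rank-deficient or ill-conditioned system; "
                    "ridge %.1e (×%.3e mean diagonal) applied", level, mean_diag
                )
                break
        else:
            logger.warning(
                "solve_step: residual %.2e above tolerance after ridge ladder", rel
            )
    if y is None:
        raise DivergenceError("normal-equation solve failed")
    X = y / scale[:, None]
    return TransformStack.from_stacked(X)


def register(
    source: PointCloud,
    target: PointCloud,
    landmarks: LandmarkSet | None = None,
    config: RegistrationConfig | None = None,
    topology: GridTopology | None = None,
) -> RegistrationResult:
    """Run the full non-rigid ICP loop and score the result.

    Each iteration matches correspondences under the variant's metric,
    assembles and solves the stacked system, applies the per-vertex
    transforms, and re-derives the source covariance field from the moved
    points (anisotropic variants).  Stops at ``max_iterations`` or when the
    mean per-vertex displacement drops below ``tol``.
    """
    config = config or RegistrationConfig()
    if topology is None:
        if source.grid_shape is None:
            raise ConfigError("source has no grid_shape; pass an explicit topology")
        topology = build_grid_topology(*source.grid_shape, config.connectivity)
    if landmarks is not None:
        landmarks.validate_against(source.n, target.n)
    reg_src, reg_tgt = (np.empty(0, np.int64), np.empty(0, np.int64))
    if landmarks is not None:
        reg_src, reg_tgt = landmarks.registration_pairs
    if config.variant == "anisotropic_landmark" and reg_src.size == 0:
        raise ConfigError("anisotropic_landmark variant requires registration landmarks")

    n = source.n
    mode = "isotropic" if config.variant == "isotropic" else "anisotropic"
    Minc = build_incidence(topology, n)
    weights = (
        landmark_weights(n, reg_src)
        if config.variant == "anisotropic_landmark"
        else np.ones(n)
    )
    target_field = covariance_field(target.points, config.noise) if mode == "anisotropic" else None
    UL = target.points[reg_tgt] if reg_src.size else None
    pinned = (reg_src, reg_tgt) if config.variant == "anisotropic_landmark" else None
    center = source.points.mean(axis=0) if config.center_coordinates else np.zeros(3)
    # conjugation factors mapping centered-frame transforms back to camera frame
    t_minus, t_plus = np.eye(4), np.eye(4)
    t_minus[3, :3] = -center
    t_plus[3, :3] = center

    cloud = source.copy()
    cumulative = np.broadcast_to(np.eye(4), (n, 4, 4)).copy()
    trace: list[dict] = []
    corr: Correspondences | None = None
    converged = False

    for k in range(config.max_iterations):
        alpha = config.alpha_at(k)
        source_field = (
            covariance_field(cloud.points, config.noise) if mode == "anisotropic" else None
        )
        corr = find_correspondences(
            cloud.points,
            target.points,
            mode=mode,
            source_field=source_field,
            target_field=target_field,
            pinned=pinned,
            normalization=config.normalization,
        )
        U = target.points[corr.target_index] - center
        D = assemble_D(cloud.points - center)
        DL = assemble_DL(cloud.points - center, reg_src) if reg_src.size else None
        ULc = UL - center if UL is not None else None
        A, B = assemble_system(
            config.variant, alpha, Minc, config.G, D, U, weights, DL, ULc, config.beta
        )
        X = solve_step(A, B)
        new_pts = apply_transform_stack(cloud.with_points(cloud.points - center), X).points + center
        new_cloud = cloud.with_points(new_pts)
        displacement = float(np.linalg.norm(new_cloud.points - cloud.points, axis=1).mean())

        Xs = X.stacked
        e_s = float(np.sum((stiffness_block(Minc, config.G, alpha) @ Xs) ** 2))
        e_d = distance_cost(D, Xs, U, weights)
        e_l = 0.0
        if config.variant != "anisotropic_landmark" and DL is not None and config.beta:
            e_l = float(np.sum((config.beta * (DL @ Xs) - ULc) ** 2))
        total = e_s + e_d + e_l
        trace.append(
            {
                "iteration": k,
                "alpha": alpha,
                "e_d": e_d,
                "e_s": e_s,
                "e_l": e_l,
                "total": total,
                "mean_displacement": displacement,
            }
        )
        logger.info(
            "iter %3d  alpha=%10.4g  E_d=%12.6g  E_s=%12.6g  E_l=%12.6g  "
            "total=%12.6g  disp=%10.4g",
            k, alpha, e_d, e_s, e_l, total, displacement,
        )
        if not np.isfinite(total) or not np.all(np.isfinite(new_cloud.points)):
            raise DivergenceError(f"non-finite cost at iteration {k}", trace)
        # report camera-frame transforms: conjugate the centered-frame step
        step4 = np.zeros((n, 4, 4))
        step4[:, :, :3] = X.blocks
        step4[:, 3, 3] = 1.0
        cumulative = cumulative @ (t_minus @ step4 @ t_plus)
        cloud = new_cloud
        if displacement < config.tol:
            converged = True
            break

    m1 = _metrics.mean_surface_distance(cloud.points, target.points)
    m1_assigned = float(
        np.linalg.norm(cloud.points - target.points[corr.target_index], axis=1).mean()
    )
    m3 = _metrics.single_correspondence_pct(corr, target.n)
    m2 = None
    if (
        landmarks is not None
        and target.grid_shape is not None
        and landmarks.evaluation_pairs[0].size
    ):
        m2 = _metrics.landmark_grid_error(cloud.points, target, landmarks)
    return RegistrationResult(
        cloud=cloud,
        transform=TransformStack(cumulative[:, :, :3].copy()),
        trace=trace,
        correspondences=corr,
        m1_mm=m1,
        m1_assigned_mm=m1_assigned,
        m2_units=m2,
        m3_pct=m3,
        converged=converged,
    )
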