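"""Time-of-flight localization-error model and covariance-weighted matching.

A ToF depth camera localizes a point far more precisely across the viewing
ray than along it: here σ_z ≈ 10 mm along the camera ray versus
σ_x = σ_y = 0.02 mm laterally.  Each point therefore carries a 3×3
covariance Σ = V S² Vᵀ whose third principal axis is the unit ray from the
camera origin to the point.  Candidate correspondences (x_i, y_j) are ranked
by the Mahalanobis-type distance

    d(x, y) = ‖W_xy (x − y)‖,   W_xy = w · (Σ_x + Σ_y)^(−1/2),

which discounts displacement along the ray and so recovers lateral
neighbourhood structure that plain Euclidean matching loses under ray noise.

The matching backend evaluates d² through the quadratic form
(x−y)ᵀ Σ⁻¹ (x−y) with a closed-form 3×3 adjugate, which equals the literal
inverse-square-root path to well below 1e−8 and avoids N² eigendecompositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .core import (
    ConfigError,
    DegenerateGeometryError,
    InvalidInputError,
    PointCloud,
)

_LATERAL_TOL = 1e-6  # ray-parallel-to-global-x threshold for axis fallback


FRAMES = ("per_point_ray", "camera_axis")


@dataclass
class NoiseModel:
    """Per-axis localization standard deviations (mm) and the camera origin.

    ``frame`` selects how the error's principal z axis is oriented:
    "per_point_ray" (default) aligns it with the ray from the camera origin
    to each individual point; "camera_axis" uses the camera's optical axis
    (global z) for every point — the surface-level description of the same
    model, exact for a fronto-parallel surface.  For clouds a few mm apart
    the two coincide to within the lateral sigmas; for planes far apart
    along z the per-point rays fan out and the two matching metrics differ.
    """

    sigma_x: float = 0.02
    sigma_y: float = 0.02
    sigma_z: float = 10.0
    camera_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    frame: str = "per_point_ray"

    def __post_init__(self):
        self.camera_origin = np.asarray(self.camera_origin, dtype=np.float64).reshape(3)
        if min(self.sigma_x, self.sigma_y, self.sigma_z) <= 0:
            raise ConfigError("noise sigmas must be > 0")
        if self.frame not in FRAMES:
            raise ConfigError(f"frame must be one of {FRAMES}, got {self.frame!r}")

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([self.sigma_x, self.sigma_y, self.sigma_z])


@dataclass
class CovarianceField:
    """Per-point covariance matrices and the principal-axis frames behind them."""

    cov: np.ndarray  # (N, 3, 3)
    axes: np.ndarray  # (N, 3, 3), columns = principal axes

    def __post_init__(self):
        self.cov = np.asarray(self.cov, dtype=np.float64)
        self.axes = np.asarray(self.axes, dtype=np.float64)

    @property
    def n(self) -> int:
        return self.cov.shape[0]

    def compact(self) -> np.ndarray:
        """The six unique entries (Σ00, Σ01, Σ02, Σ11, Σ12, Σ22) per point."""
        c = self.cov
        return np.stack(
            [c[:, 0, 0], c[:, 0, 1], c[:, 0, 2], c[:, 1, 1], c[:, 1, 2], c[:, 2, 2]],
            axis=1,
        )


@dataclass
class Correspondences:
    """One target assignment per source point plus the matching distance used."""

    target_index: np.ndarray
    distance: np.ndarray

    def __post_init__(self):
        self.target_index = np.asarray(self.target_index, dtype=np.int64)
        self.distance = np.asarray(self.distance, dtype=np.float64)
        if self.target_index.shape != self.distance.shape:
            raise InvalidInputError("index/distance length mismatch")
        if self.target_index.size and self.target_index.min() < 0:
            raise InvalidInputError("unassigned source point in correspondences")

    @property
    def n(self) -> int:
        return self.target_index.size

    def target_counts(self, n_target: int) -> np.ndarray:
        """Number of source correspondents attracted by each target point."""
        return np.bincount(self.target_index, minlength=n_target)


def _as_points(cloud) -> np.ndarray:
    return cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, dtype=np.float64)


def tof_axes(point, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Orthonormal principal-axis matrix for one point (column 3 = camera ray)."""
    V = tof_axes_many(np.asarray(point, dtype=np.float64).reshape(1, 3), origin)
    return V[0]


def tof_axes_many(points, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Vectorized per-point ToF frames; columns (lateral-x, lateral-y, ray).

    The first lateral axis is global-x projected off the ray; when the ray is
    (numerically) parallel to global-x, global-y is substituted.  The second
    lateral axis is ray × first, making the frame right-handed.
    """
    pts = np.asarray(points, dtype=np.float64)
    origin = np.asarray(origin, dtype=np.float64).reshape(3)
    rays = pts - origin
    norms = np.linalg.norm(rays, axis=1)
    if np.any(norms == 0):
        raise DegenerateGeometryError("point coincides with the camera origin")
    z = rays / norms[:, None]
    ex = np.array([1.0, 0.0, 0.0])
    lat = ex - z * z[:, 0][:, None]  # ex - (ex·z) z
    lat_norm = np.linalg.norm(lat, axis=1)
    near_x = lat_norm < _LATERAL_TOL
    if np.any(near_x):
        ey = np.array([0.0, 1.0, 0.0])
        sub = ey - z[near_x] * z[near_x, 1][:, None]
        lat[near_x] = sub
        lat_norm[near_x] = np.linalg.norm(sub, axis=1)
    x_lat = lat / lat_norm[:, None]
    y_lat = np.cross(z, x_lat)
    return np.stack([x_lat, y_lat, z], axis=2)


def point_covariance(V: np.ndarray, sigmas) -> np.ndarray:
    """Σ = V S² Vᵀ for one frame or a stack of frames."""
    s2 = np.asarray(sigmas, dtype=np.float64) ** 2
    V = np.asarray(V, dtype=np.float64)
    if V.ndim == 2:
        return (V * s2) @ V.T
    return np.einsum("nij,j,nkj->nik", V, s2, V)


def covariance_field(points, noise: NoiseModel) -> CovarianceField:
    """Per-point ToF covariances for a cloud under one noise model."""
    pts = _as_points(points)
    if noise.frame == "camera_axis":
        V = np.broadcast_to(np.eye(3), (pts.shape[0], 3, 3)).copy()
    else:
        V = tof_axes_many(pts, noise.camera_origin)
    return CovarianceField(cov=point_covariance(V, noise.sigmas), axes=V)


def update_source_covariance(cloud, origin, sigmas) -> CovarianceField:
    """Recompute the source covariance field from updated point positions.

    This realizes the per-iteration covariance update by re-deriving the
    camera-ray frames at the moved points (the ray definition holds in every
    iteration); :func:`propagate_by_rotation` is the alternative backend that
    rotates the previous covariances by a rigid rotation estimate.
    """
    noise = NoiseModel(sigma_x=sigmas[0], sigma_y=sigmas[1], sigma_z=sigmas[2], camera_origin=origin)
    return covariance_field(cloud, noise)


def propagate_by_rotation(cov: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Σᵏ = R Σᵏ⁻¹ Rᵀ for one covariance or a stack of covariances."""
    cov = np.asarray(cov, dtype=np.float64)
    R = np.asarray(R, dtype=np.float64)
    if cov.ndim == 2:
        return R @ cov @ R.T
    return np.einsum("ij,njk,lk->nil", R, cov, R)


def cross_covariance(cov_x: np.ndarray, cov_y: np.ndarray) -> np.ndarray:
    """Σ_ij = Σ_x + Σ_y (sum of the pair's localization covariances)."""
    return np.asarray(cov_x, dtype=np.float64) + np.asarray(cov_y, dtype=np.float64)


def weight_matrix(cov: np.ndarray, w: float = 1.0) -> np.ndarray:
    """W = w · Σ^(−1/2), the symmetric inverse matrix square root.

    Eigenvalues are floored at 1e−12 so nearly singular covariances stay
    invertible; the input must be symmetric.
    """
    cov = np.asarray(cov, dtype=np.float64)
    if not np.allclose(cov, cov.T, rtol=1e-8, atol=1e-10):
        raise InvalidInputError("covariance must be symmetric")
    vals, vecs = np.linalg.eigh(cov)
    vals = np.maximum(vals, 1e-12)
    return w * (vecs / np.sqrt(vals)) @ vecs.T


def weighted_distance(x, y, W: np.ndarray) -> float:
    """d(x, y) = ‖W (x − y)‖ in mm-equivalent units."""
    r = np.asarray(x, dtype=np.float64) - np.asarray(y, dtype=np.float64)
    return float(np.linalg.norm(W @ r))


def _aniso_sq_distances(src, tgt, src_c6, tgt_c6, normalization=1.0):
    """Squared weighted distances w²·rᵀ(Σ_i+Σ_j)⁻¹r for a block of pairs.

    Uses the closed-form 3×3 adjugate of the symmetric cross-covariance, so
    the whole block is elementwise numpy work.  ``*_c6`` are compact
    covariances from :meth:`CovarianceField.compact`.
    """
    a = src_c6[:, None, 0] + tgt_c6[None, :, 0]
    b = src_c6[:, None, 1] + tgt_c6[None, :, 1]
    c = src_c6[:, None, 2] + tgt_c6[None, :, 2]
    d = src_c6[:, None, 3] + tgt_c6[None, :, 3]
    e = src_c6[:, None, 4] + tgt_c6[None, :, 4]
    f = src_c6[:, None, 5] + tgt_c6[None, :, 5]
    u = src[:, None, 0] - tgt[None, :, 0]
    v = src[:, None, 1] - tgt[None, :, 1]
    t = src[:, None, 2] - tgt[None, :, 2]
    A11 = d * f - e * e
    A12 = c * e - b * f
    A13 = b * e - c * d
    A22 = a * f - c * c
    A23 = b * c - a * e
    A33 = a * d - b * b
    det = a * A11 + b * A12 + c * A13
    quad = (
        A11 * u * u
        + A22 * v * v
        + A33 * t * t
        + 2.0 * (A12 * u * v + A13 * u * t + A23 * v * t)
    )
    return normalization**2 * quad / det


_CHUNK_PAIRS = 4_000_000  # pairwise-block budget (float64 entries per temp array)


def find_correspondences(
    source,
    target,
    mode: str = "isotropic",
    source_field: CovarianceField | None = None,
    target_field: CovarianceField | None = None,
    pinned: tuple[np.ndarray, np.ndarray] | None = None,
    normalization: float = 1.0,
    backend: str = "brute",
) -> Correspondences:
    """Assign every source point its closest target under the chosen metric.

    ``mode`` is "isotropic" (plain Euclidean) or "anisotropic" (covariance
    weighted; both fields required).  ``pinned`` is an optional
    (source_indices, target_indices) pair of landmark assignments that are
    held fixed and excluded from the nearest-neighbour search.  Ties break to
    the lowest target index; the default brute-force backend guarantees that,
    and the "kdtree" backend (isotropic only) is an accelerated alternative.
    """
    src = _as_points(source)
    tgt = _as_points(target)
    if tgt.shape[0] == 0:
        raise InvalidInputError("target cloud is empty")
    ns, nt = src.shape[0], tgt.shape[0]
    if mode not in ("isotropic", "anisotropic"):
        raise ConfigError(f"unknown correspondence mode {mode!r}")
    if mode == "anisotropic" and (source_field is None or target_field is None):
        raise ConfigError("anisotropic matching requires source and target covariance fields")

    indices = np.empty(ns, dtype=np.int64)
    distances = np.empty(ns, dtype=np.float64)
    free = np.ones(ns, dtype=bool)
    if pinned is not None:
        p_src = np.asarray(pinned[0], dtype=np.int64)
        p_tgt = np.asarray(pinned[1], dtype=np.int64)
        free[p_src] = False
        indices[p_src] = p_tgt

    free_idx = np.flatnonzero(free)
    if free_idx.size:
        if mode == "isotropic" and backend == "kdtree":
            tree = cKDTree(tgt)
            dd, jj = tree.query(src[free_idx], k=1)
            indices[free_idx] = jj
            distances[free_idx] = dd
        else:
            chunk = max(1, _CHUNK_PAIRS // nt)
            src_c6 = source_field.compact() if mode == "anisotropic" else None
            tgt_c6 = target_field.compact() if mode == "anisotropic" else None
            for start in range(0, free_idx.size, chunk):
                sel = free_idx[start : start + chunk]
                if mode == "isotropic":
                    d2 = cdist(src[sel], tgt, metric="sqeuclidean")
                else:
                    d2 = _aniso_sq_distances(src[sel], tgt, src_c6[sel], tgt_c6, normalization)
                jj = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
                indices[sel] = jj
                distances[sel] = np.sqrt(np.maximum(d2[np.arange(sel.size), jj], 0.0))

    if pinned is not None and p_src.size:
        # distance of pinned pairs under the same metric, for maps/traces
        diff = src[p_src] - tgt[p_tgt]
        if mode == "isotropic":
            distances[p_src] = np.linalg.norm(diff, axis=1)
        else:
            d2 = _aniso_sq_distances(
                src[p_src], tgt[p_tgt], source_field.compact()[p_src],
                target_field.compact()[p_tgt], normalization,
            )
            distances[p_src] = np.sqrt(np.maximum(np.diag(d2), 0.0))
    return Correspondences(target_index=indices, distance=distances)
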