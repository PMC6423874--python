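"""Core geometric types shared by the registration pipeline.

Coordinates are camera-frame millimetres: the camera sits at the origin
looking along +z, so a surface recorded 1.1 m in front of the sensor has
z ≈ 1100 mm.  Point clouds are ordered; when a cloud is a regular mesh the
points are stored row-major and ``grid_shape`` records (rows, cols).

Every vertex carries its own 4×3 affine transform (rows 1-3 linear part,
row 4 translation), applied to the homogeneous row vector [x y z 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidInputError(ValueError):
    """Raised when an input array violates a documented precondition."""


class ConfigError(ValueError):
    """Raised for invalid configuration values or missing required inputs."""


class DegenerateGeometryError(ValueError):
    """Raised when geometry is degenerate (e.g. a point at the camera origin)."""


class DivergenceError(RuntimeError):
    """Raised when a registration run produces non-finite cost.

    Carries the per-iteration diagnostic ``trace`` accumulated so far.
    """

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace if trace is not None else []


REGISTRATION = "registration"
EVALUATION = "evaluation"


@dataclass
class PointCloud:
    """Ordered 3-D points in mm, optionally on a regular (rows, cols) grid."""

    points: np.ndarray
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
            raise InvalidInputError(f"points must be (N, 3) with N >= 1, got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("point coordinates must be finite")
        if self.grid_shape is not None:
            rows, cols = self.grid_shape
            if rows * cols != pts.shape[0]:
                raise InvalidInputError(
                    f"grid_shape {self.grid_shape} inconsistent with N={pts.shape[0]}"
                )
            self.grid_shape = (int(rows), int(cols))
        self.points = pts

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def copy(self) -> "PointCloud":
        return PointCloud(self.points.copy(), self.grid_shape)

    def with_points(self, points: np.ndarray) -> "PointCloud":
        return PointCloud(points, self.grid_shape)


@dataclass
class TransformStack:
    """Per-vertex 4×3 affine blocks; stacked they form the 4N×3 unknown X."""

    blocks: np.ndarray  # (N, 4, 3)

    def __post_init__(self):
        b = np.asarray(self.blocks, dtype=np.float64)
        if b.ndim != 3 or b.shape[1:] != (4, 3):
            raise InvalidInputError(f"blocks must be (N, 4, 3), got {b.shape}")
        if not np.all(np.isfinite(b)):
            raise InvalidInputError("transform entries must be finite")
        self.blocks = b

    @property
    def n(self) -> int:
        return self.blocks.shape[0]

    @property
    def stacked(self) -> np.ndarray:
        """The 4N×3 stacked matrix."""
        return self.blocks.reshape(-1, 3)

    @classmethod
    def from_stacked(cls, stacked: np.ndarray) -> "TransformStack":
        stacked = np.asarray(stacked, dtype=np.float64)
        if stacked.ndim != 2 or stacked.shape[1] != 3 or stacked.shape[0] % 4:
            raise InvalidInputError(f"stacked transform must be (4N, 3), got {stacked.shape}")
        return cls(stacked.reshape(-1, 4, 3))

    @classmethod
    def identity(cls, n: int) -> "TransformStack":
        block = np.vstack([np.eye(3), np.zeros(3)])
        return cls(np.broadcast_to(block, (n, 4, 3)).copy())

    @classmethod
    def translation(cls, n: int, t) -> "TransformStack":
        block = np.vstack([np.eye(3), np.asarray(t, dtype=np.float64)])
        return cls(np.broadcast_to(block, (n, 4, 3)).copy())


@dataclass
class GridTopology:
    """Directed arcs of a regular mesh, start < end in row-major index order."""

    edges: np.ndarray  # (E, 2) int
    connectivity: int = 4
    n_nodes: int | None = None

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if e.size and np.any(e[:, 0] == e[:, 1]):
            raise InvalidInputError("self-loop arc in topology")
        if e.size and e.min() < 0:
            raise InvalidInputError("negative node index in topology")
        if self.n_nodes is not None and e.size and e.max() >= self.n_nodes:
            raise InvalidInputError("arc index out of range")
        # each undirected adjacency appears once
        key = np.sort(e, axis=1)
        if e.shape[0] != len({(a, b) for a, b in map(tuple, key)}):
            raise InvalidInputError("duplicate adjacency in topology")
        self.edges = e

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


@dataclass
class LandmarkSet:
    """Known source↔target correspondences, split into registration/evaluation roles.

    Marker metadata (marker_row, marker_col, corner_id) is optional and only
    used for provenance of marker-corner landmarks.
    """

    source_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    target_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    role: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    marker_row: np.ndarray | None = None
    marker_col: np.ndarray | None = None
    corner_id: np.ndarray | None = None

    def __post_init__(self):
        self.source_index = np.asarray(self.source_index, dtype=np.int64)
        self.target_index = np.asarray(self.target_index, dtype=np.int64)
        self.role = np.asarray(self.role, dtype=object)
        if not (len(self.source_index) == len(self.target_index) == len(self.role)):
            raise InvalidInputError("landmark columns must have equal length")
        bad = set(self.role) - {REGISTRATION, EVALUATION}
        if bad:
            raise InvalidInputError(f"invalid landmark roles: {sorted(bad)}")
        if len(np.unique(self.source_index)) != len(self.source_index):
            raise InvalidInputError("duplicate source index in landmark set")

    def __len__(self) -> int:
        return len(self.source_index)

    def _select(self, role: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.role == role
        return self.source_index[mask], self.target_index[mask]

    @property
    def registration_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        return self._select(REGISTRATION)

    @property
    def evaluation_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        return self._select(EVALUATION)

    def validate_against(self, n_source: int, n_target: int) -> None:
        if len(self) == 0:
            return
        if self.source_index.min() < 0 or self.source_index.max() >= n_source:
            raise InvalidInputError("landmark source index out of range")
        if self.target_index.min() < 0 or self.target_index.max() >= n_target:
            raise InvalidInputError("landmark target index out of range")


def make_homogeneous(cloud: PointCloud | np.ndarray) -> np.ndarray:
    """Return the N×4 homogeneous vertex table [x y z 1] per row."""
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, dtype=np.float64)
    if not np.all(np.isfinite(pts)):
        raise InvalidInputError("point coordinates must be finite")
    return np.hstack([pts, np.ones((pts.shape[0], 1))])


def build_grid_topology(rows: int, cols: int, connectivity: int = 4) -> GridTopology:
    """Arcs of a rows×cols grid, 4- or 8-connected, row-major node indices.

    For 4-connectivity the arc count is rows·(cols−1) + cols·(rows−1);
    8-connectivity adds both diagonals of every grid cell.
    """
    if connectivity not in (4, 8):
        raise ConfigError(f"connectivity must be 4 or 8, got {connectivity}")
    if rows < 1 or cols < 1:
        raise ConfigError("rows and cols must be >= 1")
    idx = np.arange(rows * cols).reshape(rows, cols)
    arcs = []
    # horizontal and vertical neighbours
    arcs.append(np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1))
    arcs.append(np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1))
    if connectivity == 8:
        arcs.append(np.stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel()], axis=1))
        # anti-diagonal: (r, c+1) has the smaller row-major index than (r+1, c)
        arcs.append(np.stack([idx[:-1, 1:].ravel(), idx[1:, :-1].ravel()], axis=1))
    edges = np.concatenate([a for a in arcs if a.size], axis=0) if rows * cols > 1 else np.empty((0, 2), dtype=np.int64)
    if edges.size:
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        edges = edges[order]
    return GridTopology(edges=edges, connectivity=connectivity, n_nodes=rows * cols)


def apply_transform_stack(cloud: PointCloud, stack: TransformStack) -> PointCloud:
    """Move every point through its own block: p_i' = [p_i 1] · X_i."""
    if stack.n != cloud.n:
        raise InvalidInputError(
            f"transform stack has {stack.n} blocks for {cloud.n} points"
        )
    hom = make_homogeneous(cloud)
    new_pts = np.einsum("ni,nij->nj", hom, stack.blocks)
    return cloud.with_points(new_pts)
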