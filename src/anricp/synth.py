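"""Deterministic synthetic fixtures: flat mesh pairs, step patterns, and a
breathing-like abdominal surface pair with a 3×3 marker grid.

The flat pair is two 25×25 regular meshes spanning x, y ∈ [−125, 125] mm at
z = 1100 mm (source) and z = 1200 mm (target), optionally perturbed by ToF
localization noise (σ_z = 10 mm along each point's camera ray, 0.02 mm
laterally).  The step pair draws the noiseless source away laterally and in
depth so the surfaces only partially overlap.  The breathing pair bends one
surface up and the other down by the same radial Gaussian bump, emulating the
convex↔concave abdominal change between exhale and inhale; it carries
36 marker-corner landmarks (9 markers × 4 corners, 15 mm squares), 9 of which
(the first corner of each marker) are flagged for registration and 27 held
out for evaluation.

In every fixture point i of the source corresponds to point i of the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .aniso import NoiseModel, tof_axes_many
from .core import (
    EVALUATION,
    REGISTRATION,
    ConfigError,
    GridTopology,
    LandmarkSet,
    PointCloud,
    build_grid_topology,
)

FIXTURE_KINDS = ("flat_pair", "step_pair", "breathing_pair")


@dataclass
class FixtureSpec:
    """Geometry, noise and landmark parameters of one synthetic pair."""

    kind: str = "flat_pair"
    rows: int = 25
    cols: int = 25
    x_bounds: tuple[float, float] = (-125.0, 125.0)
    y_bounds: tuple[float, float] = (-125.0, 125.0)
    source_z: float = 1100.0
    target_z: float = 1200.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    noise_enabled: bool | None = None  # default: on for flat_pair, off otherwise
    connectivity: int = 4
    step_dx: float = 50.0
    step_dz: float = 20.0
    bump_amplitude: float = 20.0
    bump_sigma: float = 60.0
    breathing_base_z: float = 1150.0
    marker_centers: tuple[float, ...] = (-75.0, 0.0, 75.0)
    marker_size: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ConfigError(f"kind must be one of {FIXTURE_KINDS}, got {self.kind!r}")
        if self.rows < 1 or self.cols < 1:
            raise ConfigError("rows and cols must be >= 1")
        if self.bump_amplitude < 0:
            raise ConfigError("bump_amplitude must be >= 0")
        if self.noise_enabled is None:
            self.noise_enabled = self.kind == "flat_pair"


@dataclass
class Fixture:
    """A generated source/target pair with topology and optional landmarks."""

    source: PointCloud
    target: PointCloud
    topology: GridTopology
    landmarks: LandmarkSet | None = None


def _grid(spec: FixtureSpec, z: float) -> np.ndarray:
    xs = np.linspace(*spec.x_bounds, spec.cols)
    ys = np.linspace(*spec.y_bounds, spec.rows)
    gx, gy = np.meshgrid(xs, ys)  # row-major: rows over y, cols over x
    pts = np.stack([gx.ravel(), gy.ravel(), np.full(gx.size, float(z))], axis=1)
    return pts


def flat_mesh_pair(spec: FixtureSpec | None = None):
    """Two flat regular meshes at the source/target z planes (noiseless)."""
    spec = spec or FixtureSpec(kind="flat_pair")
    source = PointCloud(_grid(spec, spec.source_z), (spec.rows, spec.cols))
    target = PointCloud(_grid(spec, spec.target_z), (spec.rows, spec.cols))
    topology = build_grid_topology(spec.rows, spec.cols, spec.connectivity)
    return source, target, topology


def add_tof_noise(cloud: PointCloud, noise: NoiseModel, seed) -> PointCloud:
    """Perturb each point by zero-mean Gaussian noise in its ToF principal axes.

    σ_z acts along the camera ray through the point, the lateral sigmas
    across it; ``seed`` may be an int or a numpy Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    V = tof_axes_many(cloud.points, noise.camera_origin)
    local = rng.normal(0.0, noise.sigmas, size=(cloud.n, 3))
    return cloud.with_points(cloud.points + np.einsum("nij,nj->ni", V, local))


def _snap(values: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Index of the nearest grid coordinate for each value."""
    return np.abs(coords[None, :] - values[:, None]).argmin(axis=1)


def _subgrid_landmarks(spec: FixtureSpec, n_per_axis: int, offset_frac: float) -> np.ndarray:
    """Row-major indices of an n×n subgrid spread across the mesh interior."""
    ridx = np.round(np.linspace(offset_frac * (spec.rows - 1), (1 - offset_frac) * (spec.rows - 1), n_per_axis)).astype(int)
    cidx = np.round(np.linspace(offset_frac * (spec.cols - 1), (1 - offset_frac) * (spec.cols - 1), n_per_axis)).astype(int)
    rr, cc = np.meshgrid(ridx, cidx, indexing="ij")
    return (rr * spec.cols + cc).ravel()


def step_pattern_pair(spec: FixtureSpec | None = None):
    """Noiseless flat pair with the source drawn away into a step arrangement.

    The source plane is offset by (step_dx, 0, step_dz) so the two surfaces
    only partially overlap.  9 registration landmarks sit on a 3×3 interior
    subgrid and 16 evaluation landmarks on a disjoint 4×4 subgrid; true
    correspondences are the identity on grid indices.
    """
    spec = spec or FixtureSpec(kind="step_pair")
    source, target, topology = flat_mesh_pair(spec)
    src_pts = source.points + np.array([spec.step_dx, 0.0, spec.step_dz])
    source = PointCloud(src_pts, source.grid_shape)
    reg = _subgrid_landmarks(spec, 3, 0.25)
    ev = _subgrid_landmarks(spec, 4, 0.125)
    ev = np.setdiff1d(ev, reg)
    idx = np.concatenate([reg, ev])
    roles = np.array([REGISTRATION] * reg.size + [EVALUATION] * ev.size, dtype=object)
    landmarks = LandmarkSet(source_index=idx, target_index=idx, role=roles)
    return source, target, topology, landmarks


def breathing_pair(spec: FixtureSpec | None = None):
    """Convex (source) versus concave (target) abdominal-like surface pair.

    Both clouds share one base plane; the source adds and the target
    subtracts the same radial Gaussian bump A·exp(−r²/2s²), so the central
    point moves by 2A between phases.  36 marker-corner landmarks (9 markers
    × 4 corners of 15 mm squares, snapped to grid points) are attached; the
    first corner of each marker is a registration landmark, the remaining 27
    are evaluation landmarks.
    """
    spec = spec or FixtureSpec(kind="breathing_pair")
    base = _grid(spec, spec.breathing_base_z)
    r2 = base[:, 0] ** 2 + base[:, 1] ** 2
    bump = spec.bump_amplitude * np.exp(-r2 / (2.0 * spec.bump_sigma**2))
    src_pts = base.copy()
    src_pts[:, 2] += bump
    tgt_pts = base.copy()
    tgt_pts[:, 2] -= bump
    shape = (spec.rows, spec.cols)
    source = PointCloud(src_pts, shape)
    target = PointCloud(tgt_pts, shape)
    topology = build_grid_topology(spec.rows, spec.cols, spec.connectivity)

    xs = np.linspace(*spec.x_bounds, spec.cols)
    ys = np.linspace(*spec.y_bounds, spec.rows)
    half = spec.marker_size / 2.0
    idx, mrow, mcol, cid = [], [], [], []
    corner_offsets = [(-half, -half), (-half, half), (half, -half), (half, half)]
    for mi, cy in enumerate(spec.marker_centers):
        for mj, cx in enumerate(spec.marker_centers):
            for ci, (ox, oy) in enumerate(corner_offsets):
                c = _snap(np.array([cx + ox]), xs)[0]
                r = _snap(np.array([cy + oy]), ys)[0]
                idx.append(r * spec.cols + c)
                mrow.append(mi)
                mcol.append(mj)
                cid.append(ci)
    idx = np.asarray(idx, dtype=np.int64)
    if len(np.unique(idx)) != len(idx):
        raise ConfigError("marker corners collide on the grid; refine the mesh")
    roles = np.array(
        [REGISTRATION if c == 0 else EVALUATION for c in cid], dtype=object
    )
    landmarks = LandmarkSet(
        source_index=idx,
        target_index=idx.copy(),
        role=roles,
        marker_row=np.asarray(mrow),
        marker_col=np.asarray(mcol),
        corner_id=np.asarray(cid),
    )
    return source, target, topology, landmarks


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the pair named by ``spec.kind``, applying noise if enabled.

    With noise enabled, the source and target receive independent noise draws
    deterministically derived from ``spec.seed``.
    """
    landmarks = None
    if spec.kind == "flat_pair":
        source, target, topology = flat_mesh_pair(spec)
    elif spec.kind == "step_pair":
        source, target, topology, landmarks = step_pattern_pair(spec)
    else:
        source, target, topology, landmarks = breathing_pair(spec)
    if spec.noise_enabled:
        rng = np.random.default_rng(spec.seed)
        source = add_tof_noise(source, spec.noise, rng)
        target = add_tof_noise(target, spec.noise, rng)
    return Fixture(source=source, target=target, topology=topology, landmarks=landmarks)


def noiseless(spec: FixtureSpec) -> FixtureSpec:
    """Copy of a spec with noise disabled."""
    return replace(spec, noise_enabled=False)
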