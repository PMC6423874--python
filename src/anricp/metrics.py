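"""Registration-quality measures, correspondence/distance maps and histograms.

Three scalar measures summarize a run:

* **M1** — mean surface distance (mm): mean over source points of the
  Euclidean distance to the closest target point, recomputed with plain
  Euclidean nearest neighbours regardless of the matching metric the
  registration used.
* **M2** — mean landmark grid misalignment (grid units): for each held-out
  evaluation landmark, the Manhattan distance |Δrow| + |Δcol| between the
  grid coordinates of the target point nearest its deformed position and
  those of its true correspondent, averaged over evaluation landmarks.
* **M3** — percentage of target points with exactly one source correspondent
  in the registration's final assignment; 100% means the clouds were matched
  uniformly one-to-one.

Maps lay per-target quantities out on the mesh grid; histograms use integer
bins (correspondent count, or 1-mm left-closed distance bins where bin 0
means "closer than 1 mm").
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .aniso import Correspondences, find_correspondences
from .core import InvalidInputError, LandmarkSet, PointCloud


def _pts(cloud):
    return cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, dtype=np.float64)


def mean_surface_distance(source, target, corr: Correspondences | None = None) -> float:
    """M1: mean Euclidean closest-point distance from source to target (mm)."""
    src = _pts(source)
    tgt = _pts(target)
    if src.shape[0] == 0 or tgt.shape[0] == 0:
        raise InvalidInputError("empty cloud")
    if corr is None:
        corr = find_correspondences(src, tgt, mode="isotropic", backend="kdtree")
    return float(np.linalg.norm(src - tgt[corr.target_index], axis=1).mean())


def landmark_grid_error(deformed, target: PointCloud, landmarks: LandmarkSet) -> float:
    """M2: mean |Δrow| + |Δcol| of evaluation landmarks on the target grid."""
    if target.grid_shape is None:
        raise InvalidInputError("target cloud carries no grid_shape; M2 undefined")
    ev_src, ev_tgt = landmarks.evaluation_pairs
    if ev_src.size == 0:
        raise InvalidInputError("no evaluation landmarks; M2 undefined")
    pts = _pts(deformed)
    corr = find_correspondences(pts[ev_src], target.points, mode="isotropic")
    cols = target.grid_shape[1]
    got_r, got_c = np.divmod(corr.target_index, cols)
    true_r, true_c = np.divmod(ev_tgt, cols)
    return float((np.abs(got_r - true_r) + np.abs(got_c - true_c)).mean())


def single_correspondence_pct(corr: Correspondences, target_size: int) -> float:
    """M3: 100 · (#targets with exactly one correspondent) / target size."""
    counts = corr.target_counts(target_size)
    return 100.0 * float(np.count_nonzero(counts == 1)) / target_size


def correspondence_map_and_histogram(corr: Correspondences, target: PointCloud):
    """Per-target correspondent counts (grid map when available) and their histogram.

    The histogram is indexed by correspondent count (0 allowed) and its
    entries sum to the target-cloud size; map values sum to the source size.
    """
    counts = corr.target_counts(target.n)
    histogram = np.bincount(counts)
    cmap = counts.reshape(target.grid_shape) if target.grid_shape else counts
    return cmap, histogram


def distance_map_and_histogram(corr: Correspondences, deformed, target: PointCloud):
    """Per-target Euclidean distance map and 1-mm-bin histogram of pair distances.

    The histogram counts source points by floor(distance) so bin 0 collects
    pairs closer than 1 mm; the map shows each target's nearest assigned
    correspondent distance, NaN where no correspondent was attracted.
    """
    pts = _pts(deformed)
    dist = np.linalg.norm(pts - target.points[corr.target_index], axis=1)
    histogram = np.bincount(np.floor(dist).astype(np.int64), minlength=1)
    # NaN marks targets with no correspondent; attracted targets start at +inf
    dmap = np.full(target.n, np.nan)
    dmap[np.unique(corr.target_index)] = np.inf
    np.minimum.at(dmap, corr.target_index, dist)
    if target.grid_shape:
        dmap = dmap.reshape(target.grid_shape)
    return dmap, histogram


@dataclass
class QualityReport:
    """Scalar measures plus map/histogram fragments for one registered pair."""

    m1_mm: float
    m1_assigned_mm: float
    m3_pct: float
    m2_units: float | None = None
    correspondence_histogram: np.ndarray | None = None
    distance_histogram: np.ndarray | None = None
    correspondence_map: np.ndarray | None = None
    distance_map: np.ndarray | None = None

    def to_dict(self) -> dict:
        def arr(x):
            return None if x is None else np.asarray(x).tolist()

        return {
            "m1_mm": self.m1_mm,
            "m1_assigned_mm": self.m1_assigned_mm,
            "m2_units": self.m2_units,
            "m3_pct": self.m3_pct,
            "correspondence_histogram": arr(self.correspondence_histogram),
            "distance_histogram": arr(self.distance_histogram),
            "correspondence_map": arr(self.correspondence_map),
            "distance_map": arr(self.distance_map),
        }

    def to_json(self, **kwargs) -> str:
        d = self.to_dict()
        # NaN holes in the distance map are serialized as nulls
        if d["distance_map"] is not None:
            d["distance_map"] = _nan_to_none(d["distance_map"])
        return json.dumps(d, **kwargs)


def _nan_to_none(obj):
    if isinstance(obj, list):
        return [_nan_to_none(v) for v in obj]
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def build_quality_report(
    deformed,
    target: PointCloud,
    corr: Correspondences,
    landmarks: LandmarkSet | None = None,
) -> QualityReport:
    """Assemble M1/M2/M3 and the maps/histograms from a final assignment.

    M1 always uses fresh Euclidean nearest neighbours; ``m1_assigned_mm`` is
    the companion reading over the registration's own assigned pairs.  M2 is
    reported only when evaluation landmarks and a target grid are available.
    """
    pts = _pts(deformed)
    m1 = mean_surface_distance(pts, target)
    m1_assigned = float(np.linalg.norm(pts - target.points[corr.target_index], axis=1).mean())
    m3 = single_correspondence_pct(corr, target.n)
    m2 = None
    if (
        landmarks is not None
        and target.grid_shape is not None
        and landmarks.evaluation_pairs[0].size
    ):
        m2 = landmark_grid_error(pts, target, landmarks)
    cmap, chist = correspondence_map_and_histogram(corr, target)
    dmap, dhist = distance_map_and_histogram(corr, pts, target)
    return QualityReport(
        m1_mm=m1,
        m1_assigned_mm=m1_assigned,
        m2_units=m2,
        m3_pct=m3,
        correspondence_histogram=chist,
        distance_histogram=dhist,
        correspondence_map=cmap,
        distance_map=dmap,
    )


def median_report(reports: list[dict]) -> dict:
    """Median of each scalar measure over a batch of per-case report dicts."""
    out = {}
    for key in ("m1_mm", "m1_assigned_mm", "m2_units", "m3_pct"):
        vals = [r[key] for r in reports if r.get(key) is not None]
        out[key] = float(np.median(vals)) if vals else None
    return out


def render_maps(report: QualityReport, path) -> None:
    """Write correspondence/distance maps and histograms to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    panels = [
        (report.correspondence_map, "correspondents per target point"),
        (report.distance_map, "distance to nearest correspondent [mm]"),
    ]
    for ax, (arr, title) in zip(axes[0], panels):
        if arr is not None and np.asarray(arr).ndim == 2:
            im = ax.imshow(arr, origin="lower")
            fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_title(title, fontsize=9)
    hists = [
        (report.correspondence_histogram, "correspondent count"),
        (report.distance_histogram, "pair distance [mm, 1-mm bins]"),
    ]
    for ax, (arr, xlabel) in zip(axes[1], hists):
        if arr is not None:
            ax.bar(np.arange(len(arr)), arr)
        ax.set_xlabel(xlabel, fontsize=9)
        ax.set_ylabel("points")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
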