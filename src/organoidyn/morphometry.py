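"""Point-cloud morphometry of nuclei centroids.

Nuclei-segmentation pipelines reduce a light-sheet stack to a set of 3D
centroids per time point.  This module computes the neighbourhood metrics
used to describe organoid architecture — the Delaunay cell graph (DCG) and
the proximity cell graph (PCG, neighbours closer than a distance cutoff) —
plus convex-hull volume/surface proxies, and evaluates a segmentation against
a ground-truth centroid set by one-to-one matching within a spherical
neighbourhood (default ten voxels), reporting recall, precision and F score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, cKDTree
from scipy.spatial._qhull import QhullError

from .errors import GeometryError

logger = logging.getLogger(__name__)

DEFAULT_PROXIMITY_CUTOFF = 50.0   # voxels
DEFAULT_MATCH_RADIUS = 10.0       # voxels


@dataclass(frozen=True)
class CentroidSet:
    """Timestamped nuclei centroids in voxel units."""

    points: np.ndarray                      # (N, 3) voxels
    time_label: str | None = None
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # µm per voxel

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 1:
            raise ValueError("points must be a non-empty (N, 3) array")
        if not np.isfinite(pts).all():
            raise ValueError("centroid coordinates must be finite")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def in_microns(self) -> np.ndarray:
        return self.points * np.asarray(self.voxel_size, dtype=float)


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, CentroidSet):
        return obj.points
    return np.asarray(obj, dtype=float)


def delaunay_degrees(points) -> tuple[np.ndarray, float]:
    """Per-point neighbour counts in the 3D Delaunay cell graph (DCG)."""
    pts = _as_points(points)
    if len(pts) < 4:
        raise GeometryError(f"Delaunay graph needs at least 4 points, got {len(pts)}")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise GeometryError(f"degenerate (coplanar?) centroid cloud: {exc}") from exc
    indptr, _ = tri.vertex_neighbor_vertices
    degrees = np.diff(indptr)
    return degrees, float(degrees.mean())


def proximity_degrees(
    points, cutoff: float = DEFAULT_PROXIMITY_CUTOFF
) -> tuple[np.ndarray, float]:
    """Per-point neighbour counts in the proximity cell graph (PCG).

    Two centroids are neighbours when their Euclidean distance is strictly
    below ``cutoff`` (50 voxels by default).  Coincident points count as
    mutual neighbours.
    """
    pts = _as_points(points)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    # query_pairs uses <=; drop exact-cutoff pairs to keep the strict rule
    if len(pairs):
        d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]
    degrees = np.zeros(len(pts), dtype=int)
    for col in (0, 1):
        np.add.at(degrees, pairs[:, col], 1)
    return degrees, float(degrees.mean())


def approximate_volume_surface(points) -> tuple[float, float]:
    """Convex-hull volume (voxel³) and surface area (voxel²) of a cloud."""
    pts = _as_points(points)
    if len(pts) < 4:
        raise GeometryError(f"hull needs at least 4 points, got {len(pts)}")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise GeometryError(f"degenerate centroid cloud: {exc}") from exc
    return float(hull.volume), float(hull.area)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of centroid-level segmentation evaluation."""

    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    f_score: float
    pairs: list[tuple[int, int]]   # (ground-truth index, segmented index)


def _safe_ratio(num: int, den: int) -> float:
    return num / den if den > 0 else 0.0


def match_centroids(
    gt, seg, radius: float = DEFAULT_MATCH_RADIUS, use_microns: bool = False
) -> MatchResult:
    """One-to-one matching of segmented centroids against ground truth.

    A ground-truth centroid is a true positive when a segmented centroid lies
    within ``radius`` (ten voxels by default); among multiple candidates the
    closest wins.  Conflicts where one segmented centroid is nearest to two
    ground-truth centroids are resolved globally and deterministically by
    assigning candidate pairs in ascending distance order.  Unmatched ground
    truth counts as false negative, unmatched segmentation as false positive.
    """
    if radius <= 0:
        raise ValueError(f"matching radius must be positive, got {radius}")
    if use_microns:
        gt_pts = gt.in_microns() if isinstance(gt, CentroidSet) else np.asarray(gt)
        seg_pts = seg.in_microns() if isinstance(seg, CentroidSet) else np.asarray(seg)
    else:
        gt_pts, seg_pts = _as_points(gt), _as_points(seg)

    n_gt, n_seg = len(gt_pts), len(seg_pts)
    if n_gt == 0 and n_seg == 0:
        warnings.warn("both centroid sets empty: metrics defined as 1.0")
        return MatchResult(0, 0, 0, 1.0, 1.0, 1.0, [])
    if n_gt == 0 or n_seg == 0:
        return MatchResult(0, n_seg, n_gt, 0.0, 0.0, 0.0, [])

    tree = cKDTree(seg_pts)
    candidates: list[tuple[float, int, int]] = []
    for gi, neighbours in enumerate(tree.query_ball_point(gt_pts, r=radius)):
        for si in neighbours:
            dist = float(np.linalg.norm(gt_pts[gi] - seg_pts[si]))
            candidates.append((dist, gi, si))
    candidates.sort()

    gt_used = np.zeros(n_gt, dtype=bool)
    seg_used = np.zeros(n_seg, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for _, gi, si in candidates:
        if not gt_used[gi] and not seg_used[si]:
            gt_used[gi] = seg_used[si] = True
            pairs.append((gi, si))

    tp = len(pairs)
    fn = n_gt - tp
    fp = n_seg - tp
    recall = _safe_ratio(tp, tp + fn)
    precision = _safe_ratio(tp, tp + fp)
    f = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return MatchResult(tp, fp, fn, recall, precision, f, pairs)
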