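"""Plot cropping, RANSAC ground-plane removal, and Euclidean-cluster denoising.

A scanned row cloud is cropped into plot clouds along the travel axis, the
ground plane under each plot is fitted robustly with RANSAC and removed, and
detached point clusters (weeds) are discarded by single-linkage Euclidean
clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .cloud import PointCloud

__all__ = [
    "PlotLayout",
    "GroundPlane",
    "crop_plot",
    "fit_ground_ransac",
    "remove_ground",
    "normalize_to_plane",
    "cluster_denoise",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlotLayout:
    """Field geometry: a grid of plots along parallel rows.

    Along-track (x), plots of ``plot_width`` metres are separated by
    ``inter_col`` alleys, so column c spans
    ``[origin_x + c*(plot_width+inter_col), +plot_width)`` (half-open).
    Rows repeat cross-track at ``inter_row`` pitch.  Defaults reproduce a
    16-row x 8-column cotton trial with 3.05 m plots, 1.52 m row spacing and
    1.83 m alleys.
    """

    n_rows: int = 16
    n_cols: int = 8
    plot_width: float = 3.05
    inter_row: float = 1.52
    inter_col: float = 1.83
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if min(self.plot_width, self.inter_row, self.inter_col) <= 0:
            raise ValueError("plot width and spacings must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid counts must be >= 1")

    def col_interval(self, col: int) -> tuple[float, float]:
        x0 = self.origin[0] + col * (self.plot_width + self.inter_col)
        return x0, x0 + self.plot_width

    def row_y(self, row: int) -> float:
        return self.origin[1] + row * self.inter_row


def crop_plot(row_cloud: PointCloud, layout: PlotLayout, row: int, col: int) -> PointCloud:
    """Crop a row cloud to one plot's along-track interval (half-open).

    Cross-track extent is left to the upstream enclosure filter: each pass
    scans a single row.  A boundary point belongs to the lower-index plot.
    """
    if not (0 <= row < layout.n_rows):
        raise IndexError(f"row {row} outside grid of {layout.n_rows} rows")
    if not (0 <= col < layout.n_cols):
        raise IndexError(f"col {col} outside grid of {layout.n_cols} columns")
    x0, x1 = layout.col_interval(col)
    out = row_cloud.select((row_cloud.x >= x0) & (row_cloud.x < x1))
    if len(out) == 0:
        warnings.warn(f"plot (row={row}, col={col}) crop is empty", stacklevel=2)
    return out


@dataclass(frozen=True)
class GroundPlane:
    """Plane ax + by + cz + d = 0 with unit, upward-oriented normal."""

    a: float
    b: float
    c: float
    d: float
    inlier_count: int = 0

    @property
    def normal(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        return points @ self.normal + self.d


def _plane_from_inliers(pts: np.ndarray, n_inliers: int) -> GroundPlane:
    """Total-least-squares plane through a point set (SVD on centred points)."""
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    n = vt[-1]
    if n[2] < 0:
        n = -n
    d = -float(n @ centroid)
    return GroundPlane(float(n[0]), float(n[1]), float(n[2]), d, n_inliers)


def fit_ground_ransac(
    cloud: PointCloud | np.ndarray,
    dist_threshold: float = 0.03,
    n_iter: int = 1000,
    seed: int = 0,
) -> tuple[GroundPlane, np.ndarray]:
    """RANSAC plane fit: maximize inliers within ``dist_threshold``, then refine.

    Minimal 3-point samples over ``n_iter`` seeded trials; the best
    hypothesis is refined by a total-least-squares fit on its inliers and
    the returned mask marks inliers of the refined plane.
    """
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, dtype=np.float64)
    pts = pts.reshape(-1, 3)
    n = pts.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to fit a plane")
    centred = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-12) < 2:
        raise ValueError("degenerate input: points are collinear")

    rng = np.random.default_rng(seed)
    best_count = -1
    best_normal = None
    best_d = 0.0
    for _ in range(n_iter):
        i, j, k = rng.choice(n, size=3, replace=False)
        v1 = pts[j] - pts[i]
        v2 = pts[k] - pts[i]
        nrm = np.cross(v1, v2)
        norm = np.linalg.norm(nrm)
        if norm < 1e-12:
            continue
        nrm = nrm / norm
        d = -float(nrm @ pts[i])
        count = int(np.sum(np.abs(pts @ nrm + d) <= dist_threshold))
        if count > best_count:
            best_count = count
            best_normal = nrm
            best_d = d
    if best_normal is None:
        raise ValueError("RANSAC failed: all sampled triples were collinear")

    inliers = np.abs(pts @ best_normal + best_d) <= dist_threshold
    plane = _plane_from_inliers(pts[inliers], int(np.sum(inliers)))
    mask = np.abs(plane.signed_distance(pts)) <= dist_threshold
    plane = GroundPlane(plane.a, plane.b, plane.c, plane.d, int(np.sum(mask)))
    return plane, mask


def remove_ground(
    cloud: PointCloud, plane: GroundPlane, dist_threshold: float = 0.03
) -> tuple[PointCloud, PointCloud]:
    """Partition into (plant, ground) by signed distance to the fitted plane.

    Points more than ``dist_threshold`` above the plane are plant; everything
    else (the plane band and any below-plane outliers) is ground.  The plant
    cloud gains per-point heights above the plane.
    """
    s = plane.signed_distance(cloud.points)
    plant_mask = s > dist_threshold
    plant = cloud.select(plant_mask)
    plant.heights = s[plant_mask]
    ground = cloud.select(~plant_mask)
    ground.heights = s[~plant_mask]
    if len(plant) == 0:
        warnings.warn("remove_ground: no points above the ground plane", stacklevel=2)
    assert len(plant) + len(ground) == len(cloud)
    return plant, ground


def normalize_to_plane(cloud: PointCloud, plane: GroundPlane) -> PointCloud:
    """Re-express a cloud in the ground-plane frame: z = height above plane.

    The in-plane axes are chosen so u is the projection of world x (travel)
    onto the plane, keeping the plot frame axis-aligned with travel.
    """
    n = plane.normal
    u = np.array([1.0, 0.0, 0.0]) - n[0] * n
    u_norm = np.linalg.norm(u)
    if u_norm < 1e-9:  # plane perpendicular to travel; fall back to y
        u = np.array([0.0, 1.0, 0.0]) - n[1] * n
        u_norm = np.linalg.norm(u)
    u = u / u_norm
    v = np.cross(n, u)
    heights = plane.signed_distance(cloud.points)
    # origin: foot of the world origin on the plane
    foot = -plane.d * n
    rel = cloud.points - foot
    out = cloud.select(np.arange(len(cloud)))
    out.points = np.column_stack([rel @ u, rel @ v, heights])
    out.heights = heights
    return out


def cluster_denoise(
    plant_cloud: PointCloud,
    tolerance: float = 0.05,
    min_cluster_size: int = 30,
    plot_interval: tuple[float, float] | None = None,
    margin_frac: float = 0.1,
) -> tuple[PointCloud, dict]:
    """Remove detached clusters (weeds) by single-linkage Euclidean clustering.

    Connected components under inter-point distance <= ``tolerance`` are
    computed exactly (KD-tree radius graph; identical to naive all-pairs
    linkage).  The largest component is always kept; any other component is
    kept only if it has >= ``min_cluster_size`` points and, when
    ``plot_interval`` is given, its footprint centroid lies at least
    ``margin_frac * plot_width`` inside the plot's along-track interval.

    Returns the retained cloud and a stats dict with component labels.
    """
    n = len(plant_cloud)
    if n == 0:
        raise ValueError("empty cloud")
    tree = cKDTree(plant_cloud.points)
    pairs = tree.query_pairs(tolerance, output_type="ndarray")
    graph = sparse.coo_matrix(
        (np.ones(pairs.shape[0]), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = sparse.csgraph.connected_components(graph, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    largest = int(np.argmax(sizes))

    keep_labels = {largest}
    for c in range(n_comp):
        if c == largest or sizes[c] < min_cluster_size:
            continue
        if plot_interval is not None:
            x0, x1 = plot_interval
            margin = margin_frac * (x1 - x0)
            cx = float(np.mean(plant_cloud.x[labels == c]))
            if not (x0 + margin <= cx <= x1 - margin):
                continue
        keep_labels.add(c)

    keep = np.isin(labels, sorted(keep_labels))
    out = plant_cloud.select(keep)
    stats = {
        "n_components": int(n_comp),
        "n_kept_components": len(keep_labels),
        "n_removed_points": int(np.sum(~keep)),
        "labels": labels[keep],
    }
    if stats["n_removed_points"]:
        log.info(
            "cluster_denoise: removed %d points in %d detached clusters",
            stats["n_removed_points"],
            n_comp - len(keep_labels),
        )
    return out, stats
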