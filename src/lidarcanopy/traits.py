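"""Plot-level morphologic traits from a denoised, height-normalized cloud.

Three traits are extracted per plot and date:

* **Canopy height (CH)** — quantiles of point heights above the fitted
  ground plane (85th..100th percentile by default; the 100th is the apex).
* **Projected canopy area (PCA)** — area enclosed by the boundary of the
  points projected onto the ground plane, via an alpha-shape (concave hull)
  or an occupancy-grid cross-check, plus the axis-aligned bounding box.
* **Plant volume (PV)** — trapezoidal-rule integration: each line scan's
  cross-track height profile is integrated into an area, and the per-scan
  areas are integrated along the travel direction.

Clouds are expected in the ground-plane frame (``segment.normalize_to_plane``):
x along travel, y cross-track, z = height above the plane.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree

from .cloud import PointCloud

__all__ = [
    "TraitConfig",
    "TraitRecord",
    "ScanProfile",
    "AreaResult",
    "height_filter",
    "canopy_height",
    "projected_area",
    "scan_area",
    "plant_volume",
    "scans_from_cloud",
    "extract_traits",
]

log = logging.getLogger(__name__)

DEFAULT_PERCENTILES = (85.0, 88.0, 91.0, 94.0, 97.0, 100.0)


@dataclass(frozen=True)
class TraitConfig:
    """Trait-extraction parameters.

    ``z_min`` (m) removes residual near-ground returns before any trait is
    computed.  ``pca_method`` selects the boundary algorithm; alpha defaults
    to 5x the median nearest-neighbour spacing of the projected points.
    """

    z_min: float = 0.05
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES
    pca_method: str = "alpha_shape"
    alpha: float | None = None
    grid_cell: float = 0.02


@dataclass
class TraitRecord:
    """Per-plot, per-date trait values; None when the plot cloud was empty."""

    plot_id: str
    dap: float | None = None
    date: str | None = None
    n_points: int = 0
    ch_percentiles: dict[float, float] = field(default_factory=dict)
    max_ch: float | None = None
    pca: float | None = None
    bbox_length: float | None = None
    bbox_width: float | None = None
    pv: float | None = None

    def to_dict(self) -> dict:
        d = {
            "plot_id": self.plot_id,
            "dap": self.dap,
            "date": self.date,
            "n_points": self.n_points,
            "max_ch": self.max_ch,
            "pca": self.pca,
            "bbox_length": self.bbox_length,
            "bbox_width": self.bbox_width,
            "pv": self.pv,
        }
        for p, v in self.ch_percentiles.items():
            d[f"ch_p{p:g}"] = v
        return d


@dataclass
class ScanProfile:
    """One line scan's cross-track height profile at along-track position l."""

    l: float
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.float64).reshape(-1)
        self.z = np.asarray(self.z, dtype=np.float64).reshape(-1)
        if self.y.shape != self.z.shape:
            raise ValueError("y and z must have equal length")

    @property
    def area(self) -> float:
        return scan_area(self)


def height_filter(cloud: PointCloud, z_min: float = 0.05) -> PointCloud:
    """Drop points whose height above the ground plane is below ``z_min``."""
    if cloud.heights is None:
        raise ValueError("cloud has no heights; run ground removal first")
    return cloud.select(cloud.heights >= z_min)


def canopy_height(
    cloud: PointCloud | np.ndarray, percentiles=DEFAULT_PERCENTILES
) -> dict[float, float]:
    """Height-above-plane quantiles (linear interpolation between order stats).

    The 100th percentile equals the maximum height (canopy apex).
    """
    h = cloud.heights if isinstance(cloud, PointCloud) else np.asarray(cloud, dtype=np.float64)
    if h is None or h.size == 0:
        raise ValueError("empty cloud: canopy height undefined")
    qs = np.quantile(h, np.asarray(percentiles) / 100.0, method="linear")
    return {float(p): float(q) for p, q in zip(percentiles, qs)}


@dataclass
class AreaResult:
    pca: float
    bbox: tuple[float, float]  # (length along x, width along y)
    boundary: shapely.Geometry | None = None
    method: str = "alpha_shape"


def _alpha_shape_area(xy: np.ndarray, alpha: float) -> tuple[float, shapely.Geometry]:
    """Alpha-shape (circumradius-filtered Delaunay) area and boundary."""
    tri = Delaunay(xy)
    t = xy[tri.simplices]  # (m, 3, 2)
    a = t[:, 1] - t[:, 0]
    b = t[:, 2] - t[:, 0]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    area2 = np.abs(cross)
    la = np.linalg.norm(a, axis=1)
    lb = np.linalg.norm(b, axis=1)
    lc = np.linalg.norm(t[:, 2] - t[:, 1], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        circumradius = la * lb * lc / (2.0 * area2)
    keep = (area2 > 1e-15) & (circumradius <= alpha)
    if not np.any(keep):
        raise ValueError("alpha too small: no triangles retained")
    polys = shapely.polygons(t[keep])
    boundary = shapely.coverage_union_all(polys)
    return float(boundary.area), boundary


def projected_area(
    cloud: PointCloud | np.ndarray,
    method: str = "alpha_shape",
    alpha: float | None = None,
    grid_cell: float = 0.02,
) -> AreaResult:
    """Projected canopy area and bounding box from ground-plane projection.

    alpha_shape: concave hull built from Delaunay triangles with
    circumradius <= alpha (default 5x median nearest-neighbour spacing);
    area is the shoelace area of the resulting boundary.  grid: number of
    occupied cells x cell area (monotone in point-set inclusion).
    """
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, dtype=np.float64)
    xy = np.unique(pts[:, :2], axis=0)
    if xy.shape[0] < 3:
        raise ValueError("need at least 3 non-duplicate projected points")
    span = xy.max(axis=0) - xy.min(axis=0)
    bbox = (float(span[0]), float(span[1]))
    if np.linalg.matrix_rank(xy - xy.mean(axis=0), tol=1e-12) < 2:
        raise ValueError("degenerate projection: points are collinear")

    if method == "alpha_shape":
        if alpha is None:
            tree = cKDTree(xy)
            dist, _ = tree.query(xy, k=2)
            alpha = 5.0 * float(np.median(dist[:, 1]))
        area, boundary = _alpha_shape_area(xy, alpha)
        return AreaResult(pca=area, bbox=bbox, boundary=boundary, method=method)
    if method == "grid":
        ij = np.floor((xy - xy.min(axis=0)) / grid_cell).astype(np.int64)
        n_cells = np.unique(ij, axis=0).shape[0]
        return AreaResult(pca=float(n_cells) * grid_cell**2, bbox=bbox, boundary=None, method=method)
    raise ValueError(f"unknown method {method!r}; expected 'alpha_shape' or 'grid'")


def scan_area(scan: ScanProfile) -> float:
    """Area under one cross-track height profile by the trapezoidal rule.

    ``A = sum_j (y_{j+1} - y_j) * (z_{j+1} + z_j) / 2`` over consecutive
    samples; exact for piecewise-linear profiles sampled at their knots.
    Profiles with fewer than 2 samples have zero area.
    """
    if scan.y.size < 2:
        return 0.0
    dy = np.diff(scan.y)
    return float(np.sum(dy * (scan.z[1:] + scan.z[:-1]) / 2.0))


def plant_volume(scans: list[ScanProfile]) -> float:
    """Trapezoidal integration of per-scan areas along the travel direction.

    ``PV = sum_i (l_{i+1} - l_i) * (A_{i+1} + A_i) / 2`` with scans sorted by
    their along-track position l.
    """
    if len(scans) < 2:
        warnings.warn("plant_volume: fewer than 2 scans, volume is 0", stacklevel=2)
        return 0.0
    scans = sorted(scans, key=lambda s: s.l)
    l = np.array([s.l for s in scans])
    A = np.array([s.area for s in scans])
    return float(np.sum(np.diff(l) * (A[1:] + A[:-1]) / 2.0))


def scans_from_cloud(cloud: PointCloud) -> list[ScanProfile]:
    """Regroup a plot cloud into per-frame cross-track profiles.

    Points are grouped on frame_index; the scan position l is the frame's
    along-track coordinate and samples are ordered by beam sweep (beam_order,
    oriented so y increases), falling back to a y-sort when beam order is
    uninformative.
    """
    if cloud.heights is None:
        raise ValueError("cloud has no heights; run ground removal first")
    scans: list[ScanProfile] = []
    order = np.argsort(cloud.frame_index, kind="stable")
    fi = cloud.frame_index[order]
    boundaries = np.flatnonzero(np.diff(fi)) + 1
    for idx in np.split(order, boundaries):
        y = cloud.y[idx]
        z = cloud.heights[idx]
        bo = cloud.beam_order[idx]
        sub = np.argsort(bo, kind="stable")
        y, z = y[sub], z[sub]
        if y.size > 1 and y[0] > y[-1]:  # orient sweep toward increasing y
            y, z = y[::-1], z[::-1]
        scans.append(ScanProfile(l=float(np.median(cloud.x[idx])), y=y, z=z))
    return scans


def extract_traits(
    plot_cloud: PointCloud,
    cfg: TraitConfig = TraitConfig(),
    plot_id: str = "plot",
    dap: float | None = None,
    date: str | None = None,
) -> TraitRecord:
    """Compute all traits for one plot cloud (height filter applied first)."""
    rec = TraitRecord(plot_id=plot_id, dap=dap, date=date)
    if len(plot_cloud) == 0:
        return rec
    cloud = height_filter(plot_cloud, cfg.z_min)
    if len(cloud) == 0:
        warnings.warn(f"plot {plot_id}: no points above z_min={cfg.z_min}", stacklevel=2)
        return rec
    rec.n_points = len(cloud)
    rec.ch_percentiles = canopy_height(cloud, cfg.percentiles)
    rec.max_ch = float(np.max(cloud.heights))
    if len(cloud) >= 3:
        try:
            area = projected_area(cloud, cfg.pca_method, cfg.alpha, cfg.grid_cell)
            rec.pca = area.pca
            rec.bbox_length, rec.bbox_width = area.bbox
        except ValueError as e:
            warnings.warn(f"plot {plot_id}: projected area failed ({e})", stacklevel=2)
    scans = scans_from_cloud(cloud)
    rec.pv = plant_volume(scans) if len(scans) >= 2 else 0.0
    # sanity: quantiles monotone, area within bounding box
    qs = [rec.ch_percentiles[p] for p in sorted(rec.ch_percentiles)]
    assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
    if rec.pca is not None:
        assert rec.pca <= rec.bbox_length * rec.bbox_width + 1e-9
    return rec
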