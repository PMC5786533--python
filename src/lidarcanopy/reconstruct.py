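"""Fuse GPS and line-scan LiDAR streams into a georeferenced 3D point cloud.

The platform is assumed to move at constant speed within each GPS interval.
With ``alpha = f_lidar / f_gps`` frames per interval, the j-th frame after
fix i is placed at ``P_i + j * (P_{i+1} - P_i) / alpha + D_offset`` and its
beams are converted from polar (angle, range) to Cartesian under the
overhead scan-plane convention: theta = 90 deg is nadir, the point lies at
``(x, y + r cos(theta), z - r sin(theta))`` relative to the frame position.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .cloud import PointCloud

__all__ = [
    "GpsFix",
    "LidarFrame",
    "SensorConfig",
    "SyncResult",
    "synchronize",
    "frame_positions",
    "frame_to_points",
    "enclosure_filter",
    "reconstruct_cloud",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GpsFix:
    """One GPS fix: timestamp (s) and planar metric ENU position (m)."""

    t: float
    x: float
    y: float
    z: float


@dataclass
class LidarFrame:
    """One line scan: shared timestamp plus per-beam angle/range pairs.

    ``angles`` are degrees, strictly increasing; ``ranges`` are metres with a
    large sentinel value (the scanner's maximum range) marking no-hit beams.
    """

    t: float
    angles: np.ndarray
    ranges: np.ndarray
    index: int = 0

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=np.float64).reshape(-1)
        self.ranges = np.asarray(self.ranges, dtype=np.float64).reshape(-1)
        if self.angles.shape != self.ranges.shape:
            raise ValueError("angles and ranges must have equal length")
        if self.angles.size > 1 and not np.all(np.diff(self.angles) > 0):
            raise ValueError("beam angles must be strictly increasing")
        if np.any(self.ranges < 0):
            raise ValueError("ranges must be non-negative")

    @property
    def n_beams(self) -> int:
        return self.angles.size


@dataclass(frozen=True)
class SensorConfig:
    """Acquisition geometry shared by simulator and reconstruction.

    ``d_offset`` is the fixed LiDAR-to-GPS lever arm added to every frame
    position.  ``enclosure_range_bounds`` is the accepted raw-range interval
    of the distance filter; returns outside it (enclosure walls, no-hit
    sentinel) are discarded.  ``clock_offset`` is added to every frame
    timestamp before synchronization (the streams are otherwise assumed to
    share one clock).
    """

    f_gps: float = 5.0
    f_lidar: float = 50.0
    sensor_height: float = 2.4
    d_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    enclosure_range_bounds: tuple[float, float] = (0.5, 3.0)
    no_hit_range: float = 80.0
    clock_offset: float = 0.0

    def __post_init__(self):
        alpha = self.f_lidar / self.f_gps
        if alpha <= 0 or abs(alpha - round(alpha)) > 1e-9:
            raise ValueError(f"f_lidar/f_gps = {alpha} must be a positive integer")
        lo, hi = self.enclosure_range_bounds
        if not lo < hi:
            raise ValueError("enclosure_range_bounds must satisfy min < max")

    @property
    def alpha(self) -> int:
        return int(round(self.f_lidar / self.f_gps))


@dataclass
class SyncResult:
    """Frames paired with their containing GPS interval.

    ``interval[k]`` is the fix index i whose interval [t_i, t_{i+1}) contains
    frame k's timestamp; ``rank[k]`` is the frame's 0-based ordinal within
    that interval (the j of the interpolation formula).  Frames timestamped
    before the first fix are dropped; frames at or beyond the last fix are
    kept and flagged for velocity extrapolation.
    """

    frames: list[LidarFrame]
    interval: np.ndarray
    rank: np.ndarray
    n_dropped: int = 0
    n_extrapolated: int = 0


def _fix_times(gps: list[GpsFix]) -> np.ndarray:
    t = np.array([f.t for f in gps], dtype=np.float64)
    if t.size == 0:
        raise ValueError("empty GPS stream")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("GPS timestamps must be strictly increasing")
    return t


def synchronize(gps: list[GpsFix], frames: list[LidarFrame], cfg: SensorConfig | None = None) -> SyncResult:
    """Assign each frame to the GPS interval containing its timestamp.

    A frame timestamped exactly on a fix time belongs to the interval
    starting at that fix.  Raises if the two time spans do not overlap at
    all (every frame would be dropped).
    """
    if not frames:
        raise ValueError("empty LiDAR stream")
    t_fix = _fix_times(gps)
    offset = cfg.clock_offset if cfg is not None else 0.0
    t_frame = np.array([f.t for f in frames], dtype=np.float64) + offset
    if t_frame.size > 1 and not np.all(np.diff(t_frame) > 0):
        raise ValueError("frame timestamps must be strictly increasing")

    idx = np.searchsorted(t_fix, t_frame, side="right") - 1
    keep = idx >= 0
    n_dropped = int(np.sum(~keep))
    if not np.any(keep):
        raise ValueError("no time overlap between GPS and LiDAR streams")

    kept_frames = [f for f, k in zip(frames, keep) if k]
    idx = idx[keep]
    n_extrapolated = int(np.sum(t_frame[keep] > t_fix[-1]))
    if n_dropped:
        log.info("synchronize: dropped %d frames before first GPS fix", n_dropped)
    if n_extrapolated:
        log.info("synchronize: %d trailing frames beyond last GPS fix (extrapolated)", n_extrapolated)

    # rank within interval: 0-based ordinal among retained frames sharing i
    rank = np.zeros(idx.size, dtype=np.int64)
    start = 0
    for g in range(1, idx.size + 1):
        if g == idx.size or idx[g] != idx[start]:
            rank[start:g] = np.arange(g - start)
            start = g
    return SyncResult(kept_frames, idx, rank, n_dropped, n_extrapolated)


def frame_positions(gps: list[GpsFix], sync: SyncResult, cfg: SensorConfig) -> np.ndarray:
    """Per-frame 3D positions by constant-speed interpolation within intervals.

    Frame k assigned to interval i with rank j gets
    ``P_i + j * d_i + D_offset`` where ``d_i = (P_{i+1} - P_i) / alpha``.
    Trailing frames (interval = last fix) reuse the last interval's velocity.
    """
    _fix_times(gps)
    P = np.array([[f.x, f.y, f.z] for f in gps], dtype=np.float64)
    n = P.shape[0]
    alpha = cfg.alpha
    if n == 1:
        d = np.zeros((1, 3))
    else:
        d = np.empty((n, 3))
        d[:-1] = np.diff(P, axis=0) / alpha
        d[-1] = d[-2]  # extrapolate trailing frames at the last interval's velocity
    pos = P[sync.interval] + sync.rank[:, None] * d[sync.interval]
    return pos + np.asarray(cfg.d_offset, dtype=np.float64)


def frame_to_points(frame: LidarFrame, position, cfg: SensorConfig) -> PointCloud:
    """Convert one frame's polar beams to Cartesian points at its position.

    No-hit beams (range at or beyond the sentinel) are skipped; the raw range
    of each converted beam is kept on the cloud for later range filtering.
    """
    position = np.asarray(position, dtype=np.float64).reshape(3)
    hit = frame.ranges < cfg.no_hit_range - 1e-9
    r = frame.ranges[hit]
    theta = np.deg2rad(frame.angles[hit])
    pts = np.column_stack(
        [
            np.full(r.size, position[0]),
            position[1] + r * np.cos(theta),
            position[2] - r * np.sin(theta),
        ]
    )
    return PointCloud(
        points=pts,
        frame_index=np.full(r.size, frame.index, dtype=np.int64),
        beam_order=np.flatnonzero(hit).astype(np.int64),
        ranges=r.copy(),
    )


def enclosure_filter(cloud: PointCloud, bounds: tuple[float, float]) -> tuple[PointCloud, int]:
    """Drop points whose originating beam range lies outside [min, max]."""
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must satisfy min < max")
    if cloud.ranges is None:
        raise ValueError("cloud carries no per-point beam ranges")
    keep = (cloud.ranges >= lo) & (cloud.ranges <= hi)
    n_removed = int(np.sum(~keep))
    if n_removed:
        log.info("enclosure_filter: removed %d points outside range bounds %s", n_removed, bounds)
    return cloud.select(keep), n_removed


def reconstruct_cloud(
    gps: list[GpsFix],
    frames: list[LidarFrame],
    cfg: SensorConfig,
    apply_enclosure_filter: bool = True,
) -> tuple[PointCloud, dict]:
    """Full fusion: synchronize, interpolate frame positions, georeference beams.

    Returns the cloud plus a stats dict (frame/point counts, drops, filter
    removals) whose point-count bookkeeping is conservation-checked.
    """
    sync = synchronize(gps, frames, cfg)
    pos = frame_positions(gps, sync, cfg)
    parts = [frame_to_points(f, p, cfg) for f, p in zip(sync.frames, pos)]
    cloud = PointCloud.concat(parts)
    n_valid_beams = len(cloud)
    n_removed = 0
    if apply_enclosure_filter:
        cloud, n_removed = enclosure_filter(cloud, cfg.enclosure_range_bounds)
    stats = {
        "n_frames_in": len(frames),
        "n_frames_used": len(sync.frames),
        "n_frames_dropped": sync.n_dropped,
        "n_frames_extrapolated": sync.n_extrapolated,
        "n_valid_beams": n_valid_beams,
        "n_filtered": n_removed,
        "n_points": len(cloud),
    }
    assert stats["n_points"] == stats["n_valid_beams"] - stats["n_filtered"]
    return cloud, stats
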