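"""Seeded scan simulator: a constant-speed platform pass over analytic canopies.

The simulator emulates an overhead 2D line-scan LiDAR (vertical scan plane
perpendicular to travel) plus a GPS receiver on a shared clock.  Scenes are
built from parametric solids — hemisphere, ellipsoid cap, box, cone — resting
on a flat ground plane, optionally with detached "weed" blobs and enclosure
walls.  Every shape carries closed-form maximum height, footprint area and
volume, so a simulated pass doubles as a ground-truth oracle for the whole
downstream pipeline.

Geometry conventions (local ENU metres): x is the travel direction, y is
cross-track, z is up.  Beam angle theta is measured so that theta = 90 deg is
nadir; a beam of range r from sensor position p lands at
``(p_x, p_y + r cos(theta), p_z - r sin(theta))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely

from .reconstruct import GpsFix, LidarFrame

__all__ = [
    "CanopyShape",
    "Hemisphere",
    "EllipsoidCap",
    "BoxCanopy",
    "ConeCanopy",
    "WeedBlob",
    "Scene",
    "ShapeTruth",
    "GroundTruth",
    "PassConfig",
    "build_scene",
    "cast_beam",
    "simulate_pass",
]

_EPS = 1e-9


def _pick_root(t1: np.ndarray, t2: np.ndarray, valid1: np.ndarray, valid2: np.ndarray) -> np.ndarray:
    """Smallest positive valid root of a per-ray quadratic, +inf when none."""
    t1 = np.where(valid1 & (t1 > _EPS), t1, np.inf)
    t2 = np.where(valid2 & (t2 > _EPS), t2, np.inf)
    return np.minimum(t1, t2)


# ---------------------------------------------------------------------------
# Analytic shapes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CanopyShape:
    """Base class: an analytic solid resting on the ground plane."""

    center_x: float
    center_y: float

    kind = "abstract"

    # closed-form ground truth -----------------------------------------
    @property
    def max_height(self) -> float:
        raise NotImplementedError

    @property
    def footprint_area(self) -> float:
        raise NotImplementedError

    @property
    def volume(self) -> float:
        raise NotImplementedError

    def footprint_polygon(self) -> shapely.Geometry:
        raise NotImplementedError

    def intersect(self, origin: np.ndarray, dirs: np.ndarray, ground_z: float) -> np.ndarray:
        """Per-ray distance to the nearest surface intersection (+inf = miss)."""
        raise NotImplementedError


@dataclass(frozen=True)
class Hemisphere(CanopyShape):
    radius: float = 1.0
    kind = "hemisphere"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("hemisphere radius must be positive")

    @property
    def max_height(self) -> float:
        return self.radius

    @property
    def footprint_area(self) -> float:
        return math.pi * self.radius**2

    @property
    def volume(self) -> float:
        return 2.0 / 3.0 * math.pi * self.radius**3

    def footprint_polygon(self) -> shapely.Geometry:
        return shapely.Point(self.center_x, self.center_y).buffer(self.radius, quad_segs=64)

    def intersect(self, origin, dirs, ground_z):
        c = np.array([self.center_x, self.center_y, ground_z])
        oc = origin - c
        b = dirs @ oc
        c0 = oc @ oc - self.radius**2
        disc = b * b - c0
        ok = disc >= 0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        t1, t2 = -b - sq, -b + sq
        z1 = origin[2] + t1 * dirs[:, 2]
        z2 = origin[2] + t2 * dirs[:, 2]
        return _pick_root(t1, t2, ok & (z1 >= ground_z - 1e-12), ok & (z2 >= ground_z - 1e-12))


@dataclass(frozen=True)
class EllipsoidCap(CanopyShape):
    """Upper half of an ellipsoid with semi-axes (a, b, c); height c."""

    a: float = 1.0
    b: float = 1.0
    c: float = 1.0
    kind = "ellipsoid-cap"

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("ellipsoid semi-axes must be positive")

    @property
    def max_height(self) -> float:
        return self.c

    @property
    def footprint_area(self) -> float:
        return math.pi * self.a * self.b

    @property
    def volume(self) -> float:
        return 2.0 / 3.0 * math.pi * self.a * self.b * self.c

    def footprint_polygon(self) -> shapely.Geometry:
        circ = shapely.Point(self.center_x, self.center_y).buffer(1.0, quad_segs=64)
        return _scale_xy(circ, self)

    def intersect(self, origin, dirs, ground_z):
        scale = np.array([self.a, self.b, self.c])
        o = (origin - np.array([self.center_x, self.center_y, ground_z])) / scale
        d = dirs / scale
        A = np.einsum("ij,ij->i", d, d)
        B = d @ o
        C = o @ o - 1.0
        disc = B * B - A * C
        ok = disc >= 0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        t1 = (-B - sq) / A
        t2 = (-B + sq) / A
        z1 = origin[2] + t1 * dirs[:, 2]
        z2 = origin[2] + t2 * dirs[:, 2]
        return _pick_root(t1, t2, ok & (z1 >= ground_z - 1e-12), ok & (z2 >= ground_z - 1e-12))


def _scale_xy(geom, shape: "EllipsoidCap"):
    from shapely import affinity

    return affinity.scale(geom, xfact=shape.a, yfact=shape.b, origin=(shape.center_x, shape.center_y))


@dataclass(frozen=True)
class BoxCanopy(CanopyShape):
    """Axis-aligned box: length along x, width along y, height along z."""

    length: float = 1.0
    width: float = 1.0
    height: float = 1.0
    kind = "box"

    def __post_init__(self):
        if min(self.length, self.width, self.height) <= 0:
            raise ValueError("box dimensions must be positive")

    @property
    def max_height(self) -> float:
        return self.height

    @property
    def footprint_area(self) -> float:
        return self.length * self.width

    @property
    def volume(self) -> float:
        return self.length * self.width * self.height

    def footprint_polygon(self) -> shapely.Geometry:
        return shapely.box(
            self.center_x - self.length / 2,
            self.center_y - self.width / 2,
            self.center_x + self.length / 2,
            self.center_y + self.width / 2,
        )

    def intersect(self, origin, dirs, ground_z):
        lo = np.array([self.center_x - self.length / 2, self.center_y - self.width / 2, ground_z])
        hi = np.array([self.center_x + self.length / 2, self.center_y + self.width / 2, ground_z + self.height])
        n = dirs.shape[0]
        tmin = np.full(n, -np.inf)
        tmax = np.full(n, np.inf)
        hit = np.ones(n, dtype=bool)
        for ax in range(3):
            d = dirs[:, ax]
            o = origin[ax]
            par = np.abs(d) < 1e-15
            inside = (o >= lo[ax]) & (o <= hi[ax])
            hit &= ~par | inside
            with np.errstate(divide="ignore", invalid="ignore"):
                ta = (lo[ax] - o) / d
                tb = (hi[ax] - o) / d
            t_lo = np.minimum(ta, tb)
            t_hi = np.maximum(ta, tb)
            tmin = np.where(par, tmin, np.maximum(tmin, t_lo))
            tmax = np.where(par, tmax, np.minimum(tmax, t_hi))
        hit &= (tmax >= tmin) & (tmax > _EPS)
        t = np.where(tmin > _EPS, tmin, tmax)  # origin inside -> exit face
        return np.where(hit & (t > _EPS), t, np.inf)


@dataclass(frozen=True)
class ConeCanopy(CanopyShape):
    """Right circular cone, apex up, base resting on the ground."""

    radius: float = 1.0
    height: float = 1.0
    kind = "cone"

    def __post_init__(self):
        if min(self.radius, self.height) <= 0:
            raise ValueError("cone dimensions must be positive")

    @property
    def max_height(self) -> float:
        return self.height

    @property
    def footprint_area(self) -> float:
        return math.pi * self.radius**2

    @property
    def volume(self) -> float:
        return math.pi * self.radius**2 * self.height / 3.0

    def footprint_polygon(self) -> shapely.Geometry:
        return shapely.Point(self.center_x, self.center_y).buffer(self.radius, quad_segs=64)

    def intersect(self, origin, dirs, ground_z):
        k2 = (self.radius / self.height) ** 2
        apex = np.array([self.center_x, self.center_y, ground_z + self.height])
        w = origin - apex
        A = dirs[:, 0] ** 2 + dirs[:, 1] ** 2 - k2 * dirs[:, 2] ** 2
        B = w[0] * dirs[:, 0] + w[1] * dirs[:, 1] - k2 * w[2] * dirs[:, 2]
        C = w[0] ** 2 + w[1] ** 2 - k2 * w[2] ** 2
        disc = B * B - A * C
        ok = (disc >= 0) & (np.abs(A) > 1e-15)
        sq = np.sqrt(np.where(ok, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (-B - sq) / A
            t2 = (-B + sq) / A

        def _valid(t):
            z = origin[2] + t * dirs[:, 2]
            return ok & (z >= ground_z - 1e-12) & (z <= ground_z + self.height + 1e-12)

        return _pick_root(t1, t2, _valid(t1), _valid(t2))


_SHAPE_KINDS = {
    "hemisphere": Hemisphere,
    "ellipsoid-cap": EllipsoidCap,
    "box": BoxCanopy,
    "cone": ConeCanopy,
}


@dataclass(frozen=True)
class WeedBlob:
    """Small detached blob, modelled as a sphere resting on the ground."""

    center_x: float
    center_y: float
    radius: float = 0.08
    n_points: int = 60

    def footprint_polygon(self) -> shapely.Geometry:
        return shapely.Point(self.center_x, self.center_y).buffer(self.radius, quad_segs=32)

    def intersect(self, origin, dirs, ground_z):
        c = np.array([self.center_x, self.center_y, ground_z + self.radius])
        oc = origin - c
        b = dirs @ oc
        c0 = oc @ oc - self.radius**2
        disc = b * b - c0
        ok = disc >= 0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        return _pick_root(-b - sq, -b + sq, ok, ok)


# ---------------------------------------------------------------------------
# Scene and ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShapeTruth:
    kind: str
    center_x: float
    center_y: float
    max_height: float
    footprint_area: float
    volume: float


@dataclass
class GroundTruth:
    """Closed-form trait values per shape, plus the platform trajectory."""

    shapes: list[ShapeTruth] = field(default_factory=list)
    trajectory: np.ndarray | None = None  # (N, 3) GPS fix positions


@dataclass
class Scene:
    ground_z: float = 0.0
    shapes: list[CanopyShape] = field(default_factory=list)
    weeds: list[WeedBlob] = field(default_factory=list)
    enclosure_halfwidth: float | None = None
    truth: GroundTruth = field(default_factory=GroundTruth)

    @property
    def max_height(self) -> float:
        hs = [s.max_height for s in self.shapes] + [2 * w.radius for w in self.weeds]
        return max(hs, default=0.0)

    def cast(self, origin: np.ndarray, dirs: np.ndarray, max_range: float = 80.0) -> np.ndarray:
        """Nearest-intersection range per ray; +inf where nothing is hit in range."""
        origin = np.asarray(origin, dtype=np.float64).reshape(3)
        dirs = np.asarray(dirs, dtype=np.float64).reshape(-1, 3)
        t = np.full(dirs.shape[0], np.inf)
        # ground plane z = ground_z
        dz = dirs[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            tg = (self.ground_z - origin[2]) / dz
        t = np.minimum(t, np.where((dz < 0) & (tg > _EPS), tg, np.inf))
        for obj in [*self.shapes, *self.weeds]:
            t = np.minimum(t, obj.intersect(origin, dirs, self.ground_z))
        if self.enclosure_halfwidth is not None:
            for wy in (-self.enclosure_halfwidth, self.enclosure_halfwidth):
                dy = dirs[:, 1]
                with np.errstate(divide="ignore", invalid="ignore"):
                    tw = (wy - origin[1]) / dy
                zw = origin[2] + tw * dirs[:, 2]
                t = np.minimum(t, np.where((np.abs(dy) > 1e-15) & (tw > _EPS) & (zw >= self.ground_z), tw, np.inf))
        return np.where(t <= max_range, t, np.inf)


def build_scene(
    shapes: list[CanopyShape | dict] | None = None,
    weeds: list[WeedBlob | dict] | None = None,
    ground_z: float = 0.0,
    enclosure_halfwidth: float | None = None,
) -> Scene:
    """Validate shapes/weeds and assemble a Scene with closed-form ground truth.

    Shape dicts use ``{"kind": ..., "center": [x, y], **dims}`` (see
    ``_SHAPE_KINDS`` for per-kind dimension names).  Overlapping shape
    footprints, or weeds intersecting a shape footprint, are rejected.
    """
    built: list[CanopyShape] = []
    for s in shapes or []:
        if isinstance(s, dict):
            s = dict(s)
            kind = s.pop("kind")
            if kind not in _SHAPE_KINDS:
                raise ValueError(f"unknown shape kind {kind!r}; expected one of {sorted(_SHAPE_KINDS)}")
            cx, cy = s.pop("center", (0.0, 0.0))
            s = _SHAPE_KINDS[kind](center_x=float(cx), center_y=float(cy), **s)
        built.append(s)
    built_weeds: list[WeedBlob] = []
    for w in weeds or []:
        if isinstance(w, dict):
            w = dict(w)
            cx, cy = w.pop("center", (0.0, 0.0))
            w = WeedBlob(center_x=float(cx), center_y=float(cy), **w)
        built_weeds.append(w)

    polys = [s.footprint_polygon() for s in built]
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            if polys[i].intersection(polys[j]).area > 1e-12:
                raise ValueError(
                    f"shape footprints overlap: #{i} ({built[i].kind}) and #{j} ({built[j].kind})"
                )
    for k, w in enumerate(built_weeds):
        wp = w.footprint_polygon()
        for i, p in enumerate(polys):
            if wp.intersection(p).area > 1e-12:
                raise ValueError(f"weed #{k} intersects footprint of shape #{i} ({built[i].kind})")

    truth = GroundTruth(
        shapes=[
            ShapeTruth(s.kind, s.center_x, s.center_y, s.max_height, s.footprint_area, s.volume)
            for s in built
        ]
    )
    return Scene(
        ground_z=ground_z,
        shapes=built,
        weeds=built_weeds,
        enclosure_halfwidth=enclosure_halfwidth,
        truth=truth,
    )


def cast_beam(scene: Scene, origin, direction, max_range: float = 80.0) -> float:
    """Single-ray convenience wrapper; returns +inf for a no-hit."""
    direction = np.asarray(direction, dtype=np.float64).reshape(3)
    n = np.linalg.norm(direction)
    if not math.isclose(n, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("direction must be a unit vector")
    return float(scene.cast(origin, direction[None, :], max_range)[0])


# ---------------------------------------------------------------------------
# Pass simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PassConfig:
    """Platform and sensor configuration for one scanning pass.

    Defaults reproduce the field protocol the package targets: a platform at
    about 0.5 m/s, GPS at 5 Hz, a 50 Hz line scanner with a 190 deg aperture
    at 1/3 deg resolution mounted 2.4 m above the ground, scanning from
    directly above.
    """

    speed: float = 0.5           # m/s
    f_gps: float = 5.0           # Hz
    f_lidar: float = 50.0        # Hz
    aperture_deg: float = 190.0
    resolution_deg: float = 1.0 / 3.0
    sensor_height: float = 2.4   # m above ground
    range_noise_sd: float = 0.005  # m, 1-sigma additive range noise
    max_range: float = 80.0      # no-hit sentinel range
    seed: int = 0

    def __post_init__(self):
        if self.speed <= 0 or self.f_gps <= 0 or self.f_lidar <= 0:
            raise ValueError("speed and rates must be positive")
        alpha = self.f_lidar / self.f_gps
        if abs(alpha - round(alpha)) > 1e-9:
            raise ValueError(f"f_lidar/f_gps = {alpha} must be an integer")
        nb = self.aperture_deg / self.resolution_deg
        if abs(nb - round(nb)) > 1e-6:
            raise ValueError(
                f"aperture/resolution = {nb} must be an integer number of beam steps"
            )

    @property
    def alpha(self) -> int:
        return int(round(self.f_lidar / self.f_gps))

    @property
    def n_beams(self) -> int:
        return int(round(self.aperture_deg / self.resolution_deg)) + 1

    @property
    def beam_angles_deg(self) -> np.ndarray:
        """Beam angles; 90 deg is nadir, spanning aperture symmetrically."""
        start = 90.0 - self.aperture_deg / 2.0
        return start + self.resolution_deg * np.arange(self.n_beams)


def simulate_pass(
    scene: Scene,
    cfg: PassConfig,
    path: tuple[float, float, float] = (0.0, 10.0, 0.0),
) -> tuple[list[GpsFix], list[LidarFrame], GroundTruth]:
    """Simulate one straight pass; returns GPS fixes, LiDAR frames and truth.

    ``path = (x_start, x_end, y)``: the platform travels parallel to the x
    axis at constant speed with the sensor at ``ground_z + sensor_height``.
    GPS fixes are exact platform positions; LiDAR ranges get i.i.d. Gaussian
    noise (sd ``cfg.range_noise_sd``) from a generator seeded with
    ``cfg.seed``, so identical configs give bit-identical streams.  No-hit
    beams carry the sentinel range ``cfg.max_range``.
    """
    x_start, x_end, y0 = path
    length = abs(x_end - x_start)
    if length <= 0:
        raise ValueError("zero-length path")
    if cfg.sensor_height <= scene.max_height:
        raise ValueError(
            f"sensor height {cfg.sensor_height} must exceed tallest scene object {scene.max_height}"
        )
    direction = 1.0 if x_end > x_start else -1.0
    duration = length / cfg.speed
    z0 = scene.ground_z + cfg.sensor_height

    n_fix = int(math.floor(duration * cfg.f_gps + 1e-9)) + 1
    t_fix = np.arange(n_fix) / cfg.f_gps
    fixes = [
        GpsFix(t=float(t), x=float(x_start + direction * cfg.speed * t), y=float(y0), z=float(z0))
        for t in t_fix
    ]

    theta = np.deg2rad(cfg.beam_angles_deg)
    dirs = np.column_stack([np.zeros_like(theta), np.cos(theta), -np.sin(theta)])

    rng = np.random.default_rng(cfg.seed)
    n_frames = int(math.floor(duration * cfg.f_lidar + 1e-9)) + 1
    frames: list[LidarFrame] = []
    for k in range(n_frames):
        t = k / cfg.f_lidar
        origin = np.array([x_start + direction * cfg.speed * t, y0, z0])
        r = scene.cast(origin, dirs, cfg.max_range)
        hit = np.isfinite(r)
        if cfg.range_noise_sd > 0:
            noise = rng.normal(0.0, cfg.range_noise_sd, size=r.shape)
            r = np.where(hit, r + noise, r)
        r = np.where(hit, r, cfg.max_range)
        frames.append(LidarFrame(t=float(t), angles=cfg.beam_angles_deg.copy(), ranges=r, index=k))

    truth = GroundTruth(shapes=list(scene.truth.shapes), trajectory=np.array([[f.x, f.y, f.z] for f in fixes]))
    return fixes, frames, truth
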