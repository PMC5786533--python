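"""File formats and run configuration.

Interchange between pipeline stages is file-based: GPS and frame streams as
pinned CSV dialects (comma separator, '.' decimal, LF endings, 9 significant
digits), point clouds as PLY / PCD / CSV with frame_index and beam_order
carried as extra per-vertex channels, and a YAML run configuration validated
against the documented schema before any stage runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cloud import PointCloud
from .reconstruct import GpsFix, LidarFrame, SensorConfig
from .segment import PlotLayout
from .traits import TraitConfig

__all__ = [
    "read_gps_csv",
    "write_gps_csv",
    "read_frames_csv",
    "write_frames_csv",
    "read_cloud",
    "write_cloud",
    "SegmentParams",
    "RunConfig",
    "load_config",
]

_FLOAT_FMT = "%.9g"


# ---------------------------------------------------------------------------
# GPS / frame CSV streams
# ---------------------------------------------------------------------------


def write_gps_csv(path, fixes: list[GpsFix]) -> None:
    df = pd.DataFrame([(f.t, f.x, f.y, f.z) for f in fixes], columns=["t", "x", "y", "z"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_gps_csv(path) -> list[GpsFix]:
    df = pd.read_csv(path)
    missing = {"t", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    t = df["t"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ValueError(f"{path}: timestamps not strictly increasing at row {int(bad[0]) + 1}")
    return [GpsFix(*row) for row in df[["t", "x", "y", "z"]].itertuples(index=False)]


def write_frames_csv(path, frames: list[LidarFrame]) -> None:
    """Long format: one row per beam (t, frame_id, angle_deg, range_m)."""
    parts = [
        pd.DataFrame(
            {
                "t": np.full(f.n_beams, f.t),
                "frame_id": np.full(f.n_beams, f.index, dtype=np.int64),
                "angle_deg": f.angles,
                "range_m": f.ranges,
            }
        )
        for f in frames
    ]
    df = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["t", "frame_id", "angle_deg", "range_m"]
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_frames_csv(path) -> list[LidarFrame]:
    df = pd.read_csv(path)
    missing = {"t", "frame_id", "angle_deg", "range_m"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if np.any(df["range_m"].to_numpy(dtype=float) < 0):
        raise ValueError(f"{path}: negative range")
    frames = []
    for fid, g in df.groupby("frame_id", sort=True):
        g = g.sort_values("angle_deg")
        frames.append(
            LidarFrame(
                t=float(g["t"].iloc[0]),
                angles=g["angle_deg"].to_numpy(dtype=float),
                ranges=g["range_m"].to_numpy(dtype=float),
                index=int(fid),
            )
        )
    counts = {f.n_beams for f in frames}
    if len(counts) > 1:
        import logging

        logging.getLogger(__name__).warning(
            "%s: inconsistent beam counts across frames: %s", path, sorted(counts)
        )
    return frames


# ---------------------------------------------------------------------------
# Point clouds: CSV / PLY / PCD
# ---------------------------------------------------------------------------

_CLOUD_COLUMNS = ["x", "y", "z", "frame_index", "beam_order", "range_m", "height"]


def _cloud_frame(cloud: PointCloud) -> pd.DataFrame:
    d = {
        "x": cloud.x,
        "y": cloud.y,
        "z": cloud.z,
        "frame_index": cloud.frame_index,
        "beam_order": cloud.beam_order,
    }
    if cloud.ranges is not None:
        d["range_m"] = cloud.ranges
    if cloud.heights is not None:
        d["height"] = cloud.heights
    return pd.DataFrame(d)


def _cloud_from_frame(df: pd.DataFrame) -> PointCloud:
    return PointCloud(
        points=df[["x", "y", "z"]].to_numpy(dtype=float),
        frame_index=df["frame_index"].to_numpy(dtype=np.int64),
        beam_order=df["beam_order"].to_numpy(dtype=np.int64),
        ranges=df["range_m"].to_numpy(dtype=float) if "range_m" in df else None,
        heights=df["height"].to_numpy(dtype=float) if "height" in df else None,
    )


_PLY_TYPES = {"double": "<f8", "float": "<f4", "int": "<i4", "uint": "<u4", "uchar": "<u1", "short": "<i2", "ushort": "<u2"}


def write_cloud(path, cloud: PointCloud, format: str | None = None, binary: bool = True) -> None:
    """Write a cloud as PLY, PCD or CSV (format inferred from the suffix).

    PLY/PCD default to little-endian binary; ``binary=False`` selects ASCII.
    frame_index and beam_order (and range/height when present) are stored as
    extra per-vertex properties and survive a round-trip.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    df = _cloud_frame(cloud)
    if fmt == "csv":
        df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
        return
    if fmt == "ply":
        _write_ply(path, df, binary)
        return
    if fmt == "pcd":
        _write_pcd(path, df, binary)
        return
    raise ValueError(f"unknown cloud format {fmt!r}; expected ply, pcd or csv")


def read_cloud(path, format: str | None = None) -> PointCloud:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return _cloud_from_frame(pd.read_csv(path))
    if fmt == "ply":
        return _cloud_from_frame(_read_ply(path))
    if fmt == "pcd":
        return _cloud_from_frame(_read_pcd(path))
    raise ValueError(f"unknown cloud format {fmt!r}; expected ply, pcd or csv")


def _ply_schema(df: pd.DataFrame) -> list[tuple[str, str]]:
    schema = []
    for col in df.columns:
        ply_t = "int" if col in ("frame_index", "beam_order") else "double"
        schema.append((col, ply_t))
    return schema


def _write_ply(path: Path, df: pd.DataFrame, binary: bool) -> None:
    schema = _ply_schema(df)
    header = ["ply", f"format {'binary_little_endian' if binary else 'ascii'} 1.0"]
    header.append(f"element vertex {len(df)}")
    header += [f"property {t} {name}" for name, t in schema]
    header.append("end_header")
    dtype = np.dtype([(name, _PLY_TYPES[t]) for name, t in schema])
    rec = np.empty(len(df), dtype=dtype)
    for name, t in schema:
        rec[name] = df[name].to_numpy()
    if binary:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            fh.write(rec.tobytes())
    else:
        with open(path, "w", newline="\n") as fh:
            fh.write("\n".join(header) + "\n")
            for row in rec:
                fh.write(" ".join("%.17g" % row[name] if t == "double" else str(int(row[name])) for name, t in schema) + "\n")


def _read_ply(path: Path) -> pd.DataFrame:
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise ValueError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated PLY header")
            tok = line.decode("ascii").split()
            if not tok:
                continue
            if tok[0] == "format":
                fmt = tok[1]
            elif tok[0] == "element":
                in_vertex = tok[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tok[2])
            elif tok[0] == "property" and in_vertex:
                if tok[1] == "list":
                    raise ValueError(f"{path}: list properties not supported")
                props.append((tok[2], tok[1]))
            elif tok[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian") or n_vertex is None:
            raise ValueError(f"{path}: unsupported PLY format {fmt}")
        dtype = np.dtype([(name, _PLY_TYPES[t]) for name, t in props])
        if fmt == "binary_little_endian":
            rec = np.frombuffer(fh.read(n_vertex * dtype.itemsize), dtype=dtype, count=n_vertex)
        else:
            rec = np.loadtxt(fh, dtype=dtype, max_rows=n_vertex, ndmin=1)
    return pd.DataFrame({name: rec[name] for name, _ in props})


def _write_pcd(path: Path, df: pd.DataFrame, binary: bool) -> None:
    fields = list(df.columns)
    types = ["I" if c in ("frame_index", "beam_order") else "F" for c in fields]
    sizes = ["4" if t == "I" else "8" for t in types]
    header = [
        "# .PCD v0.7 - Point Cloud Data file format",
        "VERSION 0.7",
        "FIELDS " + " ".join(fields),
        "SIZE " + " ".join(sizes),
        "TYPE " + " ".join(types),
        "COUNT " + " ".join(["1"] * len(fields)),
        f"WIDTH {len(df)}",
        "HEIGHT 1",
        "VIEWPOINT 0 0 0 1 0 0 0",
        f"POINTS {len(df)}",
        f"DATA {'binary' if binary else 'ascii'}",
    ]
    dtype = np.dtype([(c, "<i4" if t == "I" else "<f8") for c, t in zip(fields, types)])
    rec = np.empty(len(df), dtype=dtype)
    for c in fields:
        rec[c] = df[c].to_numpy()
    if binary:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            fh.write(rec.tobytes())
    else:
        with open(path, "w", newline="\n") as fh:
            fh.write("\n".join(header) + "\n")
            for row in rec:
                fh.write(" ".join(str(int(row[c])) if t == "I" else "%.17g" % row[c] for c, t in zip(fields, types)) + "\n")


def _read_pcd(path: Path) -> pd.DataFrame:
    with open(path, "rb") as fh:
        meta: dict[str, list[str]] = {}
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated PCD header")
            if line.startswith(b"#"):
                continue
            tok = line.decode("ascii").split()
            meta[tok[0]] = tok[1:]
            if tok[0] == "DATA":
                break
        fields = meta["FIELDS"]
        types = meta["TYPE"]
        sizes = meta["SIZE"]
        n = int(meta["POINTS"][0])
        np_types = {("F", "8"): "<f8", ("F", "4"): "<f4", ("I", "4"): "<i4", ("U", "4"): "<u4"}
        dtype = np.dtype([(f, np_types[(t, s)]) for f, t, s in zip(fields, types, sizes)])
        mode = meta["DATA"][0]
        if mode == "binary":
            rec = np.frombuffer(fh.read(n * dtype.itemsize), dtype=dtype, count=n)
        elif mode == "ascii":
            rec = np.loadtxt(fh, dtype=dtype, max_rows=n, ndmin=1)
        else:
            raise ValueError(f"{path}: unsupported PCD data mode {mode}")
    return pd.DataFrame({f: rec[f] for f in fields})


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentParams:
    ransac_dist_threshold: float = 0.03
    ransac_n_iter: int = 1000
    cluster_tolerance: float = 0.05
    min_cluster_size: int = 30
    margin_frac: float = 0.1

    def __post_init__(self):
        if self.ransac_dist_threshold <= 0 or self.cluster_tolerance <= 0:
            raise ValueError("thresholds must be positive")
        if self.ransac_n_iter < 1 or self.min_cluster_size < 1:
            raise ValueError("iteration/size counts must be >= 1")


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run (see docs for the schema)."""

    scene: dict = field(default_factory=dict)
    pass_: dict = field(default_factory=dict)
    sensor: SensorConfig = field(default_factory=SensorConfig)
    layout: PlotLayout = field(default_factory=PlotLayout)
    segmentation: SegmentParams = field(default_factory=SegmentParams)
    traits: TraitConfig = field(default_factory=TraitConfig)
    growth: dict = field(default_factory=dict)
    seed: int = 0
    plots: list[tuple[int, int]] = field(default_factory=list)  # (row, col) to extract


_KNOWN_SECTIONS = {"scene", "pass", "sensor", "layout", "segmentation", "traits", "growth", "seed", "plots"}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"{path}: unknown config sections {sorted(unknown)}")

    def _build(cls, section):
        data = raw.get(section) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: section {section!r} must be a mapping")
        try:
            return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in data.items()})
        except TypeError as e:
            raise ValueError(f"{path}: bad keys in section {section!r}: {e}") from e

    cfg = RunConfig(
        scene=raw.get("scene") or {},
        pass_=raw.get("pass") or {},
        sensor=_build(SensorConfig, "sensor"),
        layout=_build(PlotLayout, "layout"),
        segmentation=_build(SegmentParams, "segmentation"),
        traits=_build(TraitConfig, "traits"),
        growth=raw.get("growth") or {},
        seed=int(raw.get("seed", 0)),
        plots=[tuple(p) for p in raw.get("plots") or []],
    )
    for p in cfg.plots:
        if len(p) != 2:
            raise ValueError(f"{path}: plots entries must be [row, col] pairs")
    return cfg
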