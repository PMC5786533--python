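"""Georeferenced point-cloud container shared by all pipeline stages.

A :class:`PointCloud` stores, for every point, the index of the line-scan
frame it came from and its beam position within that frame.  Both are needed
downstream: the volume integrator regroups points into per-frame cross-track
profiles, and the enclosure filter works on the raw beam range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PointCloud"]


@dataclass
class PointCloud:
    """N points in a local ENU metric frame (x = travel, y = cross-track, z = up).

    Parameters
    ----------
    points : (N, 3) float array
    frame_index : (N,) int array
        Ordinal of the originating LiDAR frame; non-decreasing in storage order.
    beam_order : (N,) int array
        Beam position within the frame; increasing within a frame.
    ranges : (N,) float array, optional
        Raw beam range in metres (kept so the enclosure filter can run after
        georeferencing).
    heights : (N,) float array, optional
        Height above the fitted ground plane, attached by ground removal.
    """

    points: np.ndarray
    frame_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    beam_order: np.ndarray = field(default=None)  # type: ignore[assignment]
    ranges: np.ndarray | None = None
    heights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        n = self.points.shape[0]
        if self.frame_index is None:
            self.frame_index = np.zeros(n, dtype=np.int64)
        if self.beam_order is None:
            self.beam_order = np.arange(n, dtype=np.int64)
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64).reshape(-1)
        self.beam_order = np.asarray(self.beam_order, dtype=np.int64).reshape(-1)
        for name in ("frame_index", "beam_order"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length {getattr(self, name).shape[0]} != {n} points")
        for name in ("ranges", "heights"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.float64).reshape(-1)
                if arr.shape[0] != n:
                    raise ValueError(f"{name} length {arr.shape[0]} != {n} points")
                setattr(self, name, arr)

    # -- basic protocol ------------------------------------------------

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    # -- construction helpers ------------------------------------------

    @classmethod
    def empty(cls, with_ranges: bool = False, with_heights: bool = False) -> "PointCloud":
        z = np.zeros(0)
        return cls(
            points=np.zeros((0, 3)),
            frame_index=np.zeros(0, dtype=np.int64),
            beam_order=np.zeros(0, dtype=np.int64),
            ranges=z.copy() if with_ranges else None,
            heights=z.copy() if with_heights else None,
        )

    @classmethod
    def concat(cls, clouds: list["PointCloud"]) -> "PointCloud":
        if not clouds:
            return cls.empty()

        def _cat(name: str):
            arrs = [getattr(c, name) for c in clouds]
            if any(a is None for a in arrs):
                return None
            return np.concatenate(arrs)

        return cls(
            points=np.concatenate([c.points for c in clouds]),
            frame_index=np.concatenate([c.frame_index for c in clouds]),
            beam_order=np.concatenate([c.beam_order for c in clouds]),
            ranges=_cat("ranges"),
            heights=_cat("heights"),
        )

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Subset by boolean mask or integer index array (metadata preserved)."""
        mask = np.asarray(mask)
        return PointCloud(
            points=self.points[mask],
            frame_index=self.frame_index[mask],
            beam_order=self.beam_order[mask],
            ranges=None if self.ranges is None else self.ranges[mask],
            heights=None if self.heights is None else self.heights[mask],
        )

    def translated(self, v) -> "PointCloud":
        v = np.asarray(v, dtype=np.float64).reshape(3)
        out = self.select(np.arange(len(self)))
        out.points = out.points + v
        return out
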