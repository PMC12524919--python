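"""Shared geometric primitives: HU volumes, vessel centerlines, landmark sets.

World coordinates are millimetres.  Voxel indices are 0-based and the grid
origin sits at the centre of voxel (0, 0, 0); the voxel-to-world map is an
axis-aligned scaling (no oblique acquisition geometry is supported).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["CTVolume", "Centerline", "CenterlineSet", "LandmarkSet"]


@dataclass
class CTVolume:
    """A 3-D CT grid in Hounsfield units with axis-aligned voxel spacing (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("CT volume must be a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive along every axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CT volume contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to world mm coordinates of voxel centres."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Inclusive world-coordinate bounds of voxel centres (lo, hi)."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi


@dataclass
class Centerline:
    """An ordered polyline through the arterial lumen, arc-length parameterised.

    ``arc[i]`` is the cumulative chord length (mm) from the first vertex to
    vertex ``i``; it is strictly increasing (coincident consecutive vertices
    are rejected).
    """

    id: str
    points: np.ndarray
    arc: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("centerline points must be an (N, 3) array")
        if len(self.points) < 2:
            raise ValueError("centerline needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError(f"centerline '{self.id}' has coincident consecutive points")
        self.arc = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc[-1])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """World coordinates at arc length ``s`` (linear interpolation)."""
        s = np.asarray(s, dtype=float)
        out = np.stack(
            [np.interp(s, self.arc, self.points[:, k]) for k in range(3)], axis=-1
        )
        return out

    def tangent_at(self, s: float) -> np.ndarray:
        """Unit tangent of the polyline segment containing arc length ``s``."""
        j = int(np.clip(np.searchsorted(self.arc, s, side="right") - 1, 0, len(self.arc) - 2))
        d = self.points[j + 1] - self.points[j]
        return d / np.linalg.norm(d)

    def resample(self, step: float) -> tuple[np.ndarray, np.ndarray]:
        """Resample at uniform arc steps; returns (points (M, 3), arcs (M,)).

        Arc targets are exact multiples of ``step`` (plus the endpoint), so
        landmark positions that are multiples of ``step`` are hit exactly.
        """
        if step <= 0:
            raise ValueError("resampling step must be positive")
        n = int(np.floor(self.length / step))
        t = step * np.arange(n + 1)
        if self.length - t[-1] > 1e-9:
            t = np.append(t, self.length)
        return self.point_at(t), t

    def reversed(self) -> "Centerline":
        return Centerline(self.id, self.points[::-1].copy())


@dataclass
class CenterlineSet:
    """The centerlines of one bifurcation, kept sorted by id for determinism."""

    lines: list[Centerline]

    def __post_init__(self) -> None:
        self.lines = sorted(self.lines, key=lambda c: c.id)
        ids = [c.id for c in self.lines]
        if len(set(ids)) != len(ids):
            raise ValueError("centerline ids must be unique")

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.lines]

    def get(self, cid: str) -> Centerline:
        for c in self.lines:
            if c.id == cid:
                return c
        raise KeyError(f"no centerline with id '{cid}'")

    def __iter__(self) -> Iterable[Centerline]:
        return iter(self.lines)

    def __len__(self) -> int:
        return len(self.lines)


@dataclass
class LandmarkSet:
    """Anatomical landmarks as arc lengths (mm) along the two centerlines.

    ``p2`` (epigastric artery level), ``p3`` (midway) and ``p4`` (bifurcation)
    live on the shared trunk, so their arc lengths are valid on both lines.
    ``p5`` is 2 cm beyond the deep-branch ostium measured along the deep
    centerline; ``p6`` the analogue on the superficial centerline.
    """

    p2: float
    p3: float
    p4: float
    p5: float
    p6: float
    dfa_id: str
    sfa_id: str

    def __post_init__(self) -> None:
        for name in ("p2", "p3", "p4", "p5", "p6"):
            setattr(self, name, float(getattr(self, name)))
        if not (0 <= self.p2 < self.p3 < self.p4):
            raise ValueError(
                f"trunk landmarks must satisfy 0 <= P2 < P3 < P4, got "
                f"P2={self.p2}, P3={self.p3}, P4={self.p4}"
            )
        if not (self.p5 > self.p4 and self.p6 > self.p4):
            raise ValueError("P5 and P6 must lie distal to the bifurcation P4")
        if self.dfa_id == self.sfa_id:
            raise ValueError("deep and superficial centerline ids must differ")

    def as_records(self) -> list[dict]:
        """Rows for CSV serialisation: name, centerline_id, arc_length_mm."""
        return [
            {"name": "P2", "centerline_id": self.dfa_id, "arc_length_mm": self.p2},
            {"name": "P3", "centerline_id": self.dfa_id, "arc_length_mm": self.p3},
            {"name": "P4", "centerline_id": self.dfa_id, "arc_length_mm": self.p4},
            {"name": "P5", "centerline_id": self.dfa_id, "arc_length_mm": self.p5},
            {"name": "P6", "centerline_id": self.sfa_id, "arc_length_mm": self.p6},
        ]
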