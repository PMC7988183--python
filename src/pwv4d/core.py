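"""Shared in-memory containers for volumetric 4D-flow data and derived geometry.

Unit conventions used throughout the package (embedded in CSV column names
by the I/O layer): lengths in mm, velocities in cm/s, flow rates in mL/s,
volumes in mL, times in ms. Velocity fields are stored as 5-axis arrays
indexed (x, y, z, frame, component) with components aligned to the grid
axes. Voxel centers sit at ``origin + index * spacing`` (0-based indices,
physical mm world coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ImageVolume",
    "VelocityField4D",
    "LumenMask",
    "Centerline",
    "SectionPlane",
    "FlowWaveform",
]


@dataclass
class ImageVolume:
    """Scalar image volume, 3-D ``(x, y, z)`` or 4-D ``(x, y, z, frame)``."""

    data: np.ndarray
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray  # (3,) mm, world position of voxel (0, 0, 0) center
    frame_ms: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError("ImageVolume expects a 3-D or 4-D array")
        if self.data.ndim == 4 and self.frame_ms is None:
            raise ValueError("4-D ImageVolume requires frame_ms")

    @property
    def n_frames(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]

    def frame(self, k: int) -> np.ndarray:
        return self.data if self.data.ndim == 3 else self.data[..., k]

    def time_mean(self) -> "ImageVolume":
        d = self.data if self.data.ndim == 3 else self.data.mean(axis=3)
        return ImageVolume(d, self.spacing.copy(), self.origin.copy())

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) / self.spacing

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.atleast_2d(idx) * self.spacing + self.origin


@dataclass
class VelocityField4D:
    """Time-resolved three-component voxel velocity field.

    ``data`` has shape (nx, ny, nz, n_frames, 3) in cm/s; frame k covers the
    interval [k*frame_ms, (k+1)*frame_ms) and is stamped at its center.
    """

    data: np.ndarray
    spacing: np.ndarray  # (3,) mm
    frame_ms: float
    venc: float  # cm/s
    origin: np.ndarray  # (3,) mm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 5 or self.data.shape[-1] != 3:
            raise ValueError("velocity data must have shape (x, y, z, frame, 3)")
        if self.frame_ms <= 0:
            raise ValueError("frame_ms must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def frame_times(self) -> np.ndarray:
        """Frame-center time stamps in ms."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_ms

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) / self.spacing


@dataclass
class LumenMask:
    """Binary lumen segmentation with its provenance."""

    data: np.ndarray  # bool (nx, ny, nz)
    spacing: np.ndarray
    origin: np.ndarray
    threshold: float | None = None
    seed_point: tuple | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("lumen mask must be 3-D")
        if not self.data.any():
            raise ValueError("lumen mask is empty")

    @property
    def voxel_volume(self) -> float:
        """mm^3 per voxel."""
        return float(np.prod(self.spacing))

    def volume(self) -> float:
        """Total lumen volume in mm^3."""
        return float(self.data.sum()) * self.voxel_volume

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) / self.spacing


class Centerline:
    """Ordered, arclength-parameterized lumen centerline.

    Points are world mm coordinates; ``s`` is cumulative arclength from the
    first point. Landmarks map labels (e.g. 'LSA', 'outlet') to arclengths.
    """

    def __init__(
        self,
        points: np.ndarray,
        landmarks: dict[str, float] | None = None,
    ) -> None:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[0] < 2 or points.shape[1] != 3:
            raise ValueError("centerline needs >= 2 three-dimensional points")
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("centerline arclength must be strictly increasing")
        self.points = points
        self.s = np.concatenate([[0.0], np.cumsum(seg)])
        self.landmarks = dict(landmarks or {})

    @property
    def length(self) -> float:
        return float(self.s[-1])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.column_stack(
            [np.interp(s, self.s, self.points[:, i]) for i in range(3)]
        )
        return out[0] if out.shape[0] == 1 else out

    def tangent_at(self, s: float | np.ndarray, h: float = 1.0) -> np.ndarray:
        """Unit tangent by centered difference, oriented toward increasing s."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        lo = np.clip(s - h, 0.0, self.length)
        hi = np.clip(s + h, 0.0, self.length)
        d = np.atleast_2d(self.point_at(hi)) - np.atleast_2d(self.point_at(lo))
        n = np.linalg.norm(d, axis=1, keepdims=True)
        if np.any(n == 0):
            raise ValueError("degenerate tangent (coincident centerline points)")
        t = d / n
        return t[0] if t.shape[0] == 1 else t

    def segment_bounds(self, segment) -> tuple[float, float]:
        """Resolve a sub-segment selector to (s0, s1).

        ``segment`` may be None (full curve), a (label, label) pair of
        landmark names, or a numeric (s0, s1) pair in mm.
        """
        if segment is None:
            return 0.0, self.length
        a, b = segment
        s0 = self.landmarks[a] if isinstance(a, str) else float(a)
        s1 = self.landmarks[b] if isinstance(b, str) else float(b)
        if not (0.0 <= s0 < s1 <= self.length + 1e-9):
            raise ValueError(f"segment [{s0}, {s1}] outside centerline [0, {self.length}]")
        return s0, min(s1, self.length)

    def reversed(self) -> "Centerline":
        lm = {k: self.length - v for k, v in self.landmarks.items()}
        return Centerline(self.points[::-1].copy(), lm)


@dataclass
class SectionPlane:
    """Oriented cross-sectional analysis plane with its in-plane lumen region.

    The in-plane grid is spanned by the orthonormal axes (u, v); pixel (i, j)
    sits at ``center + a_i * u + b_j * v`` where a/b run over
    ``offsets``. ``lumen`` is the boolean cross-section A_k (connected region
    containing the center) and ``fraction`` the interpolated lumen fraction.
    """

    center: np.ndarray  # (3,) mm
    normal: np.ndarray  # unit
    s: float  # arclength along the parent centerline, mm
    grid_step: float | None = None  # mm
    extent: float | None = None  # mm
    u: np.ndarray | None = None
    v: np.ndarray | None = None
    offsets: np.ndarray | None = None  # (n,) in-plane coordinates, mm
    lumen: np.ndarray | None = None  # (n, n) bool
    fraction: np.ndarray | None = None  # (n, n) float in [0, 1]

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if n == 0:
            raise ValueError("zero plane normal")
        self.normal = self.normal / n

    @property
    def area(self) -> float:
        """Cross-sectional lumen area in mm^2."""
        if self.lumen is None or self.grid_step is None:
            raise ValueError("plane has no sampled cross-section")
        return float(self.lumen.sum()) * self.grid_step**2

    def pixel_world_coords(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World mm coordinates of in-plane pixels (default: lumen pixels)."""
        if self.offsets is None:
            raise ValueError("plane has no sampling grid")
        if mask is None:
            mask = self.lumen
        aa, bb = np.meshgrid(self.offsets, self.offsets, indexing="ij")
        pts = (
            self.center[None, :]
            + aa.ravel()[:, None] * self.u[None, :]
            + bb.ravel()[:, None] * self.v[None, :]
        )
        if mask is not None:
            pts = pts[mask.ravel()]
        return pts


@dataclass
class FlowWaveform:
    """Flow-rate time series Q_k[t] for one analysis plane."""

    time_ms: np.ndarray  # frame-center time stamps
    flow_mlps: np.ndarray
    RR: float | None = None  # cycle length ms
    s: float | None = None  # plane arclength, mm
    plane_id: int | None = None

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.flow_mlps = np.asarray(self.flow_mlps, dtype=float)
        if self.time_ms.shape != self.flow_mlps.shape:
            raise ValueError("time and flow must have equal length")
        if not np.all(np.isfinite(self.flow_mlps)):
            raise ValueError("non-finite flow values")
        if len(self.time_ms) >= 2:
            dt = np.diff(self.time_ms)
            if not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("time grid must be uniform")

    @property
    def frame_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    def shifted(self, dt_ms: float) -> "FlowWaveform":
        return FlowWaveform(
            self.time_ms + dt_ms, self.flow_mlps.copy(), self.RR, self.s, self.plane_id
        )
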