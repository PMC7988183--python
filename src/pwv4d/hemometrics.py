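"""Per-plane hemodynamic metrics: flow-rate waveforms, net flow, velocity
statistics, cross-sectional area change, and flow splits.

Flow rate is the surface integral of the velocity component normal to an
oriented cross-section, Q_k[t] = sum over in-plane lumen pixels of
<v, n_k> * pixel area, converted to mL/s (cm/s * mm^2 * 1e-2). Net flow is
the time integral over one cycle. Unit convention: velocities cm/s,
lengths mm, flows mL/s, volumes mL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .core import FlowWaveform, ImageVolume, SectionPlane, VelocityField4D

__all__ = [
    "VelocityStats",
    "AreaSeries",
    "flow_rate_waveform",
    "net_flow",
    "velocity_stats",
    "area_change_series",
    "flow_split",
]


@dataclass
class VelocityStats:
    """Per-frame speed statistics within the lumen contour (cm/s)."""

    time_ms: np.ndarray
    mean_speed: np.ndarray
    max_speed: np.ndarray
    through_plane_mean: np.ndarray  # signed mean of <v, n>


@dataclass
class AreaSeries:
    """Per-frame cross-sectional area and relative change vs frame 0."""

    time_ms: np.ndarray
    area_mm2: np.ndarray
    relative_change: np.ndarray
    flagged_frames: np.ndarray  # frames where the contour was lost

    @property
    def peak_relative_change(self) -> float:
        ok = ~self.flagged_frames
        return float(np.nanmax(np.abs(self.relative_change[ok])))


def _sample_velocity(field: VelocityField4D, points_mm: np.ndarray) -> np.ndarray:
    """Trilinear velocity samples at world points, all frames: (npts, nt, 3)."""
    vox = field.world_to_voxel(points_mm)
    if np.any(vox < -0.5) or np.any(vox > np.asarray(field.shape) - 0.5):
        raise ValueError("plane extends outside the velocity field")
    out = np.empty((points_mm.shape[0], field.n_frames, 3))
    for k in range(field.n_frames):
        for c in range(3):
            out[:, k, c] = ndimage.map_coordinates(
                field.data[:, :, :, k, c], vox.T, order=1, mode="nearest"
            )
    return out


def flow_rate_waveform(field: VelocityField4D, plane: SectionPlane) -> FlowWaveform:
    """Integrate the normal velocity component over the plane's lumen region."""
    if plane.lumen is None:
        raise ValueError("plane has no sampled cross-section")
    pts = plane.pixel_world_coords()
    if len(pts) == 0:
        raise ValueError("empty lumen contour")
    v = _sample_velocity(field, pts)  # (npts, nt, 3)
    vn = v @ plane.normal  # (npts, nt)
    q = vn.sum(axis=0) * plane.grid_step**2 * 1e-2  # cm/s * mm^2 -> mL/s
    return FlowWaveform(
        time_ms=field.frame_times,
        flow_mlps=q,
        RR=field.n_frames * field.frame_ms,
        s=plane.s,
    )


def net_flow(w: FlowWaveform) -> float:
    """Trapezoidal time integral of Q over one cycle, in mL.

    The waveform is treated as periodic: the first sample is appended at
    t0 + RR to close the cycle. For uniform frame grids this equals
    mean(Q) * RR.
    """
    if len(w.flow_mlps) < 2:
        raise ValueError("need at least 2 frames for a net flow")
    RR = w.RR if w.RR is not None else len(w.flow_mlps) * w.frame_ms
    t = np.append(w.time_ms, w.time_ms[0] + RR)
    q = np.append(w.flow_mlps, w.flow_mlps[0])
    return float(np.trapezoid(q, t) / 1000.0)


def velocity_stats(
    field: VelocityField4D,
    plane: SectionPlane,
    boundary_weight_min: float | None = 0.5,
) -> VelocityStats:
    """Mean and maximum speed within the lumen contour per frame.

    The maximum is taken after discarding pixels whose interpolated lumen
    fraction falls below ``boundary_weight_min`` — a guard against spurious
    near-boundary spikes from noise and contour inaccuracy. Pass None to
    disable the guard.
    """
    if plane.lumen is None or not plane.lumen.any():
        raise ValueError("empty lumen contour")
    pts = plane.pixel_world_coords()
    v = _sample_velocity(field, pts)
    speed = np.linalg.norm(v, axis=2)  # (npts, nt)
    if boundary_weight_min is not None and plane.fraction is not None:
        wts = plane.fraction[plane.lumen]
        keep = wts >= boundary_weight_min
        if not keep.any():
            keep = np.ones(len(wts), dtype=bool)
    else:
        keep = np.ones(speed.shape[0], dtype=bool)
    return VelocityStats(
        time_ms=field.frame_times,
        mean_speed=speed.mean(axis=0),
        max_speed=speed[keep].max(axis=0),
        through_plane_mean=(v @ plane.normal).mean(axis=0),
    )


def area_change_series(
    magnitude: ImageVolume,
    plane: SectionPlane,
    threshold_fraction: float = 0.5,
) -> AreaSeries:
    """Relative lumen area change over time from per-frame magnitude contours.

    Each frame's in-plane contour is re-derived from that frame's magnitude
    image with the same region rule as the static cross-section: threshold
    at ``threshold_fraction`` times the median intensity of the 3x3 pixels
    around the plane center, keep the connected region containing the
    center. Frames whose contour vanishes are flagged and skipped.
    """
    if magnitude.data.ndim != 4 or magnitude.n_frames < 2:
        raise ValueError("need a 4-D magnitude volume with >= 2 frames")
    if plane.offsets is None:
        raise ValueError("plane has no sampling grid")
    pts = plane.pixel_world_coords(mask=np.ones((len(plane.offsets),) * 2, dtype=bool))
    vox = magnitude.world_to_voxel(pts)
    n = len(plane.offsets)
    ic = min(np.searchsorted(plane.offsets, 0.0), n - 1)
    nt = magnitude.n_frames
    areas = np.zeros(nt)
    flagged = np.zeros(nt, dtype=bool)
    for k in range(nt):
        vals = ndimage.map_coordinates(
            magnitude.data[..., k].astype(np.float32), vox.T, order=1, mode="nearest"
        ).reshape(n, n)
        ref = float(
            np.median(vals[max(ic - 1, 0) : ic + 2, max(ic - 1, 0) : ic + 2])
        )
        binary = vals >= threshold_fraction * ref
        if not binary.any() or ref <= 0:
            flagged[k] = True
            continue
        labels = measure.label(binary, connectivity=2)
        lab = labels[ic, ic]
        if lab == 0:
            flagged[k] = True
            continue
        areas[k] = (labels == lab).sum() * plane.grid_step**2
    if flagged[0]:
        raise ValueError("contour lost in the reference frame")
    if flagged.any():
        warnings.warn(
            f"contour lost in {int(flagged.sum())} frame(s); flagged", stacklevel=2
        )
    rel = np.where(flagged, np.nan, (areas - areas[0]) / areas[0])
    t = (np.arange(nt) + 0.5) * (magnitude.frame_ms or 1.0)
    return AreaSeries(t, areas, rel, flagged)


def flow_split(
    outlet_net_flows,
    inlet_net_flow: float,
    ndigits: int | None = 0,
) -> dict:
    """Outlet shares of the inlet net flow, in percent.

    Returns shares per outlet (rounded to ``ndigits``; None for no
    rounding) and the unaccounted residual inlet volume in mL. Negative
    net flows are flagged rather than rejected.
    """
    if inlet_net_flow <= 0:
        raise ValueError("inlet net flow must be positive")
    outlets = np.atleast_1d(np.asarray(outlet_net_flows, dtype=float))
    shares = 100.0 * outlets / inlet_net_flow
    if ndigits is not None:
        shares = np.round(shares, ndigits)
    return {
        "shares_percent": shares,
        "residual_ml": float(inlet_net_flow - outlets.sum()),
        "negative_flagged": outlets < 0,
    }
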