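"""Synthetic 4D-flow phantom: a tapered compliant tube carrying a traveling
pulsatile flow wave of known speed.

The phantom is a prescribed-flow stand-in for an acquired dataset, not a
fluid-structure simulation: the local flow rate is the inflow waveform
delayed by arclength over the true wave speed,

    Q(s, t) = D(s) * Q_in(t - s / PWV_true),

with optional exponential damping D(s) = exp(-s / L_d) emulating branch
outflow. The lumen radius breathes with the local flow,

    R(s, t) = R0(s) * sqrt(1 + alpha * (Q - Qmin) / (Qmax - Qmin)),

so the peak relative cross-sectional area change equals ``compliance_alpha``
exactly. Axial velocity follows a parabolic (Poiseuille) or plug profile.
Voxel magnitude encodes the partial-volume lumen fraction (supersampled
3x3x3); a static gel block fills the rest of the volume. Each stored frame
is the boxcar mean of an internal fine-step (default 1 ms) simulation over
its frame interval, as with a gated acquisition averaging over the frame
duration. Gaussian velocity noise and a spatially linear static phase
offset can be added; velocities beyond the encoding range are clipped and
counted. Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ImageVolume, VelocityField4D
from .waveform import InflowWaveform

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "synthesize_phantom",
    "synthesize_spgr",
    "resample_temporal",
]


@dataclass
class PhantomSpec:
    """Ground-truth parameterization of a synthetic 4D-flow experiment.

    Defaults reproduce the emulated in vitro experiment: a 36 -> 20 mm diameter
    taper, 2.5 mm isotropic voxels, Venc 120 cm/s, 20 ms frames over a
    1000 ms cycle, and distal damping matching a 68 % descending-aorta flow
    split. ``compliance_alpha`` is the peak relative area change: 0.06 for
    the compliant configuration (area change > 5 %), 0.002 for the nearly
    rigid one (< 1 %).
    """

    length: float = 250.0  # mm, tube (arc) length
    radius_inlet: float = 18.0  # mm
    radius_outlet: float = 10.0  # mm, linear taper
    grid_spacing: float = 2.5  # mm, isotropic
    fov_margin: float = 10.0  # mm of gel beyond the inlet radius transversely
    pwv_true: float = 6.0  # m/s
    compliance_alpha: float = 0.06  # peak relative area change
    profile: str = "parabolic"  # or "plug"
    noise_sd: float = 3.0  # cm/s per velocity component
    frame_ms: float = 20.0
    n_frames: int | None = None  # default floor(RR / frame_ms)
    venc: float = 120.0  # cm/s
    static_offset_coeffs: np.ndarray | None = None  # (3, 4): a0, ax, ay, az per comp
    seed: int = 0
    damping_length: float | None = 648.0  # mm; None disables damping
    bend_radius: float | None = None  # mm; None = straight tube along z
    fluid_intensity: float = 100.0
    gel_intensity: float = 40.0
    sub_dt: float = 1.0  # ms, internal simulation step
    supersample: int = 3  # per-axis magnitude supersampling
    # generic transverse axis position (mm): an axis aligned with (or at a
    # simple rational offset of) either voxel grid correlates boundary
    # voxelization errors around the lumen ring
    axis_offset: tuple = (0.37, 0.61)
    spgr_spacing: float = 1.0  # mm, high-resolution structural (SPGR) scan

    def __post_init__(self) -> None:
        if self.radius_outlet > self.radius_inlet:
            raise ValueError("radius_outlet must not exceed radius_inlet")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.pwv_true <= 0:
            raise ValueError("pwv_true must be positive")
        if self.frame_ms < 1.0:
            raise ValueError("frame_ms below the 1 ms simulation step")
        if self.profile not in ("parabolic", "plug"):
            raise ValueError("profile must be 'parabolic' or 'plug'")
        if self.bend_radius is not None and self.bend_radius <= 0:
            raise ValueError("bend_radius must be positive")

    def radius0(self, s) -> np.ndarray:
        """Rest (diastolic-minimum) lumen radius profile R0(s), mm."""
        s = np.asarray(s, dtype=float)
        return self.radius_inlet + (self.radius_outlet - self.radius_inlet) * s / self.length

    def area0(self, s) -> np.ndarray:
        """Rest cross-sectional area A0(s), mm^2."""
        return np.pi * self.radius0(s) ** 2

    def damping(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if self.damping_length is None:
            return np.ones_like(s)
        return np.exp(-s / self.damping_length)


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a synthesized phantom."""

    spec: PhantomSpec
    inflow: InflowWaveform
    axis_points: np.ndarray  # (n, 3) mm, proximal to distal
    axis_s: np.ndarray  # (n,) mm
    lumen_mask_frames: np.ndarray  # (nx, ny, nz, n_frames) bool
    static_mask: np.ndarray  # (nx, ny, nz) bool
    spacing: np.ndarray
    origin: np.ndarray
    frame_ms: float
    n_clipped: int = 0

    @property
    def pwv_true(self) -> float:
        return self.spec.pwv_true

    def flow(self, s, t_ms) -> np.ndarray:
        """Ground-truth flow rate Q(s, t) in mL/s (broadcasts s against t)."""
        s = np.asarray(s, dtype=float)
        t = np.asarray(t_ms, dtype=float)
        delay = s / self.spec.pwv_true  # mm / (m/s) = ms
        return self.spec.damping(s) * self.inflow(t - delay)

    def area(self, s, t_ms) -> np.ndarray:
        """Ground-truth lumen area A(s, t) in mm^2."""
        q = self.inflow(np.asarray(t_ms, dtype=float) - np.asarray(s) / self.spec.pwv_true)
        qmin, qmax = self.inflow.flow_mlps.min(), self.inflow.flow_mlps.max()
        qn = np.zeros_like(q) if qmax <= qmin else (q - qmin) / (qmax - qmin)
        return self.spec.area0(s) * (1.0 + self.spec.compliance_alpha * qn)

    def flow_table(self, s_values, t_values) -> "np.ndarray":
        """Q(s, t) sampled on a grid; rows follow s_values, columns t_values."""
        s = np.asarray(s_values, dtype=float)[:, None]
        t = np.asarray(t_values, dtype=float)[None, :]
        return self.flow(s, t)


def _axis_geometry(spec: PhantomSpec, X, Y, Z):
    """Per-voxel arclength s, radial distance rho, and tangent components.

    Straight tube: axis along +z through ``axis_offset``. Optional
    circular-arc bend of radius ``bend_radius`` in the x-z plane, starting
    at the offset origin and curving toward +x.
    """
    X = X - spec.axis_offset[0]
    Y = Y - spec.axis_offset[1]
    if spec.bend_radius is None:
        s = Z + 0.0 * X + 0.0 * Y
        rho = np.sqrt(X**2 + Y**2) + 0.0 * Z
        tangent = None  # constant (0, 0, 1)
        return s, rho, tangent
    Rb = spec.bend_radius
    # arc center at (Rb, 0, 0): a(theta) = (Rb - Rb cos, 0, Rb sin), s = Rb*theta
    dx = X - Rb
    theta = np.arctan2(Z, -dx)
    s = Rb * theta
    d_inplane = np.sqrt(dx**2 + Z**2)
    rho = np.sqrt((d_inplane - Rb) ** 2 + Y**2)
    valid = (theta >= 0) & (s <= spec.length)
    s = np.where(valid, s, np.nan)
    tx = np.sin(theta)
    tz = np.cos(theta)
    tangent = (tx, np.zeros_like(tx), tz)
    return s, rho, tangent


def synthesize_phantom(
    spec: PhantomSpec, inflow: InflowWaveform
) -> tuple[ImageVolume, VelocityField4D, PhantomTruth]:
    """Generate magnitude and 4D velocity volumes with analytic ground truth.

    Returns a 4-D magnitude ``ImageVolume``, a ``VelocityField4D``, and the
    ``PhantomTruth`` (per-frame lumen masks, static gel mask, axis polyline,
    and the exact Q(s, t))."""
    RR = inflow.RR
    n_frames = spec.n_frames or int(RR // spec.frame_ms)
    if n_frames < 1:
        raise ValueError("frame_ms longer than the cycle")
    if n_frames * spec.frame_ms > RR + 1e-9:
        raise ValueError("n_frames * frame_ms exceeds the cycle length RR")

    dx = spec.grid_spacing
    alpha = spec.compliance_alpha
    g_max = np.sqrt(1.0 + alpha)
    r_dyn_max = spec.radius_inlet * g_max

    # --- grid -----------------------------------------------------------
    half_w = r_dyn_max + spec.fov_margin
    if spec.bend_radius is not None:
        sag = spec.bend_radius * (1 - np.cos(min(spec.length / spec.bend_radius, np.pi)))
        half_w_x = half_w + sag
    else:
        half_w_x = half_w
    # odd transverse dimensions center the tube axis on a voxel column
    nx = int(np.ceil(2 * half_w_x / dx)) | 1
    ny = int(np.ceil(2 * half_w / dx)) | 1
    nz = int(round(spec.length / dx))
    if nz < 2:
        raise ValueError("tube does not fit the field of view")
    xs = (np.arange(nx) - (nx - 1) / 2) * dx
    ys = (np.arange(ny) - (ny - 1) / 2) * dx
    zs = (np.arange(nz) + 0.5) * dx
    if spec.bend_radius is not None:
        xs = xs + half_w_x - half_w  # shift so the arc curves into the volume
    origin = np.array([xs[0], ys[0], zs[0]])
    spacing = np.array([dx, dx, dx])
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]

    s_vox, rho_vox, tangent = _axis_geometry(spec, X, Y, Z)
    s_vox = np.broadcast_to(s_vox, (nx, ny, nz)).copy()
    rho_vox = np.broadcast_to(rho_vox, (nx, ny, nz)).copy()

    # --- time tables ----------------------------------------------------
    n_sub = max(1, int(np.ceil(spec.frame_ms / spec.sub_dt)))
    dt_eff = spec.frame_ms / n_sub
    t_sub = (np.arange(n_frames * n_sub) + 0.5) * dt_eff  # global substep times
    qmin = float(inflow.flow_mlps.min())
    qmax = float(inflow.flow_mlps.max())
    steady = qmax - qmin <= 0

    # delay-binned waveform tables over arclength (exact radii, binned delays)
    n_bins = max(1, int(np.ceil(spec.length / dx)))
    s_bins = (np.arange(n_bins) + 0.5) * (spec.length / n_bins)
    qin = inflow(t_sub[None, :] - (s_bins / spec.pwv_true)[:, None])  # (n_bins, T)
    qn = np.zeros_like(qin) if steady else (qin - qmin) / (qmax - qmin)
    g_tab = np.sqrt(1.0 + alpha * qn)  # radial breathing factor

    def bin_of(s):
        return np.clip((s / (spec.length / n_bins)).astype(int), 0, n_bins - 1)

    # --- velocity field -------------------------------------------------
    inside_reach = np.isfinite(s_vox) & (rho_vox < r_dyn_max)
    sup = np.where(inside_reach.ravel())[0]  # support voxel flat indices
    s_sup = s_vox.ravel()[sup]
    rr_sup = rho_vox.ravel()[sup] / spec.radius0(s_sup)  # rho / R0
    d_sup = spec.damping(s_sup)
    r0_sup = spec.radius0(s_sup)
    bin_sup = bin_of(s_sup)
    if tangent is not None:
        tx_sup = np.broadcast_to(tangent[0], (nx, ny, nz)).ravel()[sup]
        tz_sup = np.broadcast_to(tangent[2], (nx, ny, nz)).ravel()[sup]

    vel = np.zeros((nx * ny * nz, n_frames, 3), dtype=np.float32)
    for k in range(n_frames):
        acc = np.zeros(sup.shape[0])
        acc_x = np.zeros(sup.shape[0]) if tangent is not None else None
        for j in range(k * n_sub, (k + 1) * n_sub):
            g = g_tab[bin_sup, j]
            q = d_sup * qin[bin_sup, j]
            inside = rr_sup < g
            area_cm2 = np.pi * (r0_sup * g) ** 2 * 0.01  # mm^2 -> cm^2
            vmean = q / area_cm2  # cm/s
            if spec.profile == "parabolic":
                v = 2.0 * vmean * (1.0 - (rr_sup / g) ** 2)
            else:
                v = vmean
            v = np.where(inside, v, 0.0)
            if tangent is None:
                acc += v
            else:
                acc += v * tz_sup
                acc_x += v * tx_sup
        if tangent is None:
            vel[sup, k, 2] = acc / n_sub
        else:
            vel[sup, k, 2] = acc / n_sub
            vel[sup, k, 0] = acc_x / n_sub
    vel = vel.reshape(nx, ny, nz, n_frames, 3)

    # --- magnitude (partial-volume lumen fraction, supersampled) --------
    ss = spec.supersample
    offs = (np.arange(ss) - (ss - 1) / 2) / ss * dx
    frac = np.zeros((nx * ny * nz, n_frames), dtype=np.float32)
    support_any = np.zeros(nx * ny * nz, dtype=bool)
    # precompute sorted g per (bin, frame) for counting substeps inside
    g_sorted = np.sort(g_tab.reshape(n_bins, n_frames, n_sub), axis=2)
    for ox in offs:
        for oy in offs:
            for oz in offs:
                s_o, rho_o, _ = _axis_geometry(
                    spec, X + ox, Y + oy, Z + oz
                )
                s_o = np.broadcast_to(s_o, (nx, ny, nz)).ravel()
                rho_o = np.broadcast_to(rho_o, (nx, ny, nz)).ravel()
                ok = np.isfinite(s_o) & (s_o >= 0) & (s_o <= spec.length)
                ratio = np.full(s_o.shape, np.inf)
                ratio[ok] = rho_o[ok] / spec.radius0(s_o[ok])
                cand = np.where(ratio < g_max)[0]
                support_any[cand] = True
                if cand.size == 0:
                    continue
                b_c = bin_of(s_o[cand])
                order = np.argsort(b_c, kind="stable")
                cand, b_c = cand[order], b_c[order]
                ratio_c = ratio[cand]
                bounds = np.searchsorted(b_c, np.arange(n_bins + 1))
                for b in range(n_bins):
                    lo, hi = bounds[b], bounds[b + 1]
                    if lo == hi:
                        continue
                    for k in range(n_frames):
                        cnt = n_sub - np.searchsorted(g_sorted[b, k], ratio_c[lo:hi])
                        frac[cand[lo:hi], k] += cnt.astype(np.float32)
    frac /= ss**3 * n_sub
    gel = ~support_any
    mag = spec.fluid_intensity * frac
    mag[gel, :] = spec.gel_intensity
    mag = mag.reshape(nx, ny, nz, n_frames)
    lumen_frames = mag >= 0.5 * spec.fluid_intensity
    lumen_frames &= ~gel.reshape(nx, ny, nz)[..., None]

    # --- noise, static offset, velocity encoding ------------------------
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        vel = vel + rng.normal(0.0, spec.noise_sd, size=vel.shape).astype(np.float32)
    if spec.static_offset_coeffs is not None:
        c = np.asarray(spec.static_offset_coeffs, dtype=float).reshape(3, 4)
        plane = (
            c[:, 0][None, None, None, :]
            + c[:, 1][None, None, None, :] * np.broadcast_to(X[..., None], (nx, ny, nz, 3))
            + c[:, 2][None, None, None, :] * np.broadcast_to(Y[..., None], (nx, ny, nz, 3))
            + c[:, 3][None, None, None, :] * np.broadcast_to(Z[..., None], (nx, ny, nz, 3))
        )
        vel = vel + plane[:, :, :, None, :].astype(np.float32)
    n_clipped = int(np.count_nonzero(np.abs(vel) > spec.venc))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} velocity samples exceeded Venc = {spec.venc} cm/s and were clipped",
            stacklevel=2,
        )
        np.clip(vel, -spec.venc, spec.venc, out=vel)

    field = VelocityField4D(vel, spacing, spec.frame_ms, spec.venc, origin)
    magnitude = ImageVolume(mag.astype(np.float32), spacing, origin, spec.frame_ms)

    axis_s = np.arange(0.0, spec.length + 1e-9, 1.0)
    ox, oy = spec.axis_offset
    if spec.bend_radius is None:
        axis_points = np.column_stack(
            [np.full_like(axis_s, ox), np.full_like(axis_s, oy), axis_s]
        )
    else:
        th = axis_s / spec.bend_radius
        axis_points = np.column_stack(
            [
                ox + spec.bend_radius * (1 - np.cos(th)),
                np.full_like(axis_s, oy),
                spec.bend_radius * np.sin(th),
            ]
        )
    truth = PhantomTruth(
        spec=spec,
        inflow=inflow,
        axis_points=axis_points,
        axis_s=axis_s,
        lumen_mask_frames=lumen_frames,
        static_mask=gel.reshape(nx, ny, nz),
        spacing=spacing,
        origin=origin,
        frame_ms=spec.frame_ms,
        n_clipped=n_clipped,
    )
    return magnitude, field, truth


def synthesize_spgr(spec: PhantomSpec) -> ImageVolume:
    """High-resolution structural (SPGR-analog) magnitude volume.

    Emulates the steady-flow 3-D anatomical scan used for lumen
    segmentation: the resting lumen geometry R0(s) rendered at
    ``spgr_spacing`` (finer than the 4D-flow voxels) with supersampled
    partial-volume edges and the static gel block around it. Co-registered
    with the 4D volumes (same world coordinates); noise-free (the
    structural scan's SNR is far above the segmentation threshold).
    """
    dx = spec.spgr_spacing
    g_max = np.sqrt(1.0 + spec.compliance_alpha)
    half_w = spec.radius_inlet * g_max + spec.fov_margin
    if spec.bend_radius is not None:
        sag = spec.bend_radius * (1 - np.cos(min(spec.length / spec.bend_radius, np.pi)))
        half_w_x = half_w + sag
    else:
        half_w_x = half_w
    nx = int(np.ceil(2 * half_w_x / dx)) | 1
    ny = int(np.ceil(2 * half_w / dx)) | 1
    nz = int(round(spec.length / dx))
    xs = (np.arange(nx) - (nx - 1) / 2) * dx
    ys = (np.arange(ny) - (ny - 1) / 2) * dx
    zs = (np.arange(nz) + 0.5) * dx
    if spec.bend_radius is not None:
        xs = xs + half_w_x - half_w
    origin = np.array([xs[0], ys[0], zs[0]])
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]
    ss = spec.supersample
    offs = (np.arange(ss) - (ss - 1) / 2) / ss * dx
    frac = np.zeros((nx, ny, nz), dtype=np.float32)
    support = np.zeros((nx, ny, nz), dtype=bool)
    for ox in offs:
        for oy in offs:
            for oz in offs:
                s_o, rho_o, _ = _axis_geometry(spec, X + ox, Y + oy, Z + oz)
                s_o = np.broadcast_to(s_o, (nx, ny, nz))
                rho_o = np.broadcast_to(rho_o, (nx, ny, nz))
                ok = np.isfinite(s_o) & (s_o >= 0) & (s_o <= spec.length)
                r0 = spec.radius0(np.where(ok, s_o, 0.0))
                inside = ok & (rho_o < r0)
                frac += inside.astype(np.float32)
                support |= ok & (rho_o < r0 * g_max)
    frac /= ss**3
    data = spec.fluid_intensity * frac
    data[~support] = spec.gel_intensity
    return ImageVolume(data, np.array([dx] * 3), origin)


def resample_temporal(field: VelocityField4D, target_frame_ms: float) -> VelocityField4D:
    """Reduce temporal resolution by boxcar frame averaging.

    ``target_frame_ms`` must be an integer multiple of the field's frame
    duration; each output frame is the mean of the input frames it spans.
    Non-commensurate targets require re-running the generator instead.
    """
    ratio = target_frame_ms / field.frame_ms
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"target {target_frame_ms} ms is not an integer multiple of "
            f"{field.frame_ms} ms; re-run the generator for arbitrary rates"
        )
    if factor == 1:
        return VelocityField4D(
            field.data.copy(),
            field.spacing.copy(),
            field.frame_ms,
            field.venc,
            field.origin.copy(),
        )
    n_out = field.n_frames // factor
    if n_out < 1:
        raise ValueError("fewer input frames than the averaging factor")
    d = field.data[:, :, :, : n_out * factor, :]
    nx, ny, nz, _, _ = d.shape
    d = d.reshape(nx, ny, nz, n_out, factor, 3).mean(axis=4)
    return VelocityField4D(
        d.astype(field.data.dtype),
        field.spacing.copy(),
        target_frame_ms,
        field.venc,
        field.origin.copy(),
    )
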