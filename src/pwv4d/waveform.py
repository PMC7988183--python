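"""Pulsatile inflow waveform construction.

The programmed pump waveform is modeled as an analytic cosine-squared
(Hann-shaped) systolic pulse plus a small secondary diastolic lobe, spline
resampled to the pump's discretization grid, rescaled to a target stroke
volume, and down-scaled if the pump's peak flow-rate limit would be
exceeded. The secondary lobe mimics the distinct second flow-rate peak
observed around two thirds of the cycle in pump-driven aortic waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["InflowWaveform", "WaveformShape", "make_inflow_waveform"]


@dataclass
class WaveformShape:
    """Analytic shape parameters of the inflow pulse (times in ms).

    systole_onset: delay of the systolic foot after the cycle trigger.
    systole_duration: base width of the cosine-squared systolic lobe.
    lobe_amplitude: secondary diastolic lobe amplitude as a fraction of the
        systolic peak (0.15 by default, at lobe_time_frac * RR).
    """

    systole_onset: float = 50.0
    systole_duration: float = 500.0
    lobe_amplitude: float = 0.15
    lobe_time_frac: float = 0.66
    lobe_width: float = 150.0


@dataclass
class InflowWaveform:
    """One cycle of pump inflow, discretized on a uniform grid over [0, RR).

    The waveform is periodic: the value at t = RR wraps to the value at 0.
    ``stroke_volume`` is the realized cycle integral (mL); when the peak cap
    forced a down-scaling it is smaller than the requested volume.
    """

    time_ms: np.ndarray
    flow_mlps: np.ndarray
    RR: float
    stroke_volume: float
    peak_flow: float
    requested_stroke_volume: float | None = None
    capped: bool = False

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.flow_mlps = np.asarray(self.flow_mlps, dtype=float)

    @property
    def dt_wave(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    @property
    def mean_flow(self) -> float:
        """Cycle-mean flow rate in mL/s."""
        return float(self.flow_mlps.mean())

    @property
    def total_flow_lpm(self) -> float:
        """Cycle-mean flow expressed in L/min."""
        return self.mean_flow * 60.0 / 1000.0

    def __call__(self, t_ms) -> np.ndarray:
        """Periodic linear interpolation of the discretized waveform."""
        t = np.mod(np.asarray(t_ms, dtype=float), self.RR)
        tp = np.concatenate([self.time_ms, [self.RR]])
        fp = np.concatenate([self.flow_mlps, [self.flow_mlps[0]]])
        return np.interp(t, tp, fp)

    def cycle_integral(self) -> float:
        """Periodic trapezoidal integral over one cycle, mL."""
        return float(self.flow_mlps.mean() * self.RR / 1000.0)


def _analytic_shape(t: np.ndarray, RR: float, shape: WaveformShape) -> np.ndarray:
    """Unit-peak analytic pulse evaluated at times t (ms), periodic in RR."""
    t = np.mod(np.asarray(t, dtype=float), RR)
    q = np.zeros_like(t)
    t0, ts = shape.systole_onset, shape.systole_duration
    m = (t >= t0) & (t < t0 + ts)
    q[m] = np.sin(np.pi * (t[m] - t0) / ts) ** 2
    lc = shape.lobe_time_frac * RR
    lw = shape.lobe_width
    m2 = (t >= lc - lw / 2) & (t < lc + lw / 2)
    q[m2] += shape.lobe_amplitude * np.sin(np.pi * (t[m2] - lc + lw / 2) / lw) ** 2
    return q


def make_inflow_waveform(
    stroke_volume: float,
    RR: float = 1000.0,
    peak_cap: float | None = 300.0,
    shape: WaveformShape | None = None,
    dt_wave: float = 10.0,
) -> InflowWaveform:
    """Build a discretized pump inflow waveform.

    Parameters
    ----------
    stroke_volume : target cycle integral in mL (may be 0 for a null waveform).
    RR : cycle length in ms.
    peak_cap : pump peak flow-rate limit in mL/s; when the rescaled waveform
        would exceed it, the whole waveform is uniformly down-scaled to the
        cap and the realized (smaller) stroke volume is reported.
    shape : analytic shape parameters; defaults reproduce a pump-limited
        aortic waveform (broad systole, 15 % secondary lobe at 0.66 RR).
    dt_wave : discretization step in ms.

    Returns
    -------
    InflowWaveform with the realized stroke volume and peak flow.
    """
    if stroke_volume < 0:
        raise ValueError("stroke_volume must be non-negative")
    if RR <= 0 or dt_wave <= 0:
        raise ValueError("RR and dt_wave must be positive")
    if peak_cap is not None and peak_cap <= 0:
        raise ValueError("peak_cap must be positive")
    shape = shape or WaveformShape()
    if shape.systole_onset + shape.systole_duration >= RR:
        raise ValueError("systole must end within the cycle")

    t = np.arange(0.0, RR - dt_wave / 2, dt_wave)
    # dense analytic evaluation, then cubic-spline resampling to the pump grid
    td = np.arange(0.0, RR, min(1.0, dt_wave))
    qd = _analytic_shape(td, RR, shape)
    cs = CubicSpline(
        np.concatenate([td, [RR]]),
        np.concatenate([qd, [qd[0]]]),
        bc_type="periodic",
    )
    q = np.clip(cs(t), 0.0, None)

    if stroke_volume == 0:
        flow = np.zeros_like(q)
        return InflowWaveform(t, flow, RR, 0.0, 0.0, 0.0, capped=False)

    # uniform-grid periodic integral: mean * RR
    unit_integral = q.mean() * RR / 1000.0  # mL per unit amplitude
    scale = stroke_volume / unit_integral
    flow = q * scale
    capped = False
    if peak_cap is not None and flow.max() > peak_cap:
        flow = flow * (peak_cap / flow.max())
        capped = True
    realized = flow.mean() * RR / 1000.0
    return InflowWaveform(
        t,
        flow,
        RR,
        realized,
        float(flow.max()),
        requested_stroke_volume=stroke_volume,
        capped=capped,
    )
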