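"""Pulse wave velocity from per-plane flow waveforms.

The time-to-foot (TTF) of a flow waveform is the x-intercept of a line
fitted through the waveform's systolic upslope between 20 % and 80 % of
the peak flow rate, after cubic-spline interpolation to a dense time grid.
TTF plotted against centerline arclength is fitted by ordinary least
squares and by RANSAC; PWV is the inverse slope of the regression line
(a slope in ms/mm inverts to m/s with no further unit factors).

A validity gate withholds the PWV value when the TTF-distance relation is
not credibly linear (non-positive slope or R^2 below a threshold), which
is the situation encountered with nearly rigid vessels whose wave transit
is too fast to resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.linear_model import LinearRegression, RANSACRegressor

from .core import FlowWaveform

__all__ = [
    "TTFResult",
    "TTFSeries",
    "PWVEstimate",
    "MoensKortewegParams",
    "time_to_foot",
    "ttf_series",
    "fit_pwv_lse",
    "fit_pwv_ransac",
    "moens_korteweg",
]


@dataclass
class TTFResult:
    """Time-to-foot of one waveform with its upslope-fit diagnostics."""

    ttf_ms: float
    t20_ms: float  # 20 % threshold crossing on the fitted upstroke
    t80_ms: float  # 80 % threshold crossing
    upslope_mlps_per_ms: float
    peak_mlps: float
    n_band: int  # dense samples used in the line fit


@dataclass
class TTFSeries:
    """Per-plane TTF values along the centerline (regression input)."""

    s_mm: np.ndarray
    ttf_ms: np.ndarray
    diagnostics: list = field(default_factory=list)
    excluded: np.ndarray | None = None  # planes whose TTF failed outright
    exclusion_reasons: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s_mm = np.asarray(self.s_mm, dtype=float)
        self.ttf_ms = np.asarray(self.ttf_ms, dtype=float)
        if self.excluded is None:
            self.excluded = ~np.isfinite(self.ttf_ms)
        if np.any(np.diff(self.s_mm) <= 0):
            raise ValueError("plane arclengths must be strictly increasing")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.excluded & np.isfinite(self.ttf_ms)


@dataclass
class PWVEstimate:
    """Result of a TTF-vs-distance regression.

    ``pwv_mps`` is populated only when the fit is valid; the slope and
    diagnostics are always reported.
    """

    method: str  # 'LSE' or 'RANSAC'
    slope_ms_per_mm: float
    intercept_ms: float
    r2: float
    rmse_ms: float
    outlier_indices: np.ndarray
    valid: bool
    pwv_mps: float | None = None
    n_used: int = 0


@dataclass
class MoensKortewegParams:
    """Inputs of the Moens-Korteweg wave speed (SI units)."""

    E: float  # elastic modulus, Pa
    h: float  # wall thickness, m
    rho: float  # fluid density, kg/m^3
    r: float  # lumen radius, m

    def __post_init__(self) -> None:
        for name in ("E", "h", "rho", "r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def time_to_foot(w: FlowWaveform, dense_dt: float = 1.0) -> TTFResult:
    """Time-to-foot of a flow waveform by the 20-80 % upslope intercept.

    The waveform is cubic-spline interpolated to ``dense_dt`` spacing, the
    global peak located, and the last upstroke before the peak identified
    as the stretch from the final sample at or below 20 % of peak up to the
    following first sample at or above 80 %. An ordinary least-squares line
    through all dense samples inside the 20-80 % band of that upstroke is
    extrapolated to its x-intercept, the TTF.
    """
    t, q = w.time_ms, w.flow_mlps
    if len(t) < 4:
        raise ValueError("need at least 4 frames for a TTF")
    cs = CubicSpline(t, q)
    td = np.arange(t[0], t[-1] + dense_dt / 2, dense_dt)
    qd = cs(td)
    ip = int(np.argmax(qd))
    qpk = float(qd[ip])
    if qpk <= 0:
        raise ValueError("waveform peak is not positive")
    lo, hi = 0.2 * qpk, 0.8 * qpk
    below = np.where(qd[: ip + 1] <= lo)[0]
    if len(below) == 0:
        raise ValueError("waveform never drops to 20 % of peak before it (flat)")
    i_lo = int(below[-1])
    above = np.where(qd[i_lo : ip + 1] >= hi)[0]
    if len(above) == 0:
        raise ValueError("80 % threshold not crossed on the upstroke")
    i_hi = i_lo + int(above[0])
    band = slice(i_lo, i_hi + 1)
    sel = (qd[band] >= lo) & (qd[band] <= hi)
    x, y = td[band][sel], qd[band][sel]
    if len(x) < 2:
        raise ValueError("upslope shorter than 2 dense samples")
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise ValueError("non-positive upslope")
    return TTFResult(
        ttf_ms=float(-intercept / slope),
        t20_ms=float(np.interp(lo, [qd[i_lo], qd[i_lo + 1]], [td[i_lo], td[i_lo + 1]]))
        if i_lo + 1 < len(qd)
        else float(td[i_lo]),
        t80_ms=float(td[i_hi]),
        upslope_mlps_per_ms=float(slope),
        peak_mlps=qpk,
        n_band=int(len(x)),
    )


def ttf_series(waveforms: list[FlowWaveform], dense_dt: float = 1.0) -> TTFSeries:
    """TTF for every plane waveform; per-plane failures are excluded, not fatal."""
    order = np.argsort([w.s for w in waveforms])
    s, ttf, diags = [], [], []
    reasons = {}
    for idx in order:
        w = waveforms[idx]
        s.append(w.s)
        try:
            res = time_to_foot(w, dense_dt)
            ttf.append(res.ttf_ms)
            diags.append(res)
        except ValueError as err:
            ttf.append(np.nan)
            diags.append(None)
            reasons[len(s) - 1] = str(err)
    return TTFSeries(
        np.asarray(s), np.asarray(ttf), diags, exclusion_reasons=reasons
    )


def _ols(s: np.ndarray, t: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, R^2, RMSE of t on s."""
    slope, intercept = np.polyfit(s, t, 1)
    res = t - (slope * s + intercept)
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r2 = 1.0 - float(np.sum(res**2)) / ss_tot if ss_tot > 0 else 0.0
    rmse = float(np.sqrt(np.mean(res**2)))
    return float(slope), float(intercept), r2, rmse


def _finalize(
    method: str,
    slope: float,
    intercept: float,
    r2: float,
    rmse: float,
    outliers: np.ndarray,
    n_used: int,
    r2_min: float,
) -> PWVEstimate:
    valid = slope > 0 and r2 >= r2_min and n_used >= 3
    return PWVEstimate(
        method=method,
        slope_ms_per_mm=slope,
        intercept_ms=intercept,
        r2=r2,
        rmse_ms=rmse,
        outlier_indices=np.asarray(outliers, dtype=int),
        valid=valid,
        pwv_mps=(1.0 / slope) if valid else None,  # mm/ms = m/s
        n_used=n_used,
    )


def fit_pwv_lse(
    series: TTFSeries,
    r2_min: float = 0.3,
    outlier_factor: float = 100.0,
) -> PWVEstimate:
    """Least-squares TTF-vs-distance fit with gross-outlier exclusion.

    Gross outliers are removed iteratively, worst point first: a point is
    excluded when its deviation from the line fitted to the *remaining*
    points exceeds ``outlier_factor`` times that fit's RMSE. (Deviations
    measured against a fit that includes the point itself are bounded by
    sqrt(n) RMSE and could never trip a 100x threshold.) PWV is reported
    only when the final fit is valid: positive slope and R^2 >= ``r2_min``.
    """
    keep = series.valid_mask.copy()
    if keep.sum() < 3:
        raise ValueError("need at least 3 planes with a finite TTF")
    s_all, t_all = series.s_mm, series.ttf_ms
    while keep.sum() > 3:
        s, t = s_all[keep], t_all[keep]
        slope, intercept, _, _ = _ols(s, t)
        res = np.abs(t - (slope * s + intercept))
        worst_local = int(np.argmax(res))
        idx = np.where(keep)[0][worst_local]
        rest = keep.copy()
        rest[idx] = False
        sl_r, ic_r, _, rmse_r = _ols(s_all[rest], t_all[rest])
        dev = abs(t_all[idx] - (sl_r * s_all[idx] + ic_r))
        scale = max(rmse_r, 1e-12 * max(1.0, float(np.abs(t_all[rest]).max())))
        if dev > outlier_factor * scale:
            keep = rest
            continue
        break
    s, t = s_all[keep], t_all[keep]
    slope, intercept, r2, rmse = _ols(s, t)
    outliers = np.where(series.valid_mask & ~keep)[0]
    return _finalize("LSE", slope, intercept, r2, rmse, outliers, int(keep.sum()), r2_min)


def fit_pwv_ransac(
    series: TTFSeries,
    residual_threshold: float | None = None,
    n_iter: int = 1000,
    seed: int = 0,
    r2_min: float = 0.3,
) -> PWVEstimate:
    """RANSAC TTF-vs-distance fit over 2-point minimal samples.

    The inlier threshold defaults to 1.4826x the median absolute deviation
    of the residuals of an initial least-squares fit (a robust sigma
    estimate). The final line is refit on the largest consensus set; the
    estimate is seeded and reproducible.
    """
    keep = series.valid_mask
    if keep.sum() < 3:
        raise ValueError("need at least 3 planes with a finite TTF")
    s = series.s_mm[keep].reshape(-1, 1)
    t = series.ttf_ms[keep]
    if residual_threshold is None:
        slope0, ic0, _, _ = _ols(s.ravel(), t)
        res0 = np.abs(t - (slope0 * s.ravel() + ic0))
        residual_threshold = 1.4826 * float(np.median(res0))
    scale_floor = 1e-9 * max(1.0, float(np.abs(t).max()))
    residual_threshold = max(residual_threshold, scale_floor)
    ransac = RANSACRegressor(
        estimator=LinearRegression(),
        min_samples=2,
        residual_threshold=residual_threshold,
        max_trials=n_iter,
        random_state=seed,
    )
    try:
        ransac.fit(s, t)
    except ValueError as err:
        raise ValueError(f"RANSAC found no consensus: {err}") from err
    inlier = ransac.inlier_mask_
    if inlier.sum() < 3:
        raise ValueError("RANSAC consensus set smaller than 3 points")
    slope, intercept, r2, rmse = _ols(s.ravel()[inlier], t[inlier])
    outliers = np.where(keep)[0][~inlier]
    return _finalize(
        "RANSAC", slope, intercept, r2, rmse, outliers, int(inlier.sum()), r2_min
    )


def moens_korteweg(params: MoensKortewegParams | None = None, **kwargs) -> float:
    """Moens-Korteweg wave speed PWV = sqrt(E h / (2 rho r)) in m/s.

    Accepts either a ``MoensKortewegParams`` or the keyword arguments
    E (Pa), h (m), rho (kg/m^3), r (m).
    """
    p = params if params is not None else MoensKortewegParams(**kwargs)
    return float(np.sqrt(p.E * p.h / (2.0 * p.rho * p.r)))
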