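"""Wall material characterization from tensile stress-strain data.

Nominal wall stress under luminal pressure is approximated by the thin-wall
(Laplace) relation sigma = P r / h_wall. The incremental stiffness of a
non-linear material is summarized by the tangent modulus E_t = d sigma /
d epsilon evaluated at an operating stress, here computed from a local
quadratic fit around the operating point for noise robustness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StressStrainCurve", "nominal_stress", "tangent_modulus", "MMHG_TO_PA"]

MMHG_TO_PA = 133.322


@dataclass
class StressStrainCurve:
    """Uniaxial stress-strain samples (strain unitless, stress Pa)."""

    strain: np.ndarray
    stress: np.ndarray
    sample_id: str | None = None

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or len(self.strain) < 3:
            raise ValueError("need >= 3 matched strain/stress samples")
        if np.any(np.diff(self.strain) <= 0):
            raise ValueError("strain must be strictly increasing")


def nominal_stress(P: float, r: float, h: float, pressure_unit: str) -> float:
    """Thin-wall nominal stress sigma = P r / h in Pa.

    ``P`` is the luminal pressure in the given unit ('mmHg' or 'Pa');
    ``r`` the lumen radius and ``h`` the wall thickness, both in meters.
    """
    if pressure_unit not in ("mmHg", "Pa"):
        raise ValueError("pressure_unit must be 'mmHg' or 'Pa'")
    if P < 0:
        raise ValueError("pressure must be non-negative")
    if r <= 0 or h <= 0:
        raise ValueError("radius and wall thickness must be positive")
    p_pa = P * MMHG_TO_PA if pressure_unit == "mmHg" else P
    return p_pa * r / h


def tangent_modulus(
    curve: StressStrainCurve,
    sigma_eval: float,
    window: float = 0.02,
) -> float:
    """Tangent modulus E_t = d sigma / d epsilon at a given stress, in Pa.

    The operating strain is located by monotone interpolation of the curve
    at ``sigma_eval``; the derivative is taken from a local quadratic fit
    over a symmetric strain window (default +/- 0.02 strain) around it.
    Raises if ``sigma_eval`` lies outside the sampled stress range or the
    curve is not monotone around the operating point.
    """
    strain, stress = curve.strain, curve.stress
    if not (stress.min() <= sigma_eval <= stress.max()):
        raise ValueError("sigma_eval outside the sampled stress range")
    if np.any(np.diff(stress) <= 0):
        # tolerate global non-monotonicity only away from the operating point
        raise ValueError("stress must increase monotonically with strain")
    eps_star = float(np.interp(sigma_eval, stress, strain))
    lo, hi = eps_star - window, eps_star + window
    sel = (strain >= lo) & (strain <= hi)
    if sel.sum() < 3:
        # widen to the 3 nearest samples for sparse curves
        nearest = np.argsort(np.abs(strain - eps_star))[:3]
        sel = np.zeros_like(sel)
        sel[nearest] = True
    coeff = np.polyfit(strain[sel] - eps_star, stress[sel], 2)
    return float(coeff[1])  # d sigma / d eps at eps_star
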