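"""Eddy-current-like background phase (velocity offset) correction.

Phase-contrast velocity data carry spatially slowly-varying spurious
offsets. Following standard practice, each velocity component's
time-averaged value over a static-material region (the ballistics gel in
the emulated experiment) is fitted by a first-order polynomial in the
physical coordinates, a + b x + c y + d z, and the fitted plane is
subtracted from every frame everywhere. Offsets are modeled as
time-stationary; a per-frame variant is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import VelocityField4D

__all__ = ["LinearOffsetModel", "eddy_current_correct"]


@dataclass
class LinearOffsetModel:
    """Fitted linear offset planes, one row of (a, bx, by, bz) per component.

    Intercepts in cm/s, gradients in cm/s per mm; ``residual_rms`` is the
    post-fit RMS over the static region per component (cm/s).
    """

    coefficients: np.ndarray  # (3, 4)
    residual_rms: np.ndarray  # (3,)
    n_static_voxels: int

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).reshape(3, 4)
        self.residual_rms = np.asarray(self.residual_rms, dtype=float)
        if np.any(self.residual_rms < 0):
            raise ValueError("residual RMS must be non-negative")

    def evaluate(self, points_mm: np.ndarray) -> np.ndarray:
        """Offset planes at world points: (npts, 3) cm/s."""
        p = np.atleast_2d(points_mm)
        design = np.column_stack([np.ones(len(p)), p])
        return design @ self.coefficients.T


def eddy_current_correct(
    field: VelocityField4D,
    static_mask: np.ndarray,
    per_frame: bool = False,
) -> tuple[VelocityField4D, LinearOffsetModel]:
    """Fit and subtract spatially linear velocity offsets from static tissue.

    Parameters
    ----------
    field : velocity field to correct.
    static_mask : boolean (nx, ny, nz) mask of static material, disjoint
        from the lumen. Must be nonempty; fewer than 50 voxels warns.
    per_frame : fit and subtract a separate plane per frame instead of the
        default single fit on the time-averaged field.

    Returns the corrected field and the fitted ``LinearOffsetModel`` (for
    ``per_frame=True`` the model holds the time-mean coefficients).
    """
    static_mask = np.asarray(static_mask).astype(bool)
    if static_mask.shape != field.shape:
        raise ValueError("static mask shape does not match the field")
    n_static = int(static_mask.sum())
    if n_static == 0:
        raise ValueError("static mask is empty")
    if n_static < 50:
        warnings.warn(
            f"only {n_static} static voxels; offset fit may be unstable", stacklevel=2
        )
    idx = np.argwhere(static_mask)
    pts = idx * field.spacing + field.origin
    design = np.column_stack([np.ones(len(pts)), pts])
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("degenerate static region (rank-deficient linear fit)")

    nx, ny, nz = field.shape
    grid = np.stack(
        np.meshgrid(
            np.arange(nx) * field.spacing[0] + field.origin[0],
            np.arange(ny) * field.spacing[1] + field.origin[1],
            np.arange(nz) * field.spacing[2] + field.origin[2],
            indexing="ij",
        ),
        axis=-1,
    )  # (nx, ny, nz, 3)
    full_design = np.concatenate(
        [np.ones(grid.shape[:3] + (1,)), grid], axis=-1
    )  # (nx, ny, nz, 4)

    corrected = field.data.astype(np.float64, copy=True)
    if per_frame:
        coeffs_all = np.zeros((field.n_frames, 3, 4))
        for k in range(field.n_frames):
            for c in range(3):
                v = field.data[:, :, :, k, c][static_mask]
                beta, *_ = np.linalg.lstsq(design, v, rcond=None)
                coeffs_all[k, c] = beta
                corrected[:, :, :, k, c] -= full_design @ beta
        coeffs = coeffs_all.mean(axis=0)
    else:
        coeffs = np.zeros((3, 4))
        vmean = field.data.mean(axis=3)  # time average
        for c in range(3):
            v = vmean[..., c][static_mask]
            beta, *_ = np.linalg.lstsq(design, v, rcond=None)
            coeffs[c] = beta
            corrected[:, :, :, :, c] -= (full_design @ beta)[..., None]
    res = corrected.mean(axis=3)[static_mask]  # (n_static, 3) time-mean residual
    rms = np.sqrt(np.mean(res**2, axis=0))
    model = LinearOffsetModel(coeffs, rms, n_static)
    out = VelocityField4D(
        corrected.astype(field.data.dtype),
        field.spacing.copy(),
        field.frame_ms,
        field.venc,
        field.origin.copy(),
    )
    return out, model
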