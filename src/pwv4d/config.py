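"""Schema-validated run configuration.

Every stage's parameters live in one nested, strictly-validated model
(unknown keys are rejected before anything runs) and every stochastic
stage carries an explicit seed that is recorded in the run report.
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "InflowConfig",
    "PhantomConfig",
    "CorrectionConfig",
    "SegmentationConfig",
    "PlanesConfig",
    "PWVConfig",
    "RunConfig",
    "load_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InflowConfig(_Strict):
    stroke_volume_ml: float = 71.2
    rr_ms: float = 1000.0
    peak_cap_mlps: Optional[float] = 300.0
    systole_onset_ms: float = 50.0
    systole_duration_ms: float = 500.0
    lobe_amplitude: float = 0.15
    lobe_time_frac: float = 0.66
    lobe_width_ms: float = 150.0
    dt_wave_ms: float = 10.0


class PhantomConfig(_Strict):
    length_mm: float = 250.0
    radius_inlet_mm: float = 18.0
    radius_outlet_mm: float = 10.0
    grid_spacing_mm: float = 2.5
    pwv_true_mps: float = 6.0
    compliance_alpha: float = 0.06
    profile: Literal["parabolic", "plug"] = "parabolic"
    noise_sd_cmps: float = 3.0
    frame_ms: float = 20.0
    n_frames: Optional[int] = None
    venc_cmps: float = 120.0
    static_offset_coeffs: Optional[list[list[float]]] = None  # (3, 4)
    damping_length_mm: Optional[float] = 648.0
    bend_radius_mm: Optional[float] = None
    spgr_spacing_mm: float = 1.0
    seed: int = 0


class CorrectionConfig(_Strict):
    enabled: bool = True
    per_frame: bool = False


class SegmentationConfig(_Strict):
    threshold_fraction: float = 0.5
    seed_point: Optional[tuple[int, int, int]] = None  # None: brightest voxel


class PlanesConfig(_Strict):
    spacing_mm: float = 5.0
    landmarks: dict[str, float] = Field(
        default_factory=lambda: {"LSA": 0.1, "outlet": 0.9}
    )
    segment: tuple[str, str] = ("LSA", "outlet")
    grid_step_mm: Optional[float] = None  # None: half the voxel spacing


class PWVConfig(_Strict):
    dense_dt_ms: float = 1.0
    r2_min: float = 0.3
    ransac_n_iter: int = 1000
    ransac_threshold_ms: Optional[float] = None
    seed: int = 0


class RunConfig(_Strict):
    inflow: InflowConfig = Field(default_factory=InflowConfig)
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    correction: CorrectionConfig = Field(default_factory=CorrectionConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    planes: PlanesConfig = Field(default_factory=PlanesConfig)
    pwv: PWVConfig = Field(default_factory=PWVConfig)
    save_volumes: bool = True
    area_series: bool = True
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"


def load_config(path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)
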