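"""Shared fixtures: inflow waveforms, phantoms, and cached analysis chains."""

from __future__ import annotations

import warnings
from types import SimpleNamespace

import numpy as np
import pytest

from pwv4d import (
    ImageVolume,
    InflowWaveform,
    LumenMask,
    PhantomSpec,
    make_inflow_waveform,
    synthesize_phantom,
    synthesize_spgr,
)
from pwv4d.geometry import (
    auto_seed_point,
    extract_centerline,
    extract_cross_section,
    orient_centerline_by_flow,
    plane_sequence,
    segment_lumen,
)
from pwv4d.hemometrics import flow_rate_waveform

LANDMARKS = {"LSA": 0.1, "outlet": 0.9}


@pytest.fixture(scope="session")
def pump_inflow():
    """The programmed pump waveform: 71.2 mL stroke volume, 300 mL/s cap."""
    return make_inflow_waveform(71.2, 1000.0, 300.0)


@pytest.fixture(scope="session")
def steady_inflow():
    """Constant 71.2 mL/s inflow (steady-flow acquisition conditions)."""
    t = np.arange(0.0, 1000.0, 10.0)
    return InflowWaveform(t, np.full_like(t, 71.2), 1000.0, 71.2, 71.2)


_CHAIN_CACHE: dict = {}


@pytest.fixture(scope="session")
def analysis_chain(pump_inflow):
    """Factory running phantom -> segment -> centerline -> planes -> waveforms.

    Results are cached per parameter set for reuse across tests.
    """

    def run(inflow=None, plane_spacing=5.0, **spec_kwargs) -> SimpleNamespace:
        inflow = inflow if inflow is not None else pump_inflow
        key = (id(inflow), plane_spacing, tuple(sorted(spec_kwargs.items())))
        if key in _CHAIN_CACHE:
            return _CHAIN_CACHE[key]
        spec = PhantomSpec(**spec_kwargs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            magnitude, field, truth = synthesize_phantom(spec, inflow)
            spgr = synthesize_spgr(spec)
            seed_pt = auto_seed_point(spgr)
            mask = segment_lumen(spgr, seed_pt)
            cl = orient_centerline_by_flow(
                extract_centerline(mask), field, landmarks=LANDMARKS
            )
            sections = [
                extract_cross_section(mask, p)
                for p in plane_sequence(cl, plane_spacing, ("LSA", "outlet"))
            ]
            waveforms = []
            for i, sec in enumerate(sections):
                w = flow_rate_waveform(field, sec)
                w.plane_id = i
                waveforms.append(w)
        out = SimpleNamespace(
            spec=spec,
            spgr=spgr,
            magnitude=magnitude,
            field=field,
            truth=truth,
            mask=mask,
            centerline=cl,
            sections=sections,
            waveforms=waveforms,
        )
        _CHAIN_CACHE[key] = out
        return out

    return run


def make_cylinder_volume(
    radius: float = 10.0,
    length: float = 100.0,
    spacing: float = 1.25,
    center_xy: tuple[float, float] = (0.33, 0.41),
    intensity: float = 100.0,
) -> SimpleNamespace:
    """Analytic partial-volume cylinder magnitude and its exact voxelization.

    A generic (off-voxel) axis position avoids grid-aligned resonance in
    the voxelization. Returns the magnitude ImageVolume, the exact
    voxel-center mask, the seed voxel, and the geometry parameters.
    """
    cx, cy = center_xy
    nxy = int(2 * (radius + 8) / spacing) | 1
    nz = int(round(length / spacing))
    xs = (np.arange(nxy) - (nxy - 1) / 2) * spacing
    zs = (np.arange(nz) + 0.5) * spacing
    origin = np.array([xs[0], xs[0], zs[0]])
    off = (np.arange(3) - 1) / 3 * spacing
    frac = np.zeros((nxy, nxy))
    for ox in off:
        for oy in off:
            frac += (xs[:, None] + ox - cx) ** 2 + (xs[None, :] + oy - cy) ** 2 < radius**2
    frac /= 9.0
    data = np.broadcast_to((intensity * frac)[:, :, None], (nxy, nxy, nz)).copy()
    exact = np.broadcast_to(
        ((xs[:, None] - cx) ** 2 + (xs[None, :] - cy) ** 2 < radius**2)[:, :, None],
        (nxy, nxy, nz),
    )
    seed = (int(round((cx - xs[0]) / spacing)), int(round((cy - xs[0]) / spacing)), nz // 2)
    return SimpleNamespace(
        volume=ImageVolume(data, [spacing] * 3, origin),
        exact_mask=exact,
        seed=seed,
        radius=radius,
        length=length,
        spacing=spacing,
        center=np.array([cx, cy]),
    )


@pytest.fixture(scope="session")
def cylinder():
    return make_cylinder_volume()


@pytest.fixture(scope="session")
def cylinder_mask(cylinder) -> LumenMask:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return segment_lumen(cylinder.volume, cylinder.seed)
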