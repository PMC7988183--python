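"""Flow integration, velocity statistics, area change, and flow splits."""

import numpy as np
import pytest

from pwv4d.core import FlowWaveform, SectionPlane, VelocityField4D
from pwv4d.geometry import extract_cross_section
from pwv4d.hemometrics import (
    area_change_series,
    flow_rate_waveform,
    flow_split,
    net_flow,
    velocity_stats,
)
from pwv4d.phantom import resample_temporal


def _cylinder_field(
    profile, vmax=10.0, radius=10.0, spacing=2.0, n=19, nz=60, frames=4,
    center=(0.33, 0.41),
):
    """Analytic axial velocity field in a cylinder of given radius (mm).

    The axis matches the off-voxel position of the shared cylinder fixture.
    """
    xs = (np.arange(n) - (n - 1) / 2) * spacing
    rho2 = (xs[:, None] - center[0]) ** 2 + (xs[None, :] - center[1]) ** 2
    if profile == "uniform":
        # uniform stream fills the volume; the section mask bounds the lumen
        v = np.full_like(rho2, vmax)
    elif profile == "parabolic":
        v = np.where(rho2 < radius**2, vmax * (1 - rho2 / radius**2), 0.0)
    else:
        raise ValueError(profile)
    data = np.zeros((n, n, nz, frames, 3), dtype=np.float64)
    data[..., 2] = v[:, :, None, None]
    origin = np.array([xs[0], xs[0], 0.0])
    return VelocityField4D(data, [spacing] * 3, 20.0, 200.0, origin)


@pytest.fixture(scope="module")
def disc_section(cylinder_mask):
    p = SectionPlane(
        center=np.array([0.33, 0.41, 50.0]), normal=np.array([0.0, 0.0, 1.0]), s=0.0
    )
    return extract_cross_section(cylinder_mask, p)


class TestFlowRateWaveform:
    def test_uniform_flow_closed_form(self, disc_section):
        """v = 10 cm/s through a 10 mm disc: Q = 10 * pi cm^3/s = 31.4 mL/s."""
        field = _cylinder_field("uniform")
        w = flow_rate_waveform(field, disc_section)
        assert np.all(np.abs(w.flow_mlps / (10 * np.pi) - 1) < 0.02)

    def test_poiseuille_flow_closed_form(self, disc_section):
        """Parabolic profile: Q = (vmax / 2) * A."""
        field = _cylinder_field("parabolic", vmax=20.0)
        w = flow_rate_waveform(field, disc_section)
        expected = 0.5 * 20.0 * np.pi * 10.0**2 * 1e-2  # cm/s * mm^2 * 1e-2
        assert np.all(np.abs(w.flow_mlps / expected - 1) < 0.02)

    def test_in_plane_velocity_contributes_nothing(self, disc_section):
        field = _cylinder_field("uniform")
        field.data[..., 0] = field.data[..., 2]  # move flow into x
        field.data[..., 2] = 0.0
        w = flow_rate_waveform(field, disc_section)
        assert np.abs(w.flow_mlps).max() < 1e-9


class TestNetFlow:
    def test_constant_flow_integrates_exactly(self):
        w = FlowWaveform(np.arange(10.0, 1000.0, 20.0), np.full(50, 71.2), RR=1000.0)
        assert net_flow(w) == pytest.approx(71.2)

    def test_antisymmetric_flow_integrates_to_zero(self):
        q = np.concatenate([np.full(25, 3.0), np.full(25, -3.0)])
        w = FlowWaveform(np.arange(10.0, 1000.0, 20.0), q, RR=1000.0)
        assert net_flow(w) == pytest.approx(0.0, abs=1e-12)

    def test_phantom_inlet_net_flow_matches_stroke_volume(self, analysis_chain):
        c = analysis_chain(compliance_alpha=0.0, damping_length=None, noise_sd=0.0)
        assert net_flow(c.waveforms[0]) == pytest.approx(71.2, rel=0.02)

    def test_single_frame_rejected(self):
        w = FlowWaveform(np.array([10.0]), np.array([5.0]), RR=1000.0)
        with pytest.raises(ValueError, match="2 frames"):
            net_flow(w)


class TestVelocityStats:
    def test_uniform_profile_mean_equals_max(self, disc_section):
        field = _cylinder_field("uniform")
        st = velocity_stats(field, disc_section)
        assert np.allclose(st.mean_speed, st.max_speed, rtol=1e-6)
        assert st.max_speed[0] == pytest.approx(10.0, rel=0.02)

    def test_poiseuille_max_twice_mean(self, disc_section):
        field = _cylinder_field("parabolic", vmax=20.0)
        st = velocity_stats(field, disc_section)
        assert st.max_speed[0] == pytest.approx(2 * st.mean_speed[0], rel=0.05)

    def test_empty_contour_rejected(self, disc_section):
        field = _cylinder_field("uniform")
        empty = SectionPlane(
            center=disc_section.center,
            normal=disc_section.normal,
            s=0.0,
            grid_step=disc_section.grid_step,
            extent=disc_section.extent,
            u=disc_section.u,
            v=disc_section.v,
            offsets=disc_section.offsets,
            lumen=np.zeros_like(disc_section.lumen),
            fraction=disc_section.fraction,
        )
        with pytest.raises(ValueError, match="empty"):
            velocity_stats(field, empty)


class TestAreaChangeSeries:
    def test_relative_change_zero_at_reference_frame(self, analysis_chain):
        c = analysis_chain(noise_sd=0.0)
        series = area_change_series(c.magnitude, c.sections[len(c.sections) // 2])
        assert series.relative_change[0] == 0.0

    def test_compliant_phantom_exceeds_five_percent(self, analysis_chain):
        c = analysis_chain(noise_sd=0.0)
        series = area_change_series(c.magnitude, c.sections[len(c.sections) // 2])
        assert series.peak_relative_change > 0.05

    def test_contour_loss_flags_frame_and_continues(self, analysis_chain):
        c = analysis_chain(noise_sd=0.0)
        mag = c.magnitude
        broken = type(mag)(
            mag.data.copy(), mag.spacing, mag.origin, frame_ms=mag.frame_ms
        )
        broken.data[..., 3] = 0.0  # contour vanishes in frame 3
        with pytest.warns(UserWarning, match="contour lost"):
            series = area_change_series(broken, c.sections[len(c.sections) // 2])
        assert series.flagged_frames[3]
        assert np.isnan(series.relative_change[3])
        assert not series.flagged_frames[0]

    def test_two_frames_required(self, analysis_chain):
        c = analysis_chain(noise_sd=0.0)
        with pytest.raises(ValueError, match="2 frames"):
            area_change_series(c.magnitude.time_mean(), c.sections[0])


class TestFlowSplit:
    def test_printed_descending_aorta_split(self):
        out = flow_split([48.5], 71.2)
        assert out["shares_percent"][0] == 68.0

    def test_identity_split(self):
        out = flow_split([71.2], 71.2)
        assert out["shares_percent"][0] == 100.0
        assert out["residual_ml"] == pytest.approx(0.0)

    def test_symmetric_split(self):
        out = flow_split([30.0, 30.0], 60.0)
        assert np.allclose(out["shares_percent"], [50.0, 50.0])
        assert out["residual_ml"] == pytest.approx(0.0)

    def test_negative_outlet_flagged(self):
        out = flow_split([-5.0, 70.0], 71.2)
        assert out["negative_flagged"][0]
        assert not out["negative_flagged"][1]

    def test_nonpositive_inlet_rejected(self):
        with pytest.raises(ValueError):
            flow_split([10.0], 0.0)


class TestTemporalDownsamplingEffects:
    def test_plane_position_independence_rigid_steady(
        self, steady_inflow, analysis_chain
    ):
        c = analysis_chain(
            inflow=steady_inflow,
            compliance_alpha=0.0,
            damping_length=None,
            noise_sd=0.0,
            n_frames=3,
        )
        nets = [net_flow(w) for w in c.waveforms]
        assert (max(nets) - min(nets)) / np.mean(nets) < 0.02

    def test_peak_flow_and_velocity_attenuate_with_coarser_frames(self, analysis_chain):
        """Boxcar averaging can only reduce the systolic peak."""
        c = analysis_chain(noise_sd=0.0)
        sec = c.sections[len(c.sections) // 2]
        f20 = c.field
        f40 = resample_temporal(f20, 40.0)
        f100 = resample_temporal(f20, 100.0)
        peaks_q, peaks_v = [], []
        for f in (f20, f40, f100):
            peaks_q.append(flow_rate_waveform(f, sec).flow_mlps.max())
            peaks_v.append(velocity_stats(f, sec).max_speed.max())
        assert peaks_q[0] >= peaks_q[1] >= peaks_q[2]
        assert peaks_v[0] >= peaks_v[1] >= peaks_v[2]
        assert peaks_q[2] < peaks_q[0]

    def test_net_flow_invariant_under_downsampling(self, analysis_chain):
        c = analysis_chain(noise_sd=0.0)
        sec = c.sections[len(c.sections) // 2]
        n20 = net_flow(flow_rate_waveform(c.field, sec))
        n100 = net_flow(flow_rate_waveform(resample_temporal(c.field, 100.0), sec))
        assert n100 == pytest.approx(n20, rel=0.03)
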