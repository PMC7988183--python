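"""Time-to-foot, TTF regression (LSE and RANSAC), and Moens-Korteweg."""

import numpy as np
import pytest

from pwv4d.core import FlowWaveform
from pwv4d.pwv import (
    MoensKortewegParams,
    TTFSeries,
    fit_pwv_lse,
    fit_pwv_ransac,
    moens_korteweg,
    time_to_foot,
    ttf_series,
)


def _pulse_waveform(t0=100.0, ts=300.0, dt=20.0, span=1000.0, amp=250.0):
    """Cosine-squared systolic pulse with analytic foot at t0."""
    t = np.arange(0.0, span, dt)
    q = np.zeros_like(t)
    m = (t >= t0) & (t < t0 + ts)
    q[m] = amp * np.sin(np.pi * (t[m] - t0) / ts) ** 2
    return FlowWaveform(t, q, RR=span)


def _band_fit_oracle(t, q):
    """Independent 20-80 % upslope x-intercept on an already-dense signal."""
    ip = int(np.argmax(q))
    lo, hi = 0.2 * q[ip], 0.8 * q[ip]
    i_lo = np.where(q[: ip + 1] <= lo)[0][-1]
    i_hi = i_lo + np.where(q[i_lo : ip + 1] >= hi)[0][0]
    sel = slice(i_lo, i_hi + 1)
    use = (q[sel] >= lo) & (q[sel] <= hi)
    A = np.vstack([t[sel][use], np.ones(use.sum())]).T
    (b, a), *_ = np.linalg.lstsq(A, q[sel][use], rcond=None)
    return -a / b


class TestTimeToFoot:
    def test_linear_ramp_foot_is_exact(self):
        t = np.arange(0.0, 301.0, 1.0)
        q = np.maximum(0.0, 2.0 * (t - 100.0))
        res = time_to_foot(FlowWaveform(t, q), dense_dt=1.0)
        # dense grid coincides with the samples: band points lie exactly on
        # the ramp, so the intercept is the analytic foot
        assert res.ttf_ms == pytest.approx(100.0, abs=1e-9)

    def test_translation_equivariance(self):
        w = _pulse_waveform()
        base = time_to_foot(w).ttf_ms
        shifted = time_to_foot(w.shifted(17.0)).ttf_ms
        assert shifted - base == pytest.approx(17.0, abs=1e-9)

    def test_coarse_sampling_matches_fine_grid_oracle_within_1ms(self):
        t0, ts = 100.0, 300.0
        coarse = time_to_foot(_pulse_waveform(t0, ts, dt=20.0)).ttf_ms
        tf = np.arange(0.0, 1000.0, 0.01)
        qf = np.zeros_like(tf)
        m = (tf >= t0) & (tf < t0 + ts)
        qf[m] = 250.0 * np.sin(np.pi * (tf[m] - t0) / ts) ** 2
        oracle = _band_fit_oracle(tf, qf)
        assert abs(coarse - oracle) < 1.0

    def test_amplitude_invariance(self):
        w = _pulse_waveform()
        scaled = FlowWaveform(w.time_ms, 3.7 * w.flow_mlps, RR=w.RR)
        assert time_to_foot(scaled).ttf_ms == pytest.approx(
            time_to_foot(w).ttf_ms, abs=1e-9
        )

    @pytest.mark.parametrize(
        "flow, msg",
        [
            (np.zeros(50), "not positive"),
            (np.full(50, 5.0), "20 %"),
            (-np.ones(50), "not positive"),
        ],
    )
    def test_degenerate_waveforms_rejected(self, flow, msg):
        w = FlowWaveform(np.arange(0.0, 1000.0, 20.0), flow, RR=1000.0)
        with pytest.raises(ValueError, match=msg):
            time_to_foot(w)

    def test_too_few_frames_rejected(self):
        w = FlowWaveform(np.array([0.0, 20.0, 40.0]), np.array([0.0, 1.0, 2.0]))
        with pytest.raises(ValueError, match="4 frames"):
            time_to_foot(w)

    def test_diagnostics_report_band(self):
        res = time_to_foot(_pulse_waveform())
        assert res.t20_ms < res.t80_ms
        assert res.upslope_mlps_per_ms > 0
        assert res.n_band >= 2


def _line_series(n=21, slope=0.2, intercept=40.0, ds=5.0):
    s = np.arange(n) * ds
    return TTFSeries(s, intercept + slope * s)


class TestLSEFit:
    def test_exact_line_inverts_slope_to_wave_speed(self):
        """A 0.2 ms/mm TTF slope is a 5 m/s wave: mm/ms = m/s, no factors."""
        est = fit_pwv_lse(_line_series())
        assert est.valid
        assert est.pwv_mps == pytest.approx(5.0, abs=1e-9)
        assert est.r2 == pytest.approx(1.0)
        assert len(est.outlier_indices) == 0

    def test_gross_outlier_excluded_by_deviation_rule(self):
        ser = _line_series()
        ttf = ser.ttf_ms.copy()
        ttf[7] += 1e5
        ser = TTFSeries(ser.s_mm, ttf)
        est = fit_pwv_lse(ser)
        assert list(est.outlier_indices) == [7]
        assert est.pwv_mps == pytest.approx(5.0, rel=1e-6)

    def test_flat_ttf_relation_withholds_pwv(self):
        """No TTF-distance slope: the estimate is reported as invalid."""
        ser = TTFSeries(np.arange(21) * 5.0, np.full(21, 55.0))
        est = fit_pwv_lse(ser)
        assert not est.valid
        assert est.pwv_mps is None

    def test_noisy_but_real_slope_not_over_excluded(self):
        rng = np.random.default_rng(3)
        s = np.arange(21) * 5.0
        ser = TTFSeries(s, 40.0 + 0.2 * s + rng.normal(0, 0.5, 21))
        est = fit_pwv_lse(ser)
        assert est.valid
        assert len(est.outlier_indices) == 0
        assert est.pwv_mps == pytest.approx(5.0, rel=0.1)

    def test_fewer_than_three_planes_rejected(self):
        with pytest.raises(ValueError, match="3 planes"):
            fit_pwv_lse(TTFSeries(np.array([0.0, 5.0]), np.array([1.0, 2.0])))


def _exhaustive_consensus(s, t, thr):
    """Brute-force RANSAC oracle: best 2-point consensus, then OLS refit."""
    best_inl = None
    for i in range(len(s)):
        for j in range(i + 1, len(s)):
            slope = (t[j] - t[i]) / (s[j] - s[i])
            ic = t[i] - slope * s[i]
            inl = np.abs(t - (slope * s + ic)) <= thr
            if best_inl is None or inl.sum() > best_inl.sum():
                best_inl = inl
    slope, ic = np.polyfit(s[best_inl], t[best_inl], 1)
    return slope, best_inl


class TestRANSACFit:
    def test_clean_line_matches_lse_with_no_outliers(self):
        ser = _line_series()
        est = fit_pwv_ransac(ser, seed=0)
        assert est.valid
        assert est.pwv_mps == pytest.approx(5.0, abs=1e-9)
        assert len(est.outlier_indices) == 0

    def test_matches_exhaustive_consensus_oracle(self):
        rng = np.random.default_rng(5)
        s = np.arange(21) * 5.0
        t = 40.0 + 0.2 * s + rng.normal(0, 0.3, 21)
        planted = [3, 11, 17]
        t[planted] -= 40.0  # gross negative TTF outliers
        ser = TTFSeries(s, t)
        est = fit_pwv_ransac(ser, residual_threshold=1.0, n_iter=2000, seed=1)
        slope_oracle, inl_oracle = _exhaustive_consensus(s, t, 1.0)
        assert sorted(est.outlier_indices) == sorted(np.where(~inl_oracle)[0])
        assert set(planted) <= set(est.outlier_indices)
        assert abs(est.pwv_mps - 1.0 / slope_oracle) < 0.05

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(9)
        s = np.arange(21) * 5.0
        t = 40.0 + 0.2 * s + rng.normal(0, 0.5, 21)
        t[[2, 9]] += 30.0
        ser = TTFSeries(s, t)
        a = fit_pwv_ransac(ser, seed=42)
        b = fit_pwv_ransac(ser, seed=42)
        assert a.pwv_mps == b.pwv_mps
        assert np.array_equal(a.outlier_indices, b.outlier_indices)

    def test_more_robust_than_lse_under_planted_outliers(self):
        """With <= 20 % gross outliers RANSAC beats LSE almost always."""
        wins = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            s = np.arange(21) * 5.0
            t = 40.0 + 0.2 * s + rng.normal(0, 0.5, 21)
            bad = rng.choice(21, size=4, replace=False)
            t[bad] -= 40.0
            ser = TTFSeries(s, t)
            err_l = abs(1.0 / fit_pwv_lse(ser).slope_ms_per_mm - 5.0)
            err_r = abs(1.0 / fit_pwv_ransac(ser, seed=rep).slope_ms_per_mm - 5.0)
            wins += err_r < err_l
        assert wins >= 95

    def test_consensus_too_small_rejected(self):
        # three scattered points admit no 3-point consensus at a tiny threshold
        ser = TTFSeries(np.array([0.0, 5.0, 10.0]), np.array([0.0, 30.0, -20.0]))
        with pytest.raises(ValueError, match="consensus|RANSAC"):
            fit_pwv_ransac(ser, residual_threshold=1e-6, seed=0)


class TestMoensKorteweg:
    def test_printed_compliant_model_range_endpoints(self):
        """E = 1.27 MPa, h = 2 mm, rho = 1100 kg/m^3: 8.0 m/s at the 36 mm
        ascending-aorta diameter, 10.7 m/s at the 20 mm distal diameter."""
        lo = moens_korteweg(E=1.27e6, h=2e-3, rho=1100.0, r=18e-3)
        hi = moens_korteweg(E=1.27e6, h=2e-3, rho=1100.0, r=10e-3)
        assert round(lo, 1) == 8.0
        assert round(hi, 1) == 10.7

    def test_fifteen_fold_modulus_gives_rigid_lower_bound(self):
        v = moens_korteweg(E=15 * 1.27e6, h=2e-3, rho=1100.0, r=18e-3)
        assert round(v) == 31

    def test_square_root_scaling_in_modulus(self):
        p = MoensKortewegParams(E=1.0e6, h=2e-3, rho=1100.0, r=12e-3)
        q = MoensKortewegParams(E=4.0e6, h=2e-3, rho=1100.0, r=12e-3)
        assert moens_korteweg(q) == pytest.approx(2 * moens_korteweg(p))

    @pytest.mark.parametrize("bad", [{"E": 0.0}, {"h": -1e-3}, {"rho": 0.0}, {"r": 0.0}])
    def test_nonpositive_parameters_rejected(self, bad):
        kwargs = dict(E=1e6, h=2e-3, rho=1100.0, r=1e-2) | bad
        with pytest.raises(ValueError):
            MoensKortewegParams(**kwargs)


class TestTTFSeriesAssembly:
    def test_failed_planes_are_excluded_not_fatal(self):
        good = _pulse_waveform()
        waveforms = []
        for i, s in enumerate([0.0, 5.0, 10.0, 15.0]):
            w = FlowWaveform(good.time_ms, good.flow_mlps.copy(), RR=good.RR, s=s)
            waveforms.append(w)
        waveforms[2] = FlowWaveform(
            good.time_ms, np.zeros_like(good.flow_mlps), RR=good.RR, s=10.0
        )
        ser = ttf_series(waveforms)
        assert ser.excluded[2]
        assert ser.valid_mask.sum() == 3
        assert 2 in ser.exclusion_reasons
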