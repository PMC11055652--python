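"""Tuning analyses: traces, curves, model selection, phase stats, AHV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import i0, i1

from mbody.core import LfpChannel, SpikeTrain
from mbody import tuning
from mbody.units import autocorrelogram, Autocorrelogram

from conftest import poisson_train


class TestSpeedTrace:
    @staticmethod
    def tracking_from_path(t, x, y, hd=None):
        hd = np.zeros_like(t) if hd is None else hd
        return pd.DataFrame(
            {"t": t, "x": x, "y": y,
             "x1": x + 2 * np.cos(hd), "y1": y + 2 * np.sin(hd),
             "x2": x - 2 * np.cos(hd), "y2": y - 2 * np.sin(hd),
             "hd_rad": hd, "speed_cm_s": np.zeros_like(t)}
        )

    def test_stationary_animal_zero_speed(self):
        t = np.arange(0.0, 30.0, 0.1)
        trk = self.tracking_from_path(t, np.full_like(t, 10.0), np.full_like(t, 20.0))
        _, v = tuning.speed_trace(trk)
        assert np.nanmax(v) == pytest.approx(0.0, abs=1e-9)

    def test_straight_run_constant_speed(self):
        t = np.arange(0.0, 30.0, 0.1)
        trk = self.tracking_from_path(t, 20.0 * t, np.zeros_like(t))
        _, v = tuning.speed_trace(trk)
        assert np.nanmedian(v) == pytest.approx(20.0, abs=0.5)

    def test_circular_path_speed_is_r_omega(self):
        """Geometry oracle: radius r at angular rate w -> speed r*w."""
        t = np.arange(0.0, 60.0, 0.1)
        r, w = 50.0, 0.5
        trk = self.tracking_from_path(t, r * np.cos(w * t), r * np.sin(w * t))
        _, v = tuning.speed_trace(trk)
        interior = v[50:-50]
        assert np.nanmedian(interior) == pytest.approx(r * w, rel=0.03)

    def test_long_gap_masked(self):
        t = np.concatenate([np.arange(0.0, 10.0, 0.1), np.arange(13.0, 20.0, 0.1)])
        trk = self.tracking_from_path(t, 10.0 * t, np.zeros_like(t))
        tt, v = tuning.speed_trace(trk)
        in_gap = (tt > 10.5) & (tt < 12.5)
        assert np.all(np.isnan(v[in_gap]))


class TestAhvSeries:
    def test_constant_hd_zero(self):
        t = np.arange(0.0, 20.0, 0.1)
        _, a = tuning.ahv_series(t, np.full_like(t, 1.2))
        assert np.nanmax(np.abs(a)) == pytest.approx(0.0, abs=1e-9)

    def test_linear_ramp_unit_slope(self):
        t = np.arange(0.0, 20.0, 0.1)
        tt, a = tuning.ahv_series(t, t * 1.0)  # 1 rad/s, wraps via unwrap
        interior = a[(tt > 2.0) & (tt < 18.0)]
        assert np.nanmedian(interior) == pytest.approx(1.0, abs=0.01)

    def test_sinusoidal_hd_matches_windowed_lsq_oracle(self):
        t10 = np.arange(0.0, 20.0, 0.1)
        hd = 0.8 * np.sin(2 * np.pi * 0.25 * t10)
        fs = 100.0
        tt, a = tuning.ahv_series(t10, hd, resample_fs=fs)
        # oracle: least-squares slope over the same smoothed resampled series
        hh = tuning.moving_average(np.interp(tt, t10, hd), int(0.1 * fs))
        m = int(0.4 * fs)
        j = np.arange(m) - (m - 1) / 2.0
        for i in (300, 700, 1100):
            seg = hh[i - m // 2 : i - m // 2 + m]
            slope = np.polyfit(j / fs, seg, 1)[0]
            assert a[i] == pytest.approx(slope, abs=0.02)


class TestSpeedTuningAndFit:
    def test_flat_unit_slope_ci_contains_zero(self, awake_session):
        s = awake_session
        speed = (s.truth["t_beh"], s.truth["speed"])
        curve = tuning.speed_tuning(s.trains[2], speed)  # homogeneous unit
        sel = tuning.fit_linear_sigmoid(curve)
        assert sel.p_linear > 0.001  # no confident slope
        assert sel.chosen == "none" or abs(sel.slope) < 0.05

    def test_generator_slope_recovered_within_25pct(self, awake_session):
        s = awake_session
        speed = (s.truth["t_beh"], s.truth["speed"])
        curve = tuning.speed_tuning(s.trains[1], speed)  # slope 0.2
        sel = tuning.fit_linear_sigmoid(curve)
        assert sel.slope == pytest.approx(0.2, rel=0.25)
        assert sel.p_linear < 1e-6  # robustly detected as speed modulated

    def test_low_occupancy_bin_masked(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 120.0, 0.01)
        v = np.where(t < 119.5, 10.0, 55.0)  # 0.5 s at 55 cm/s
        tr = poisson_train(5.0, 120.0, rng)
        curve = tuning.speed_tuning(tr, (t, v))
        assert not curve.valid[54]  # 54.5 cm/s bin under-occupied
        assert curve.valid[9]

    def test_exact_line_prefers_linear(self):
        x = np.arange(1.5, 41.5, 1.0)
        rng = np.random.default_rng(1)
        y = 2.0 + 0.1 * x + 0.05 * rng.standard_normal(x.size)
        curve = tuning.TuningCurve(x, y, np.full(x.size, 5.0), np.ones(x.size, bool))
        sel = tuning.fit_linear_sigmoid(curve)
        assert sel.chosen == "linear" and sel.bicw_linear > 0.5

    def test_saturating_curve_prefers_sigmoid(self):
        x = np.arange(1.5, 51.5, 1.0)
        rng = np.random.default_rng(2)
        y = tuning._sigmoid(x, 2.0, 6.0, 0.5, 25.0) + 0.1 * rng.standard_normal(x.size)
        curve = tuning.TuningCurve(x, y, np.full(x.size, 5.0), np.ones(x.size, bool))
        sel = tuning.fit_linear_sigmoid(curve)
        assert sel.chosen == "sigmoid" and sel.bicw_sigmoid > 0.5

    def test_constant_curve_not_modulated(self):
        x = np.arange(1.5, 31.5, 1.0)
        rng = np.random.default_rng(3)
        y = 4.0 + 0.01 * rng.standard_normal(x.size)
        curve = tuning.TuningCurve(x, y, np.full(x.size, 5.0), np.ones(x.size, bool))
        sel = tuning.fit_linear_sigmoid(curve)
        assert sel.p_linear > 0.05 and sel.chosen == "none"

    def test_too_few_bins_rejected(self):
        x = np.arange(1.5, 7.5, 1.0)
        curve = tuning.TuningCurve(x, x, np.full(x.size, 5.0), np.ones(x.size, bool))
        with pytest.raises(ValueError, match="valid bins"):
            tuning.fit_linear_sigmoid(curve)


class TestSpikesPerCycle:
    @staticmethod
    def cycle_table(n, period=0.125, speeds=None):
        starts = np.arange(n) * period
        return pd.DataFrame(
            {"peak_time": starts, "trough_time": starts + period / 2,
             "next_peak_time": starts + period,
             "descending_s": period / 2, "ascending_s": period / 2,
             "frequency_hz": 1.0 / period,
             "mean_speed": speeds if speeds is not None else np.full(n, 10.0)}
        )

    def test_one_spike_per_cycle_flat_at_one(self):
        n = 80
        cycles = self.cycle_table(n, speeds=np.repeat([5.0, 15.0, 25.0, 35.0], 20))
        times = cycles["peak_time"].to_numpy() + 0.01
        tr = SpikeTrain(0, times, 11.0)
        out = tuning.spikes_per_cycle(tr, cycles)
        assert np.allclose(out["mean_spikes_per_cycle"], 1.0)

    def test_empty_train_zeros(self):
        cycles = self.cycle_table(40)
        tr = SpikeTrain(0, np.array([]), 6.0)
        out = tuning.spikes_per_cycle(tr, cycles)
        assert np.allclose(out["mean_spikes_per_cycle"], 0.0)

    def test_rate_proportional_to_speed_gives_positive_slope(self, awake_session):
        s = awake_session
        from mbody import spectral

        cycles = spectral.theta_cycles(s.hpc, speed=(s.truth["t_beh"], s.truth["speed"]))
        out = tuning.spikes_per_cycle(s.trains[1], cycles)  # linear speed unit
        good = out[out["n_cycles"] >= 20]
        slope = np.polyfit(good["speed"], good["mean_spikes_per_cycle"], 1)[0]
        assert slope > 0


class TestPhases:
    @staticmethod
    def theta_channel(duration=120.0, fs=1200.0, freq=8.0, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(int(duration * fs)) / fs
        return LfpChannel(
            np.cos(2 * np.pi * freq * t) + noise * rng.standard_normal(t.size), fs, "HPC"
        )

    def test_spikes_at_peaks_have_zero_phase(self):
        ch = self.theta_channel()
        times = np.arange(1.0, 119.0, 0.125)  # exactly at cos peaks
        tr = SpikeTrain(0, times, 120.0)
        phases, dropped = tuning.spike_phases(tr, ch)
        assert dropped == 0
        assert np.abs(np.angle(np.exp(1j * phases))).mean() < 0.05

    def test_spikes_at_troughs_have_pi_phase(self):
        ch = self.theta_channel()
        times = np.arange(1.0625, 119.0, 0.125)  # at cos troughs
        tr = SpikeTrain(0, times, 120.0)
        phases, _ = tuning.spike_phases(tr, ch)
        assert np.mean(np.abs(np.abs(phases) - np.pi) < 0.1) > 0.9

    def test_generator_locked_unit_recovers_preferred_phase(self, awake_session):
        s = awake_session
        phases, _ = tuning.spike_phases(s.trains[0], s.hpc)
        _, pref = tuning.mrv(phases)
        assert abs(np.angle(np.exp(1j * (pref - np.pi / 2)))) < 0.15


class TestMrv:
    def test_identical_phases_r_one(self):
        r, pref = tuning.mrv(np.full(100, 0.7))
        assert r == pytest.approx(1.0)
        assert pref == pytest.approx(0.7)

    def test_antipodal_phases_r_zero(self):
        r, _ = tuning.mrv(np.array([0.0, np.pi] * 50))
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_sample_matches_bessel_ratio(self):
        """R of a kappa=2 von Mises sample ~ I1(2)/I0(2)."""
        rng = np.random.default_rng(5)
        phases = rng.vonmises(0.0, 2.0, size=10_000)
        r, _ = tuning.mrv(phases)
        assert r == pytest.approx(i1(2.0) / i0(2.0), abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tuning.mrv(np.array([]))

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(st.floats(-np.pi, np.pi), min_size=1, max_size=50),
        st.floats(-np.pi, np.pi),
    )
    def test_rotation_equivariance(self, phases, rot):
        """Length invariant, preferred phase equivariant under rotation."""
        phases = np.asarray(phases)
        r0, p0 = tuning.mrv(phases)
        r1, p1 = tuning.mrv(np.mod(phases + rot + np.pi, 2 * np.pi) - np.pi)
        assert 0.0 <= r0 <= 1.0 + 1e-12
        assert r1 == pytest.approx(r0, abs=1e-9)
        if r0 > 1e-6:
            assert abs(np.angle(np.exp(1j * (p1 - p0 - rot)))) < 1e-6


class TestPhaseEntrainment:
    def test_locked_unit_entrained(self, awake_session):
        s = awake_session
        ps = tuning.phase_entrainment_test(s.trains[0], s.hpc, seed=1)
        assert ps.entrained
        assert ps.shuffle_percentile > 95.0

    def test_poisson_unit_usually_not_entrained(self, awake_session):
        s = awake_session
        ps = tuning.phase_entrainment_test(s.trains[2], s.hpc, seed=2)
        assert ps.mrv < 0.1

    def test_underpowered_train_refused(self):
        ch = TestPhases.theta_channel(duration=30.0)
        tr = SpikeTrain(0, np.linspace(1.0, 29.0, 20), 30.0)
        with pytest.raises(ValueError, match="spikes"):
            tuning.phase_entrainment_test(tr, ch)


class TestThetaIndex:
    def test_cosine_modulated_acg_high_index(self):
        lags = np.arange(-499.5, 500.0, 1.0)
        counts = 1.0 + np.cos(2 * np.pi * 8.0 * lags / 1000.0)
        counts /= counts.sum()
        idx, fpk = tuning.theta_index(Autocorrelogram(lags, counts, 1.0))
        assert idx > 0.5
        assert fpk == pytest.approx(8.0, abs=1.0)

    def test_flat_acg_zero_index(self):
        lags = np.arange(-499.5, 500.0, 1.0)
        counts = np.full(lags.size, 1.0 / lags.size)
        idx, _ = tuning.theta_index(Autocorrelogram(lags, counts, 1.0))
        assert idx == 0.0

    def test_periodic_beats_poisson(self):
        rng = np.random.default_rng(6)
        jitter = rng.normal(0.0, 0.004, 480)
        periodic = SpikeTrain(0, np.sort(np.arange(480) * 0.125 + 1.0 + jitter), 62.0)
        idx_p, _ = tuning.theta_index(autocorrelogram(periodic))
        for trial in range(3):
            pois = poisson_train(8.0, 62.0, rng, unit_id=trial)
            idx_0, _ = tuning.theta_index(autocorrelogram(pois))
            assert idx_p > idx_0

    def test_jitter_null_flags_rhythmic_unit(self):
        rng = np.random.default_rng(7)
        jitter = rng.normal(0.0, 0.004, 950)
        tr = SpikeTrain(0, np.sort(np.arange(950) * 0.125 + 1.0 + jitter), 122.0)
        idx, fpk, sig = tuning.theta_index_test(tr, n_shuffle=50, seed=3)
        assert sig and fpk == pytest.approx(8.0, abs=0.5)


class TestAhvTuning:
    def test_cw_tuned_unit_classified(self, awake_session):
        s = awake_session
        ahv = tuning.ahv_series(s.truth["t_beh"], s.truth["hd"])
        res = tuning.ahv_tuning_and_test(s.trains[4], ahv, seed=4)
        assert res.classification == "CW-only"
        assert res.cw_slope < 0  # firing grows toward negative AHV

    def test_untuned_unit_classified_none(self, awake_session):
        s = awake_session
        ahv = tuning.ahv_series(s.truth["t_beh"], s.truth["hd"])
        res = tuning.ahv_tuning_and_test(s.trains[2], ahv, seed=5)
        assert res.classification == "none"

    def test_insufficient_occupancy_reports_reason(self):
        rng = np.random.default_rng(8)
        t = np.arange(0.0, 60.0, 0.01)
        a = np.full_like(t, 0.05)  # only one AHV bin ever occupied
        tr = poisson_train(5.0, 60.0, rng)
        res = tuning.ahv_tuning_and_test(tr, (t, a), seed=6)
        assert res.classification == "none"
        assert "occupancy" in res.reason


def test_speed_tuning_conserves_spike_count(awake_session):
    """Spikes attributed to valid bins never exceed the train length."""
    s = awake_session
    speed = (s.truth["t_beh"], s.truth["speed"])
    for tr in s.trains[:3]:
        curve = tuning.speed_tuning(tr, speed)
        attributed = np.nansum(curve.rate[curve.valid] * curve.occupancy[curve.valid])
        assert attributed <= tr.n_spikes + 1e-6
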