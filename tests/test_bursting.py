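"""Burst detection vs brute-force oracle, DB/SB clustering, CSI, LogIBI."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mbody.core import SpikeTrain
from mbody import bursting
from mbody.units import Autocorrelogram, autocorrelogram, logisi_histogram

from conftest import poisson_train


def make_train(times_ms, duration=10.0):
    return SpikeTrain(0, np.asarray(times_ms, dtype=float) / 1000.0, duration)


def brute_force_bursts(times, start_isi=0.006, continue_isi=0.008, min_spikes=3):
    """Independent re-statement of the scan rule, one ISI at a time."""
    bursts = []
    i = 0
    while i < len(times) - 1:
        if times[i + 1] - times[i] <= start_isi:
            members = [i, i + 1]
            j = i + 1
            while j < len(times) - 1 and times[j + 1] - times[j] <= continue_isi:
                members.append(j + 1)
                j += 1
            if len(members) >= min_spikes:
                bursts.append(members)
            i = j + 1
        else:
            i += 1
    return bursts


class TestDetectBursts:
    def test_hand_traced_open_and_extend(self):
        """ISI 5 ms opens, 7 ms extends -> one burst of three spikes."""
        bs = bursting.detect_bursts(make_train([0.0, 5.0, 12.0, 100.0]))
        assert bs.n_bursts == 1
        assert bs.n_spikes[0] == 3
        assert bs.starts[0] == pytest.approx(0.0)

    def test_seven_ms_cannot_open(self):
        bs = bursting.detect_bursts(make_train([0.0, 7.0, 14.0]))
        assert bs.n_bursts == 0

    def test_two_spike_candidate_rejected_later_burst_found(self):
        bs = bursting.detect_bursts(make_train([0.0, 5.0, 100.0, 105.0, 112.0, 119.0]))
        assert bs.n_bursts == 1
        assert bs.n_spikes[0] == 4
        assert bs.starts[0] == pytest.approx(0.100)

    def test_burst_center_is_median_spike(self):
        bs = bursting.detect_bursts(make_train([0.0, 5.0, 10.0]))
        assert bs.centers[0] == pytest.approx(0.005)

    def test_matches_brute_force_on_random_trains(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            if trial % 2:
                tr = poisson_train(30.0, 20.0, rng)
            else:
                # bursty: clustered ISIs around the rule boundaries
                isis = rng.choice(
                    [0.004, 0.0055, 0.0065, 0.0075, 0.0085, 0.05, 0.3],
                    size=200, p=[0.2, 0.15, 0.1, 0.15, 0.1, 0.15, 0.15],
                )
                t = np.cumsum(isis) + 0.01
                tr = SpikeTrain(0, t[t < 60.0], 60.0)
            if tr.n_spikes < 2:
                continue
            got = bursting.detect_bursts(tr)
            want = brute_force_bursts(tr.times)
            assert got.n_bursts == len(want)
            for k, members in enumerate(want):
                assert got.starts[k] == pytest.approx(tr.times[members[0]])
                assert got.n_spikes[k] == len(members)


class TestBurstProbability:
    def test_arithmetic(self):
        bs = bursting.BurstSet(0, np.zeros(2), np.full(2, 3), np.zeros(2), 8)
        assert bs.burst_probability == pytest.approx(0.2)

    def test_zero_bursts(self):
        bs = bursting.BurstSet(0, np.empty(0), np.empty(0, int), np.empty(0), 50)
        assert bs.burst_probability == 0.0

    def test_empty_train_undefined(self):
        bs = bursting.BurstSet(0, np.empty(0), np.empty(0, int), np.empty(0), 0)
        assert np.isnan(bs.burst_probability)

    def test_tonic_poisson_near_zero(self):
        rng = np.random.default_rng(1)
        tr = poisson_train(5.0, 300.0, rng)
        bs = bursting.detect_bursts(tr)
        assert bs.burst_probability < 0.02

    def test_monotone_adding_isolated_spike(self):
        tr = make_train([0.0, 5.0, 10.0, 500.0, 505.0, 510.0], duration=10.0)
        bs = bursting.detect_bursts(tr)
        with_extra = make_train([0.0, 5.0, 10.0, 300.0, 500.0, 505.0, 510.0], duration=10.0)
        bs2 = bursting.detect_bursts(with_extra)
        assert bs2.burst_probability <= bs.burst_probability


class TestClassifyDbSb:
    @staticmethod
    def synthetic_population(n_units, frac_bursting, duration, seed):
        from mbody.synthetic import SessionConfig, StateSchedule, UnitSpec, generate_session

        n_db = int(round(frac_bursting * n_units))
        rng = np.random.default_rng(seed)
        units = []
        for i in range(n_units):
            if i < n_db:
                units.append(UnitSpec(i, base_rate=float(rng.uniform(15.0, 30.0)),
                                      burst_mode="bursting", phase_lock=(0.0, 2.0)))
            else:
                units.append(UnitSpec(i, base_rate=float(rng.uniform(3.0, 8.0)),
                                      phase_lock=(0.0, 1.0)))
        sched = StateSchedule(((0.0, duration, "AWK"),), duration)
        cfg = SessionConfig(duration=duration, lfp_fs=600.0, schedule=sched,
                            units=tuple(units))
        s = generate_session(cfg, seed)
        truth = np.array(["DB"] * n_db + ["SB"] * (n_units - n_db))
        return s.trains, truth

    def test_quarter_bursters_recovered(self):
        trains, truth = self.synthetic_population(16, 0.25, 240.0, seed=3)
        logisis = [logisi_histogram(tr) for tr in trains]
        acgs = [autocorrelogram(tr) for tr in trains]
        bps = np.array([bursting.detect_bursts(tr).burst_probability for tr in trains])
        res = bursting.classify_db_sb(logisis, acgs, bps)
        assert np.mean(res.labels == truth) >= 0.9
        assert res.burst_prob_db > res.burst_prob_sb

    def test_permutation_invariance(self):
        trains, truth = self.synthetic_population(12, 0.25, 240.0, seed=4)
        logisis = [logisi_histogram(tr) for tr in trains]
        acgs = [autocorrelogram(tr) for tr in trains]
        bps = np.array([bursting.detect_bursts(tr).burst_probability for tr in trains])
        res = bursting.classify_db_sb(logisis, acgs, bps)
        perm = np.random.default_rng(5).permutation(len(trains))
        res_p = bursting.classify_db_sb(
            [logisis[i] for i in perm], [acgs[i] for i in perm], bps[perm])
        assert np.array_equal(res.labels[perm], res_p.labels)

    def test_all_tonic_population_warns(self):
        trains, _ = self.synthetic_population(12, 0.0, 240.0, seed=6)
        logisis = [logisi_histogram(tr) for tr in trains]
        acgs = [autocorrelogram(tr) for tr in trains]
        bps = np.array([bursting.detect_bursts(tr).burst_probability for tr in trains])
        res = bursting.classify_db_sb(logisis, acgs, bps)
        assert res.warnings  # "no burst structure"

    def test_too_few_units_refused(self):
        with pytest.raises(ValueError, match="10"):
            bursting.classify_db_sb([], [], np.array([]))


class TestCsi:
    @staticmethod
    def acg_with_peaks(a1, a2, bin_ms=0.5):
        lags = np.arange(-500.0 + bin_ms / 2, 500.0, bin_ms)
        counts = np.zeros(lags.size)
        for amp, center in ((a1, 125.0), (a2, 250.0)):
            counts += amp * np.exp(-((lags - center) ** 2) / (2 * 8.0**2))
            counts += amp * np.exp(-((lags + center) ** 2) / (2 * 8.0**2))
        counts /= counts.sum()
        return Autocorrelogram(lags, counts, bin_ms)

    def test_equal_peaks_zero(self):
        res = bursting.csi(self.acg_with_peaks(0.2, 0.2))
        assert res.csi == pytest.approx(0.0, abs=1e-6)

    def test_formula_arithmetic(self):
        res = bursting.csi(self.acg_with_peaks(0.1, 0.3))
        assert res.csi == pytest.approx((0.3 - 0.1) / 0.3, abs=0.01)

    def test_antisymmetric_under_peak_swap(self):
        a = bursting.csi(self.acg_with_peaks(0.1, 0.3))
        b = bursting.csi(self.acg_with_peaks(0.3, 0.1))
        assert a.csi == pytest.approx(-b.csi, abs=1e-9)
        assert -1.0 <= a.csi <= 1.0

    def test_sum_formula_option(self):
        res = bursting.csi(self.acg_with_peaks(0.1, 0.3), formula="sum")
        assert res.csi == pytest.approx(0.5, abs=0.01)

    def test_empty_windows_flagged(self):
        lags = np.arange(-40.0, 40.5, 0.5)
        counts = np.ones(lags.size) / lags.size
        res = bursting.csi(Autocorrelogram(lags, counts, 0.5))
        assert not res.defined


class TestLogIbi:
    @staticmethod
    def burst_set(centers):
        centers = np.asarray(centers)
        return bursting.BurstSet(0, centers, np.full(centers.size, 3), centers,
                                 3 * centers.size)

    def test_theta_period_bursts_in_theta_band(self):
        bs = self.burst_set(np.arange(0.0, 30.0, 0.125))  # 8 Hz
        res = bursting.logibi_analysis(bs)
        assert res.theta_band_integral == pytest.approx(1.0)
        assert res.half_theta_band_integral == pytest.approx(0.0)

    def test_alternate_cycle_bursts_in_half_theta_band(self):
        bs = self.burst_set(np.arange(0.0, 30.0, 0.250))  # 4 Hz
        res = bursting.logibi_analysis(bs)
        assert res.half_theta_band_integral == pytest.approx(1.0)

    def test_mixture_splits_mass(self):
        centers = [0.0]
        for k in range(200):
            centers.append(centers[-1] + (0.125 if k % 2 else 0.250))
        res = bursting.logibi_analysis(self.burst_set(centers))
        assert res.theta_band_integral == pytest.approx(0.5, abs=0.05)
        assert res.half_theta_band_integral == pytest.approx(0.5, abs=0.05)

    def test_too_few_bursts_refused(self):
        with pytest.raises(ValueError, match="bursts"):
            bursting.logibi_analysis(self.burst_set([0.0, 0.2, 0.4]))


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(0.0, 59.0), min_size=2, max_size=120, unique=True))
def test_burst_scan_equals_brute_force_property(times):
    times = np.sort(np.asarray(times))
    times = times[np.concatenate(([True], np.diff(times) > 1e-9))]
    tr = SpikeTrain(0, times, 60.0)
    got = bursting.detect_bursts(tr)
    want = brute_force_bursts(times)
    assert got.n_bursts == len(want)
    assert 0.0 <= (got.burst_probability if got.n_spikes_total else 0.0) <= 1.0
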