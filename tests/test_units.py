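"""Unit housekeeping: dedupe, rate filter, histograms, waveforms, PYR/INT."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mbody.core import SpikeTrain
from mbody import units as uprep

from conftest import poisson_train


def make_train(times, duration=10.0, unit_id=0):
    return SpikeTrain(unit_id, np.asarray(times, dtype=float), duration)


class TestDedupe:
    def test_identical_trains_drop_one(self):
        rng = np.random.default_rng(0)
        a = poisson_train(3.0, 100.0, rng, unit_id=0)
        b = SpikeTrain(1, a.times.copy(), 100.0)
        kept, removed = uprep.dedupe_units([a, b])
        assert len(kept) == 1
        assert kept[0].unit_id == 0  # tie -> lower unit_id kept
        assert removed[0]["unit_id"] == 1

    def test_disjoint_trains_both_kept(self):
        a = make_train([1.0, 2.0, 3.0])
        b = make_train([1.5, 2.5, 3.5], unit_id=1)
        kept, removed = uprep.dedupe_units([a, b])
        assert len(kept) == 2 and not removed

    def test_overlap_below_threshold_kept(self):
        # 1/25 = 4% coincidence: both survive
        a = make_train(np.arange(25) * 0.4 + 0.01, duration=11.0)
        b_times = np.arange(25) * 0.4 + 0.2
        b_times[0] = a.times[0]
        b = make_train(np.sort(b_times), duration=11.0, unit_id=1)
        kept, _ = uprep.dedupe_units([a, b])
        assert len(kept) == 2

    def test_lower_rate_member_dropped(self):
        rng = np.random.default_rng(1)
        a = poisson_train(5.0, 100.0, rng, unit_id=0)
        # b = subsample of a -> full overlap, lower rate
        b = SpikeTrain(1, a.times[::2], 100.0)
        kept, removed = uprep.dedupe_units([a, b])
        assert [tr.unit_id for tr in kept] == [0]
        assert removed[0]["unit_id"] == 1

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        trains = [poisson_train(3.0, 60.0, rng, unit_id=i) for i in range(4)]
        trains.append(SpikeTrain(9, trains[0].times.copy(), 60.0))
        once, _ = uprep.dedupe_units(trains)
        twice, removed = uprep.dedupe_units(once)
        assert [t.unit_id for t in once] == [t.unit_id for t in twice]
        assert not removed


class TestRateFilter:
    @pytest.mark.parametrize(
        "n_spikes,kept", [(599, False), (600, True), (0, False)]
    )
    def test_one_hz_boundary(self, n_spikes, kept):
        times = np.linspace(0.0, 599.0, n_spikes) if n_spikes else []
        tr = make_train(times, duration=600.0)
        assert (tr in uprep.rate_filter([tr])) == kept


class TestAutocorrelogram:
    def test_two_spike_case(self):
        acg = uprep.autocorrelogram(make_train([1.0, 1.010]))
        hot = acg.lags_ms[acg.counts > 0]
        assert hot.size == 2  # one pair at +10 ms, its mirror at -10 ms
        assert np.all(np.abs(np.abs(hot) - 10.0) <= 1.0)
        assert acg.counts[acg.counts > 0].sum() == pytest.approx(1.0)
        assert np.isclose(acg.counts.sum(), 1.0, atol=1e-9)

    def test_periodic_train_peaks_at_period_multiples(self):
        times = np.arange(0.0, 60.0, 0.125)  # 8 Hz
        acg = uprep.autocorrelogram(make_train(times, duration=60.0))
        hot = np.abs(acg.lags_ms[acg.counts > 1e-6])
        for expected in (125.0, 250.0, 375.0, 500.0):
            assert np.min(np.abs(hot - expected)) <= 1.0

    def test_matches_brute_force_enumeration(self):
        """Bin-for-bin equality with an O(n^2) pair count on small trains."""
        rng = np.random.default_rng(3)
        for trial in range(5):
            tr = poisson_train(5.0, 60.0, rng, unit_id=trial)
            if tr.n_spikes < 2 or tr.n_spikes > 500:
                continue
            acg = uprep.autocorrelogram(tr, max_lag=0.5, bin_ms=1.0)
            diffs = tr.times[:, None] - tr.times[None, :]
            diffs = diffs[np.abs(diffs) <= 0.5]
            diffs = diffs[diffs != 0.0]
            edges = np.arange(-0.5, 0.5 + 0.0005, 0.001)
            brute = np.histogram(diffs, bins=edges)[0].astype(float)
            brute /= brute.sum()
            assert np.allclose(acg.counts, brute, atol=1e-12)

    def test_poisson_train_flat_profile(self):
        """Flatness of a homogeneous train's autocorrelogram."""
        rng = np.random.default_rng(4)
        tr = poisson_train(20.0, 300.0, rng)
        acg = uprep.autocorrelogram(tr)
        # exclude zero-lag neighbourhood (refractory gap in the generator)
        m = np.abs(acg.lags_ms) > 5.0
        observed = acg.counts[m] * m.sum() / acg.counts[m].sum()
        # flat within sampling error: no normalized bin deviates wildly
        assert np.all(np.abs(observed - 1.0) < 0.5)

    def test_fewer_than_two_spikes_rejected(self):
        with pytest.raises(ValueError):
            uprep.autocorrelogram(make_train([1.0]))


class TestLogIsi:
    def test_constant_isi_concentrated_at_one_value(self):
        tr = make_train(np.arange(0.0, 5.0, 0.1), duration=5.0)
        h = uprep.logisi_histogram(tr)
        occupied = np.flatnonzero(h.mass > 0)
        # float jitter may straddle a bin edge, but never more than that
        assert occupied.size <= 2 and np.ptp(occupied) <= 1
        assert np.allclose(h.centers_s[occupied], 0.1, rtol=0.05)
        assert h.mass.sum() == pytest.approx(1.0)

    def test_burster_bimodal(self):
        """5 ms intra-burst / 150 ms inter-burst ISIs -> two occupied modes."""
        times = []
        t = 0.0
        for _ in range(100):
            times += [t, t + 0.005, t + 0.010]
            t += 0.160
        h = uprep.logisi_histogram(make_train(times, duration=20.0))
        centers = h.centers_s[h.mass > 0.05]
        assert np.any(centers < 0.01) and np.any(centers > 0.1)

    def test_out_of_range_isis_counted(self):
        tr = make_train([0.0, 20.0, 40.0], duration=60.0)  # 20 s ISIs
        h = uprep.logisi_histogram(tr)
        assert h.n_dropped == 2
        assert h.mass.sum() == 0


class TestWaveformFeatures:
    @staticmethod
    def mexican_hat(width=50, asym=0.0):
        x = np.linspace(-3.0, 3.0, width)
        w = (1 - x**2) * np.exp(-(x**2) / 2)
        if asym:
            w[x > 0] *= 1 - asym
        return w

    def test_symmetric_template_zero_asymmetry(self):
        f = uprep.waveform_features(self.mexican_hat())
        assert f.asymmetry == pytest.approx(0.0, abs=1e-6)
        assert f.waveform.max() == pytest.approx(1.0)

    def test_constructed_width(self):
        """Post-peak trough placed 10 samples (0.4 ms) after the peak."""
        w = np.zeros(50)
        w[20] = 1.0
        w[30] = -0.5
        w[10] = -0.2
        f = uprep.waveform_features(w)
        assert f.peak_trough_width_ms == pytest.approx(0.40)
        assert f.asymmetry == pytest.approx(-0.2 - (-0.5))

    def test_flat_waveform_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            uprep.waveform_features(np.ones(50))

    def test_edge_peak_rejected(self):
        w = np.linspace(0.0, 1.0, 50)
        with pytest.raises(ValueError, match="edge"):
            uprep.waveform_features(w)


class TestClassifyPyrInt:
    @staticmethod
    def population(n_pyr, n_int, seed):
        rng = np.random.default_rng(seed)
        waves, rates = [], []
        x = np.linspace(-3.0, 3.0, 50)
        for _ in range(n_pyr):
            # broad spike: slow repolarization (trough ~0.7 ms after peak)
            w = np.exp(-(x**2) / 2) - 0.6 * np.exp(-((x - 1.5) ** 2) / 1.2)
            waves.append(w + 0.02 * rng.standard_normal(50))
            rates.append(rng.uniform(0.8, 3.0))
        for _ in range(n_int):
            # narrow spike, fast trough (~0.3 ms), high rate
            w = np.exp(-(x**2) / 0.4) - 0.7 * np.exp(-((x - 0.8) ** 2) / 0.3)
            waves.append(w + 0.02 * rng.standard_normal(50))
            rates.append(rng.uniform(10.0, 25.0))
        return np.array(waves), np.array(rates)

    def test_broad_slow_vs_narrow_fast_split(self):
        correct = 0
        total = 0
        for seed in range(10):
            waves, rates = self.population(8, 4, seed)
            labels, _ = uprep.classify_pyr_int(waves, rates, seed=0)
            truth = np.array(["PYR"] * 8 + ["INT"] * 4)
            correct += int(np.sum(labels == truth))
            total += truth.size
        assert correct / total >= 0.95

    def test_too_few_units_all_pyr_with_warning(self):
        waves, rates = self.population(2, 1, 0)
        labels, warnings = uprep.classify_pyr_int(waves, rates)
        assert list(labels) == ["PYR"] * 3
        assert warnings

    def test_identical_units_single_cluster(self):
        w = self.population(1, 0, 0)[0][0]
        waves = np.tile(w, (6, 1))
        rates = np.full(6, 2.0)
        labels, warnings = uprep.classify_pyr_int(waves, rates)
        assert set(labels) == {"PYR"}
        assert any("identical" in msg for msg in warnings)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(0.001, 59.0), min_size=2, max_size=60, unique=True))
def test_histogram_normalizations_hold(times):
    tr = SpikeTrain(0, np.sort(np.asarray(times)), 60.0)
    acg = uprep.autocorrelogram(tr)
    assert np.all(acg.counts >= 0)
    total = acg.counts.sum()
    assert total == 0 or total == pytest.approx(1.0, abs=1e-9)
    h = uprep.logisi_histogram(tr)
    assert np.all(h.mass >= 0)
    assert h.mass.sum() == 0 or h.mass.sum() == pytest.approx(1.0, abs=1e-9)
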