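"""End-to-end validation benchmarks on synthetic ground truth.

Each function runs one self-contained study — oracle agreement, shuffle-test
calibration, parameter recovery, detector precision/recall, clustering
accuracy — on sessions drawn from :mod:`mbody.synthetic`, and returns a flat
dict of numbers. The test suite asserts on these; ``scripts/acceptance.py``
reports them. All randomness descends from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from . import bursting, sleep, sleep_dynamics, spectral, swr, tuning
from . import units as unit_prep
from .core import LfpChannel, SpikeTrain, EpochSet
from .synthetic import (
    SessionConfig,
    StateSchedule,
    UnitSpec,
    generate_session,
    inject_ripples,
    pink_noise,
)


def _awake(duration: float) -> StateSchedule:
    return StateSchedule(((0.0, duration, "AWK"),), duration)


def _poisson_train(rate, duration, rng, unit_id=0):
    t = np.sort(rng.uniform(0.0, duration, rng.poisson(rate * duration)))
    t = t[np.concatenate(([True], np.diff(t) > 1e-6))]
    return SpikeTrain(unit_id, t, duration)


# ---------------------------------------------------------------------------
# Burst-scan oracle agreement
# ---------------------------------------------------------------------------

def _brute_force_bursts(times, start_isi=0.006, continue_isi=0.008, min_spikes=3):
    bursts = []
    i = 0
    while i < len(times) - 1:
        if times[i + 1] - times[i] <= start_isi:
            j = i + 1
            while j < len(times) - 1 and times[j + 1] - times[j] <= continue_isi:
                j += 1
            if j - i + 1 >= min_spikes:
                bursts.append((i, j))
            i = j + 1
        else:
            i += 1
    return bursts


def burst_oracle_agreement(n_trains: int = 1000, seed: int = 0) -> dict:
    """Exact agreement of detect_bursts with a brute-force ISI scan.

    Half the trains are Poisson, half have ISIs drawn around the 6/8 ms
    rule boundaries to exercise every open/extend/reject path.
    """
    rng = np.random.default_rng(seed)
    mismatches = 0
    for k in range(n_trains):
        if k % 2:
            tr = _poisson_train(rng.uniform(5.0, 40.0), 20.0, rng)
        else:
            isis = rng.choice(
                [0.003, 0.0055, 0.0061, 0.0075, 0.0081, 0.02, 0.2],
                size=300, p=[0.2, 0.15, 0.1, 0.15, 0.1, 0.15, 0.15],
            )
            t = np.cumsum(isis)
            tr = SpikeTrain(0, t[t < 20.0], 20.0)
        if tr.n_spikes < 2:
            continue
        got = bursting.detect_bursts(tr)
        want = _brute_force_bursts(tr.times)
        ok = got.n_bursts == len(want) and all(
            np.isclose(got.starts[i], tr.times[a]) and got.n_spikes[i] == b - a + 1
            for i, (a, b) in enumerate(want)
        )
        mismatches += 0 if ok else 1
    return {"n_trains": n_trains, "n_mismatch": mismatches}


# ---------------------------------------------------------------------------
# Shuffle-test calibration on null (untuned Poisson) units
# ---------------------------------------------------------------------------

def phase_calibration(n_units: int = 500, seed: int = 0, duration: float = 300.0) -> dict:
    """False-positive rate of the theta-entrainment shuffle test."""
    rng = np.random.default_rng(seed)
    s = generate_session(SessionConfig(duration=duration, schedule=_awake(duration),
                                       units=()), seed + 1)
    interp = tuning.PhaseInterpolant(s.hpc)
    fp = 0
    for i in range(n_units):
        tr = _poisson_train(rng.uniform(1.0, 5.0), duration, rng, unit_id=i)
        ps = tuning.phase_entrainment_test(tr, interp, seed=rng)
        fp += int(ps.entrained)
    return {"n_units": n_units, "fp_rate": fp / n_units, "nominal": 0.05}


def ahv_calibration(n_units: int = 500, seed: int = 0, duration: float = 300.0) -> dict:
    """Per-direction false-positive rate of the AHV shuffle test (alpha 1%)."""
    rng = np.random.default_rng(seed)
    s = generate_session(SessionConfig(duration=duration, schedule=_awake(duration),
                                       units=()), seed + 2)
    ahv = tuning.ahv_series(s.truth["t_beh"], s.truth["hd"])
    hits = 0
    tests = 0
    for i in range(n_units):
        tr = _poisson_train(rng.uniform(2.0, 6.0), duration, rng, unit_id=i)
        res = tuning.ahv_tuning_and_test(tr, ahv, seed=rng)
        if res.reason:
            continue
        hits += int(res.cw_significant) + int(res.ccw_significant)
        tests += 2
    return {"n_tests": tests, "fp_rate": hits / tests if tests else 0.0, "nominal": 0.01}


def swr_ri_calibration(n_units: int = 500, seed: int = 0, duration: float = 600.0) -> dict:
    """Rate of positive-or-negative SWR-RI calls on unmodulated units."""
    rng = np.random.default_rng(seed)
    events = np.sort(rng.uniform(10.0, duration - 10.0, 80))
    hits = 0
    for i in range(n_units):
        tr = _poisson_train(rng.uniform(2.0, 6.0), duration, rng, unit_id=i)
        resp = sleep_dynamics.swr_ri(tr, events, seed=rng)
        hits += int(resp.classification != "ns")
    return {"n_units": n_units, "fp_rate": hits / n_units, "nominal": 0.10}


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def phase_recovery(n_units: int = 100, seed: int = 0, duration: float = 600.0) -> dict:
    """Preferred-phase recovery and entrainment power for kappa >= 2 units."""
    rng = np.random.default_rng(seed)
    n_sessions = 4
    per = n_units // n_sessions
    errs, entrained = [], []
    for k in range(n_sessions):
        units = tuple(
            UnitSpec(i, base_rate=5.0,
                     phase_lock=(float(rng.uniform(-np.pi, np.pi)),
                                 float(rng.uniform(2.0, 4.0))))
            for i in range(per)
        )
        s = generate_session(SessionConfig(duration=duration, schedule=_awake(duration),
                                           units=units), seed + 10 + k)
        interp = tuning.PhaseInterpolant(s.hpc)
        for spec, tr in zip(units, s.trains):
            ps = tuning.phase_entrainment_test(tr, interp, seed=rng)
            errs.append(abs(np.angle(np.exp(1j * (ps.preferred_phase - spec.phase_lock[0])))))
            entrained.append(ps.entrained)
    errs = np.asarray(errs)
    return {
        "n_units": len(errs),
        "mean_abs_error_rad": float(errs.mean()),
        "frac_within_0p15_rad": float(np.mean(errs <= 0.15)),
        "entrained_frac": float(np.mean(entrained)),
    }


def speed_slope_recovery(n_units: int = 20, seed: int = 0, duration: float = 900.0) -> dict:
    """Relative error of linear speed-tuning slopes (true 0.1-0.3 Hz/(cm/s))."""
    rng = np.random.default_rng(seed)
    slopes = [float(rng.uniform(0.1, 0.3)) for _ in range(n_units)]
    units = tuple(
        UnitSpec(i, base_rate=4.0, speed_model=("linear", sl, float(rng.uniform(1.0, 4.0))))
        for i, sl in enumerate(slopes)
    )
    s = generate_session(SessionConfig(duration=duration, schedule=_awake(duration),
                                       units=units), seed + 20)
    speed = (s.truth["t_beh"], s.truth["speed"])
    rel_errs = []
    for sl, tr in zip(slopes, s.trains):
        curve = tuning.speed_tuning(tr, speed)
        sel = tuning.fit_linear_sigmoid(curve)
        rel_errs.append(abs(sel.slope - sl) / sl)
    rel_errs = np.asarray(rel_errs)
    return {
        "n_units": n_units,
        "median_rel_error": float(np.median(rel_errs)),
        "frac_within_25pct": float(np.mean(rel_errs <= 0.25)),
    }


def model_selection_recovery(n_each: int = 20, seed: int = 0, duration: float = 900.0) -> dict:
    """BIC-weight wins for sigmoid-generated vs linear-generated units."""
    rng = np.random.default_rng(seed)
    sig_units = tuple(
        UnitSpec(i, base_rate=3.0,
                 speed_model=("sigmoid", float(rng.uniform(1.5, 3.0)),
                              float(rng.uniform(5.0, 9.0)),
                              float(rng.uniform(0.3, 0.7)),
                              float(rng.uniform(18.0, 30.0))))
        for i in range(n_each)
    )
    lin_units = tuple(
        UnitSpec(i, base_rate=3.0,
                 speed_model=("linear", float(rng.uniform(0.1, 0.25)),
                              float(rng.uniform(1.0, 3.0))))
        for i in range(n_each)
    )
    out = {}
    for name, units in (("sigmoid", sig_units), ("linear", lin_units)):
        s = generate_session(SessionConfig(duration=duration, schedule=_awake(duration),
                                           units=units), seed + 30 + len(name))
        speed = (s.truth["t_beh"], s.truth["speed"])
        wins = 0
        for tr in s.trains:
            curve = tuning.speed_tuning(tr, speed)
            sel = tuning.fit_linear_sigmoid(curve)
            w = sel.bicw_sigmoid if name == "sigmoid" else sel.bicw_linear
            wins += int(w > 0.5)
        out[f"{name}_bicw_win_frac"] = wins / n_each
    out["n_each"] = n_each
    return out


# ---------------------------------------------------------------------------
# SWR detection quality
# ---------------------------------------------------------------------------

def swr_detection_quality(
    n_events: int = 200, seed: int = 0, amp_sd: float = 8.0, fs: float = 1200.0
) -> dict:
    """Precision/recall for injected ripples plus the false-event rate.

    Ripples go into pink noise at ``amp_sd`` times the 150-250 Hz band SD;
    a separate 600 s ripple-free trace measures validated false events.
    """
    rng = np.random.default_rng(seed)
    duration = 600.0
    per_channel = 50
    tp = fp = fn = 0
    n_done = 0
    k = 0
    while n_done < n_events:
        ch = LfpChannel(pink_noise(int(duration * fs), rng), fs, "HPC")
        times = np.sort(rng.uniform(5.0, duration - 5.0, per_channel))
        times = times[np.concatenate(([True], np.diff(times) > 0.5))]
        ch = inject_ripples(ch, times, amp_sd=amp_sd)
        sws = EpochSet({"SWS": [(0.0, duration)]})
        events = swr.validate_ripples(swr.detect_ripples(ch, sws), ch, sws)
        det = events.valid_times()
        matched = np.zeros(det.size, dtype=bool)
        for t in times:
            d = np.abs(det - t) if det.size else np.array([np.inf])
            j = int(np.argmin(d))
            if d[j] <= 0.02 and not matched[j]:
                matched[j] = True
                tp += 1
            else:
                fn += 1
        fp += int((~matched).sum())
        n_done += times.size
        k += 1
    clean = LfpChannel(pink_noise(int(duration * fs), rng), fs, "HPC")
    sws = EpochSet({"SWS": [(0.0, duration)]})
    false_events = swr.validate_ripples(
        swr.detect_ripples(clean, sws), clean, sws).valid.sum()
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {
        "n_events": n_done,
        "precision": precision,
        "recall": recall,
        "false_valid_per_600s": int(false_events),
    }


# ---------------------------------------------------------------------------
# DB/SB clustering accuracy
# ---------------------------------------------------------------------------

def dbsb_accuracy(n_seeds: int = 50, seed: int = 0, n_units: int = 16,
                  duration: float = 240.0) -> dict:
    """Cluster-label accuracy on populations with 25% bursting units."""
    accs = []
    gap_positive = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + 100 + k)
        n_db = n_units // 4
        units = tuple(
            UnitSpec(i, base_rate=float(rng.uniform(15.0, 30.0)),
                     burst_mode="bursting", phase_lock=(0.0, 2.0))
            if i < n_db
            else UnitSpec(i, base_rate=float(rng.uniform(3.0, 8.0)),
                          phase_lock=(0.0, 1.0))
            for i in range(n_units)
        )
        s = generate_session(
            SessionConfig(duration=duration, lfp_fs=600.0,
                          schedule=_awake(duration), units=units), seed + 100 + k)
        logisis = [unit_prep.logisi_histogram(tr) for tr in s.trains]
        acgs = [unit_prep.autocorrelogram(tr) for tr in s.trains]
        bps = np.array([bursting.detect_bursts(tr).burst_probability for tr in s.trains])
        res = bursting.classify_db_sb(logisis, acgs, bps)
        truth = np.array(["DB"] * n_db + ["SB"] * (n_units - n_db))
        accs.append(float(np.mean(res.labels == truth)))
        gap_positive += int(res.burst_prob_db > res.burst_prob_sb)
    return {
        "n_seeds": n_seeds,
        "mean_accuracy": float(np.mean(accs)),
        "min_accuracy": float(np.min(accs)),
        "frac_seeds_db_gt_sb": gap_positive / n_seeds,
    }


# ---------------------------------------------------------------------------
# Cycle-skipping index signs
# ---------------------------------------------------------------------------

def csi_signs(n_sims: int = 20, seed: int = 0, duration: float = 600.0) -> dict:
    """CSI sign rates for skip probability 0.9 vs 0.0 bursting theta units."""
    out = {}
    for label, p in (("skip", 0.9), ("noskip", 0.0)):
        signs = []
        for k in range(n_sims):
            units = (UnitSpec(0, base_rate=12.0, phase_lock=(0.0, 4.0),
                              burst_mode="bursting", cycle_skip_prob=p),)
            s = generate_session(
                SessionConfig(duration=duration, schedule=_awake(duration),
                              units=units), seed + 200 + k)
            acg = unit_prep.autocorrelogram(s.trains[0], 0.5, 0.5)
            res = bursting.csi(acg)
            signs.append(res.csi)
        signs = np.asarray(signs)
        out[f"{label}_frac_correct_sign"] = float(
            np.mean(signs > 0) if p > 0 else np.mean(signs < 0))
        out[f"{label}_mean_csi"] = float(signs.mean())
    out["n_sims"] = n_sims
    return out


# ---------------------------------------------------------------------------
# Granger direction recovery and null calibration
# ---------------------------------------------------------------------------

def _var_pair(n, coupling, rng, fs=120.0):
    x = np.zeros(n)
    y = np.zeros(n)
    ex, ey = rng.standard_normal(n), rng.standard_normal(n)
    for t in range(2, n):
        x[t] = 0.55 * x[t - 1] - 0.3 * x[t - 2] + ex[t]
        y[t] = 0.4 * y[t - 1] + coupling * x[t - 1] + ey[t]
    return LfpChannel(x, fs, "HPC"), LfpChannel(y, fs, "MB")


def granger_benchmark(n_direction: int = 100, n_null: int = 1000, seed: int = 0) -> dict:
    """Theta-band GC direction on coupled pairs; significance on null pairs."""
    rng = np.random.default_rng(seed)
    correct = 0
    for _ in range(n_direction):
        x, y = _var_pair(3600, 0.6, rng)  # 30 s at 120 Hz
        res = spectral.granger_pair(x, y)
        correct += int(res.theta_peak_xy > res.theta_peak_yx)
    false_sig = 0
    for _ in range(n_null):
        x, y = _var_pair(3600, 0.0, rng)
        res = spectral.granger_pair(x, y)
        false_sig += int(res.significant_xy) + int(res.significant_yx)
    return {
        "n_direction": n_direction,
        "direction_correct_frac": correct / n_direction,
        "n_null_tests": 2 * n_null,
        "null_fp_rate": false_sig / (2 * n_null),
        "alpha": 0.001,
    }


# ---------------------------------------------------------------------------
# Sleep scoring accuracy
# ---------------------------------------------------------------------------

def sleep_scoring_accuracy(seed: int = 0, duration: float = 900.0) -> dict:
    """Window-level label accuracy against the generator schedule."""
    s = generate_session(SessionConfig(duration=duration, awake_frac=1.0 / 3.0),
                         seed + 300)
    ratio = sleep.theta_delta_ratio(s.hpc)
    labels = sleep.classify_states(ratio, (s.truth["t_beh"], s.truth["speed"]))
    mid = labels.table["window_start_s"].to_numpy() + 5.0
    truth = s.manifest.schedule.state_at(mid)
    return {
        "n_windows": len(truth),
        "accuracy": float(np.mean(labels.labels() == truth)),
    }


# ---------------------------------------------------------------------------
# Pipeline determinism
# ---------------------------------------------------------------------------

def pipeline_determinism(seed: int = 0, out_dir="scratch/determinism") -> dict:
    """Byte-compare every CSV table from two identically seeded runs."""
    from pathlib import Path

    from .config import PipelineConfig
    from .pipeline import run

    out = Path(out_dir)
    summaries = []
    for k in (1, 2):
        summaries.append(run(PipelineConfig(seed=seed), None, out / f"run{k}"))
    files = sorted(p.name for p in (out / "run1").glob("*.csv"))
    identical = all(
        (out / "run1" / f).read_bytes() == (out / "run2" / f).read_bytes()
        for f in files
    )
    return {"n_tables": len(files), "identical": bool(identical)}
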