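"""Per-unit behavioural and oscillatory tuning.

Running-speed tuning curves with linear-vs-sigmoid BIC model selection,
spikes per theta cycle, theta phase entrainment against circular-shift
shuffle nulls, MRV-vs-speed, the spectral theta index of the
autocorrelogram, and angular-head-velocity (AHV) tuning with one-sided
shuffle significance per turn direction.

All shuffle nulls circularly shift the spike train within the session so
slow rate fluctuations survive while the phase/event alignment breaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import LfpChannel, SpikeTrain, THETA_BAND, bandpass, instantaneous_phase, moving_average

SPEED_BINS = np.arange(1.0, 61.0, 1.0)  # 1 cm/s bins over 1-60
AHV_BINS = np.arange(-5.0, 5.0 + 1e-9, 0.1)  # 0.1 rad/s bins over +-5


# ---------------------------------------------------------------------------
# Behaviour traces
# ---------------------------------------------------------------------------

def speed_trace(
    tracking: pd.DataFrame,
    resample_fs: float = 100.0,
    smooth_s: float = 0.1,
    max_gap_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Running speed (cm/s) from two-LED tracking.

    Midpoint of the two LEDs (columns x1/y1/x2/y2, falling back to x/y),
    displacement rate at the native 10 Hz, then resampled and smoothed with
    a 100 ms moving average. Samples inside tracking gaps longer than
    ``max_gap_s`` are masked NaN rather than interpolated.
    """
    t = tracking["t"].to_numpy(dtype=float)
    if {"x1", "y1", "x2", "y2"}.issubset(tracking.columns):
        x = 0.5 * (tracking["x1"] + tracking["x2"]).to_numpy(dtype=float)
        y = 0.5 * (tracking["y1"] + tracking["y2"]).to_numpy(dtype=float)
    else:
        x = tracking["x"].to_numpy(dtype=float)
        y = tracking["y"].to_numpy(dtype=float)
    dt = np.diff(t)
    v = np.hypot(np.diff(x), np.diff(y)) / dt
    tv = 0.5 * (t[:-1] + t[1:])
    tt = np.arange(t[0], t[-1], 1.0 / resample_fs)
    vv = np.interp(tt, tv, v)
    # mask samples that fall inside long tracking gaps
    gap_idx = np.where(dt > max_gap_s)[0]
    for g in gap_idx:
        vv[(tt > t[g]) & (tt < t[g + 1])] = np.nan
    vv = moving_average(np.nan_to_num(vv, nan=0.0), int(round(smooth_s * resample_fs)))
    for g in gap_idx:
        vv[(tt > t[g]) & (tt < t[g + 1])] = np.nan
    return tt, vv


def ahv_series(
    hd_t: np.ndarray,
    hd_rad: np.ndarray,
    resample_fs: float = 100.0,
    smooth_s: float = 0.1,
    window_s: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Angular head velocity (rad/s) as windowed slopes of head direction.

    Head direction is unwrapped, resampled, smoothed with a 100 ms moving
    average; the AHV at each sample is the least-squares slope of HD over
    a centered 400 ms window. Edge samples whose window overruns the trace
    are NaN.
    """
    hd_u = np.unwrap(np.asarray(hd_rad, dtype=float))
    tt = np.arange(hd_t[0], hd_t[-1], 1.0 / resample_fs)
    hh = np.interp(tt, hd_t, hd_u)
    hh = moving_average(hh, int(round(smooth_s * resample_fs)))
    m = int(round(window_s * resample_fs))
    if m < 2:
        raise ValueError("AHV window shorter than 2 samples")
    j = np.arange(m) - (m - 1) / 2.0
    denom = np.sum(j**2) / resample_fs
    kernel = (j / denom)[::-1]
    slope = np.convolve(hh, kernel, mode="same")
    half = m // 2
    slope[:half] = np.nan
    slope[-half:] = np.nan
    return tt, slope


# ---------------------------------------------------------------------------
# Rate tuning curves and model selection
# ---------------------------------------------------------------------------

@dataclass
class TuningCurve:
    centers: np.ndarray
    rate: np.ndarray  # Hz; NaN where invalid
    occupancy: np.ndarray  # seconds
    valid: np.ndarray  # occupancy >= min_occupancy

    def n_valid(self) -> int:
        return int(self.valid.sum())


def _bin_tuning(
    spike_values: np.ndarray,
    trace_values: np.ndarray,
    trace_dt: float,
    bins: np.ndarray,
    min_occupancy_s: float = 1.0,
) -> TuningCurve:
    trace_values = trace_values[np.isfinite(trace_values)]
    occ = np.histogram(trace_values, bins=bins)[0] * trace_dt
    counts = np.histogram(spike_values[np.isfinite(spike_values)], bins=bins)[0]
    valid = occ >= min_occupancy_s
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(valid, counts / np.where(occ > 0, occ, np.nan), np.nan)
    centers = 0.5 * (bins[:-1] + bins[1:])
    return TuningCurve(centers, rate, occ, valid)


def speed_tuning(
    train: SpikeTrain,
    speed: tuple[np.ndarray, np.ndarray],
    bins: np.ndarray | None = None,
    min_occupancy_s: float = 1.0,
) -> TuningCurve:
    """Firing rate per 1 cm/s speed bin (1-60), bins under 1 s occupancy masked.

    Occupancy is histogrammed from the same (linearly interpolated) speed
    path used to attribute spike speeds; coarse traces are densified to
    100 Hz first, otherwise sample values over-represent excursion extrema
    and bias the upper bins downward.
    """
    st, sv = speed
    if bins is None:
        bins = SPEED_BINS
    dt = float(np.median(np.diff(st)))
    if dt > 0.02:
        finite = np.isfinite(sv)
        tt = np.arange(st[finite][0], st[finite][-1], 0.01)
        sv = np.interp(tt, st[finite], sv[finite])
        st, dt = tt, 0.01
    spike_speed = np.interp(train.times, st, sv)
    inside = (train.times >= st[0]) & (train.times <= st[-1])
    curve = _bin_tuning(spike_speed[inside], sv, dt, bins, min_occupancy_s)
    if curve.n_valid() == 0:
        raise ValueError("no speed bin reaches the occupancy minimum")
    return curve


def _sigmoid(v, a, b, k, v0):
    return a + b / (1.0 + np.exp(-np.clip(k * (v - v0), -500, 500)))


@dataclass
class ModelSelection:
    slope: float
    intercept: float
    r2_linear: float
    p_linear: float
    sigmoid_params: tuple[float, float, float, float] | None
    r2_sigmoid: float
    bicw_linear: float
    bicw_sigmoid: float
    chosen: str  # "linear" | "sigmoid" | "none"
    direction: str  # "positive" | "negative" | "flat"
    sigmoid_converged: bool


def _bic(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + k * np.log(n)


def fit_linear_sigmoid(
    curve: TuningCurve,
    alpha: float = 0.05,
    always_try_sigmoid: bool = False,
) -> ModelSelection:
    """Linear regression of rate on the binned variable, then a sigmoid.

    Following the selection sequence: the sigmoid r(v) = a + b/(1+e^{-k(v-v0)})
    is fitted (multi-start nonlinear least squares) only when the linear fit
    is significant; BIC weights from Gaussian residual likelihoods decide
    the winner. Non-significant linear fits classify the unit unmodulated.

    Both model fits and the BIC comparison weight each bin by its
    occupancy: a binned rate's sampling variance scales as 1/occupancy, so
    unweighted least squares would let the sparsely sampled tail bins
    dominate the comparison. The reported slope/intercept/p come from the
    conventional unweighted regression.
    """
    m = curve.valid & np.isfinite(curve.rate)
    x, y = curve.centers[m], curve.rate[m]
    if x.size < 8:
        raise ValueError(f"only {x.size} valid bins (need >= 8)")
    w = curve.occupancy[m].astype(float)
    w = w / w.mean() if w.sum() > 0 else np.ones_like(x)
    res = stats.linregress(x, y)
    tss = float(np.sum((y - y.mean()) ** 2))
    n = x.size

    # weighted linear fit for the model comparison
    W = np.diag(w)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    resid_lin = y - X @ beta
    wrss_lin = float(np.sum(w * resid_lin**2))
    r2_lin = 1.0 - float(np.sum(resid_lin**2)) / tss if tss > 0 else 0.0

    sig_params, wrss_sig, converged = None, np.inf, False
    if always_try_sigmoid or res.pvalue < alpha:
        span = float(np.ptp(y)) or 1.0
        sigma = 1.0 / np.sqrt(w)
        for k0 in (0.1, 0.3, 1.0):
            for v0 in (10.0, 20.0, 30.0):
                k_start = k0 if res.slope >= 0 else -k0
                try:
                    popt, _ = optimize.curve_fit(
                        _sigmoid, x, y, p0=[float(y.min()), span, k_start, v0],
                        sigma=sigma, maxfev=4000,
                    )
                except (RuntimeError, optimize.OptimizeWarning):
                    continue
                wrss = float(np.sum(w * (y - _sigmoid(x, *popt)) ** 2))
                if wrss < wrss_sig:
                    wrss_sig, sig_params, converged = wrss, tuple(popt), True
    if converged and tss > 0:
        r2_sig = 1.0 - float(np.sum((y - _sigmoid(x, *sig_params)) ** 2)) / tss
    else:
        r2_sig = 0.0

    if converged:
        bics = np.array([_bic(wrss_lin, n, 3), _bic(wrss_sig, n, 5)])
        bw = np.exp(-(bics - bics.min()) / 2.0)
        bw /= bw.sum()
        bicw_lin, bicw_sig = float(bw[0]), float(bw[1])
    else:
        bicw_lin, bicw_sig = 1.0, 0.0

    if res.pvalue >= alpha and not always_try_sigmoid:
        chosen = "none"
    else:
        chosen = "sigmoid" if bicw_sig > bicw_lin else "linear"
    if chosen == "sigmoid" and sig_params is not None:
        direction = "positive" if sig_params[1] * sig_params[2] > 0 else "negative"
    elif chosen == "linear":
        direction = "positive" if res.slope > 0 else "negative"
    else:
        direction = "flat"
    return ModelSelection(
        float(res.slope), float(res.intercept), r2_lin, float(res.pvalue),
        sig_params, r2_sig, bicw_lin, bicw_sig, chosen, direction, converged,
    )


def spikes_per_cycle(
    train: SpikeTrain, cycles: pd.DataFrame, max_speed: float = 60.0
) -> pd.DataFrame:
    """Mean spikes per theta cycle, grouped by integer-rounded cycle speed."""
    if not len(cycles):
        return pd.DataFrame(columns=["speed", "mean_spikes_per_cycle", "n_cycles"])
    starts = cycles["peak_time"].to_numpy()
    ends = cycles["next_peak_time"].to_numpy()
    n_spk = np.searchsorted(train.times, ends) - np.searchsorted(train.times, starts)
    spd = np.rint(cycles["mean_speed"].to_numpy()) if "mean_speed" in cycles else np.zeros(len(cycles))
    rows = []
    for s in np.unique(spd):
        if not (0 <= s <= max_speed):
            continue
        m = spd == s
        rows.append({"speed": s, "mean_spikes_per_cycle": float(n_spk[m].mean()),
                     "n_cycles": int(m.sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phase statistics
# ---------------------------------------------------------------------------

class PhaseInterpolant:
    """Reusable theta-phase lookup for one LFP channel.

    Precomputes the bandpass-filtered Hilbert phase so that many spike
    trains (or many circular shifts of one train) can be phased cheaply.
    Phase convention: 0 = filtered-signal peak, +-pi = trough.
    """

    def __init__(self, lfp: LfpChannel, band: tuple[float, float] = THETA_BAND):
        self.band = band
        self.t = lfp.times
        filt = bandpass(lfp.samples, lfp.fs, band)
        self.phase_unwrapped = instantaneous_phase(filt)
        self.t0, self.t1 = float(self.t[0]), float(self.t[-1])

    def __call__(self, times: np.ndarray) -> np.ndarray:
        """Wrapped phases at ``times`` (linear interpolation of unwrapped phase)."""
        phi = np.interp(times, self.t, self.phase_unwrapped)
        return np.mod(phi + np.pi, 2 * np.pi) - np.pi


def spike_phases(
    train: SpikeTrain,
    lfp: LfpChannel | PhaseInterpolant,
    band: tuple[float, float] = THETA_BAND,
) -> tuple[np.ndarray, int]:
    """Theta phase of each spike (piecewise-cubic interpolated Hilbert phase).

    Returns (phases in [-pi, pi), n_dropped outside the LFP support).
    """
    if isinstance(lfp, PhaseInterpolant):
        inside = (train.times >= lfp.t0) & (train.times <= lfp.t1)
        return lfp(train.times[inside]), int((~inside).sum())
    from .core import phase_at_times

    inside = (train.times >= lfp.t0) & (train.times <= lfp.t0 + lfp.duration)
    phases = phase_at_times(lfp, band, train.times[inside])
    return phases, int((~inside).sum())


def mrv(phases: np.ndarray) -> tuple[float, float]:
    """Mean resultant vector length and preferred phase of spike phases."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("no phases")
    c, s = np.cos(phases).mean(), np.sin(phases).mean()
    return float(np.hypot(c, s)), float(np.arctan2(s, c))


def rayleigh_z(phases: np.ndarray) -> float:
    r, _ = mrv(phases)
    return float(phases.size * r * r)


@dataclass
class PhaseStats:
    phases: np.ndarray
    mrv: float
    preferred_phase: float
    shuffle_percentile: float  # percentile of the observed MRV in the null
    entrained: bool
    rayleigh_z: float
    shuffle_mrvs: np.ndarray


def phase_entrainment_test(
    train: SpikeTrain,
    lfp: LfpChannel | PhaseInterpolant,
    n_shuffle: int = 1000,
    shift_range: tuple[float, float] = (-5.0, 5.0),
    min_spikes: int = 50,
    band: tuple[float, float] = THETA_BAND,
    seed: int | np.random.Generator = 0,
) -> PhaseStats:
    """Is the unit's theta MRV above the 95th percentile of shift nulls?

    Each of the ``n_shuffle`` nulls circularly shifts the whole train by a
    uniform draw from ``shift_range`` (wrapping within the session) and
    recomputes the MRV. Note: shifts smaller than the width of the train's
    autocorrelation leave residual locking in the null; the +-5 s default
    spans many theta cycles.
    """
    if train.n_spikes < min_spikes:
        raise ValueError(f"unit {train.unit_id}: {train.n_spikes} spikes < {min_spikes}")
    interp = lfp if isinstance(lfp, PhaseInterpolant) else PhaseInterpolant(lfp, band)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phases, _ = spike_phases(train, interp)
    r_obs, pref = mrv(phases)
    T = train.session_duration
    shifts = rng.uniform(shift_range[0], shift_range[1], size=n_shuffle)
    shifted = np.mod(train.times[None, :] + shifts[:, None], T)
    phi = interp(shifted.ravel()).reshape(n_shuffle, -1)
    c = np.cos(phi).mean(axis=1)
    s = np.sin(phi).mean(axis=1)
    null = np.hypot(c, s)
    pct = float(stats.percentileofscore(null, r_obs, kind="weak"))
    return PhaseStats(
        phases, r_obs, pref, pct, r_obs > np.quantile(null, 0.95),
        rayleigh_z(phases), null,
    )


def mrv_speed_relation(
    train: SpikeTrain,
    lfp: LfpChannel | PhaseInterpolant,
    speed: tuple[np.ndarray, np.ndarray],
    bins: np.ndarray | None = None,
    sta_window_s: float = 0.2,
    min_spikes_per_bin: int = 20,
    min_occupancy_s: float = 1.0,
) -> tuple[pd.DataFrame, stats._stats_mstats_common.LinregressResult]:
    """MRV length per running-speed bin, with a linear regression on speed.

    Each spike's speed is the mean of the speed trace in a 200 ms window
    around the spike (spike-triggered average); bins with fewer than 20
    spikes or under 1 s occupancy are masked.
    """
    if bins is None:
        bins = SPEED_BINS
    st, sv = speed
    interp = lfp if isinstance(lfp, PhaseInterpolant) else PhaseInterpolant(lfp)
    phases, _ = spike_phases(train, interp)
    inside = (train.times >= interp.t0) & (train.times <= interp.t1)
    times = train.times[inside]
    dt = float(np.median(np.diff(st)))
    half = max(1, int(round(sta_window_s / 2 / dt)))
    sv_c = np.nan_to_num(sv, nan=0.0)
    csum = np.concatenate(([0.0], np.cumsum(sv_c)))
    idx = np.clip(np.searchsorted(st, times), half, st.size - half - 1)
    spike_speed = (csum[idx + half] - csum[idx - half]) / (2 * half)
    occ = np.histogram(sv[np.isfinite(sv)], bins=bins)[0] * dt
    which = np.digitize(spike_speed, bins) - 1
    rows = []
    for b in range(bins.size - 1):
        m = which == b
        if occ[b] < min_occupancy_s or m.sum() < min_spikes_per_bin:
            continue
        r, _ = mrv(phases[m])
        rows.append({"speed": 0.5 * (bins[b] + bins[b + 1]), "mrv": r, "n_spikes": int(m.sum())})
    table = pd.DataFrame(rows, columns=["speed", "mrv", "n_spikes"])
    if len(table) < 2:
        raise ValueError(f"only {len(table)} valid speed bins: regression refused")
    reg = stats.linregress(table["speed"], table["mrv"])
    return table, reg


# ---------------------------------------------------------------------------
# Theta index
# ---------------------------------------------------------------------------

def theta_index(acg) -> tuple[float, float]:
    """Spectral theta concentration of an autocorrelogram.

    FFT of the mean-subtracted autocorrelogram; the index is the power
    within +-1 Hz of the theta-band (4-12 Hz) peak divided by the total
    power. Returns (index, peak_frequency_hz); a flat autocorrelogram
    gives (0, nan).
    """
    counts = acg.counts - acg.counts.mean()
    if not np.any(counts):
        return 0.0, float("nan")
    fs = 1000.0 / acg.bin_ms
    power = np.abs(np.fft.rfft(counts)) ** 2
    freqs = np.fft.rfftfreq(counts.size, 1.0 / fs)
    band = (freqs >= THETA_BAND[0]) & (freqs <= THETA_BAND[1])
    if not band.any() or power.sum() == 0:
        return 0.0, float("nan")
    fpk = float(freqs[band][np.argmax(power[band])])
    near = (freqs >= fpk - 1.0) & (freqs <= fpk + 1.0)
    return float(power[near].sum() / power.sum()), fpk


def theta_index_test(
    train: SpikeTrain,
    max_lag: float = 0.5,
    bin_ms: float = 1.0,
    n_shuffle: int = 200,
    jitter_s: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, bool]:
    """Theta index with a spike-time jitter null.

    Each null jitters every spike independently by U(-jitter_s, +jitter_s)
    (wrapping), which destroys rhythmicity while keeping slow rate
    structure; significant when the observed index exceeds the null's 95th
    percentile. (A whole-train circular shift leaves the autocorrelogram
    unchanged, so it cannot serve as the null here.)
    """
    from .units import autocorrelogram

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx_obs, fpk = theta_index(autocorrelogram(train, max_lag, bin_ms))
    null = np.empty(n_shuffle)
    T = train.session_duration
    for i in range(n_shuffle):
        jit = np.sort(np.mod(train.times + rng.uniform(-jitter_s, jitter_s, train.n_spikes), T))
        jit = jit[np.concatenate(([True], np.diff(jit) > 0))]
        null[i] = theta_index(autocorrelogram(
            SpikeTrain(train.unit_id, jit, T, train.region), max_lag, bin_ms))[0]
    return idx_obs, fpk, bool(idx_obs > np.quantile(null, 0.95))


# ---------------------------------------------------------------------------
# AHV tuning
# ---------------------------------------------------------------------------

@dataclass
class AhvResult:
    curve: TuningCurve
    cw_slope: float
    ccw_slope: float
    cw_null: np.ndarray
    ccw_null: np.ndarray
    cw_significant: bool
    ccw_significant: bool
    cw_significant_two_sided: bool
    ccw_significant_two_sided: bool
    classification: str  # both | CW-only | CCW-only | none
    reason: str = ""


def _side_slope(centers, rates, valid, side):
    m = valid & np.isfinite(rates)
    m &= (centers <= 0) if side == "cw" else (centers >= 0)
    if m.sum() < 2:
        return np.nan
    x, y = centers[m], rates[m]
    xc = x - x.mean()
    return float(np.sum(xc * (y - y.mean())) / np.sum(xc**2))


def ahv_tuning_and_test(
    train: SpikeTrain,
    ahv: tuple[np.ndarray, np.ndarray],
    bins: np.ndarray | None = None,
    n_shuffle: int = 500,
    shift_range: tuple[float, float] = (20.0, 100.0),
    min_occupancy_s: float = 1.0,
    min_bins: int = 5,
    alpha: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> AhvResult:
    """AHV tuning curve with per-direction shuffle significance.

    Linear regressions run separately on the clockwise (-5..0 rad/s) and
    counterclockwise (0..5 rad/s) halves of the 0.1 rad/s tuning curve.
    The null circularly shifts the train by U(20, 100) s, 500 times. The
    one-sided test takes the tail where firing grows with angular speed in
    that direction (lower tail on the negative-AHV side, upper tail on the
    positive side); two-sided outcomes are reported alongside.
    """
    if bins is None:
        bins = AHV_BINS
    at, av = ahv
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = float(np.median(np.diff(at)))
    finite = np.isfinite(av)
    occ = np.histogram(av[finite], bins=bins)[0] * dt
    valid = occ >= min_occupancy_s
    centers = 0.5 * (bins[:-1] + bins[1:])
    n_cw = int((valid & (centers <= 0)).sum())
    n_ccw = int((valid & (centers >= 0)).sum())

    def bin_rates(times: np.ndarray) -> np.ndarray:
        sval = np.interp(times, at[finite], av[finite])
        counts = np.histogram(sval, bins=bins)[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(valid, counts / np.where(occ > 0, occ, np.nan), np.nan)

    rates = bin_rates(train.times[(train.times >= at[0]) & (train.times <= at[-1])])
    curve = TuningCurve(centers, rates, occ, valid)
    if n_cw < min_bins or n_ccw < min_bins:
        return AhvResult(curve, np.nan, np.nan, np.empty(0), np.empty(0),
                         False, False, False, False, "none",
                         reason=f"insufficient occupancy ({n_cw} CW / {n_ccw} CCW bins)")

    cw = _side_slope(centers, rates, valid, "cw")
    ccw = _side_slope(centers, rates, valid, "ccw")
    T = train.session_duration
    span = at[-1] - at[0]
    cw_null = np.empty(n_shuffle)
    ccw_null = np.empty(n_shuffle)
    for i in range(n_shuffle):
        s = rng.uniform(*shift_range) % max(span, 1e-9)
        shifted = np.mod(train.times - at[0] + s, span) + at[0]
        r = bin_rates(shifted)
        cw_null[i] = _side_slope(centers, r, valid, "cw")
        ccw_null[i] = _side_slope(centers, r, valid, "ccw")
    cw_null = cw_null[np.isfinite(cw_null)]
    ccw_null = ccw_null[np.isfinite(ccw_null)]
    cw_sig = bool(cw < np.quantile(cw_null, alpha)) if cw_null.size else False
    ccw_sig = bool(ccw > np.quantile(ccw_null, 1 - alpha)) if ccw_null.size else False
    cw_two = bool(cw < np.quantile(cw_null, alpha / 2) or cw > np.quantile(cw_null, 1 - alpha / 2)) if cw_null.size else False
    ccw_two = bool(ccw < np.quantile(ccw_null, alpha / 2) or ccw > np.quantile(ccw_null, 1 - alpha / 2)) if ccw_null.size else False
    if cw_sig and ccw_sig:
        cls = "both"
    elif cw_sig:
        cls = "CW-only"
    elif ccw_sig:
        cls = "CCW-only"
    else:
        cls = "none"
    return AhvResult(curve, cw, ccw, cw_null, ccw_null, cw_sig, ccw_sig, cw_two, ccw_two, cls)
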