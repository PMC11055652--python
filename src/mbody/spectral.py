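"""Frequency-domain LFP analyses.

Multitaper power spectra (integral-normalized to cancel electrode-impedance
differences), magnitude-squared coherence, theta cycle segmentation with
ascending/descending asymmetry, per-cycle HPC-MB phase lag, and spectral
Granger causality from a bivariate autoregression fitted by the
Levinson-Wiggins-Robinson recursion with BIC order selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.signal.windows import dpss
from scipy.stats import f as f_dist

from .core import LfpChannel, THETA_BAND, bandpass

GC_THETA_BAND = (6.0, 12.0)


@dataclass
class Spectrum:
    freqs: np.ndarray
    power: np.ndarray
    normalized: bool = False
    resolution_hz: float = 0.0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.normalized:
            integral = np.trapezoid(self.power, self.freqs)
            if abs(integral - 1.0) > 1e-9:
                raise ValueError(f"normalized spectrum integrates to {integral}")

    def band_power(self, band: tuple[float, float]) -> float:
        lo, hi = band
        m = (self.freqs >= lo) & (self.freqs <= hi)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(self.power[m], self.freqs[m]))


def _mt_segment_spectra(
    x: np.ndarray, fs: float, window_s: float, nw: float, n_tapers: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window multitaper spectra (windows x freqs) and the freq axis."""
    nper = int(round(window_s * fs))
    nper = min(nper, x.size)
    tapers = dpss(nper, nw, Kmax=n_tapers)
    n_win = max(1, x.size // nper)
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    out = np.empty((n_win, freqs.size))
    for w in range(n_win):
        seg = x[w * nper : (w + 1) * nper]
        seg = seg - seg.mean()
        spec = np.fft.rfft(tapers * seg[None, :], axis=1)
        out[w] = (np.abs(spec) ** 2).mean(axis=0) / fs
    return out, freqs


def multitaper_psd(
    x: LfpChannel,
    nw: float = 3.0,
    n_tapers: int = 5,
    window_s: float = 10.0,
    fmax: float | None = None,
    normalize: bool = True,
) -> Spectrum:
    """Multitaper PSD, normalized by the integral of the power.

    Averages Slepian-tapered periodograms over non-overlapping windows.
    Resolution (half-bandwidth) is nw / window_s Hz.
    """
    if x.duration < 2.0:
        raise ValueError("need at least 2 s of signal")
    if nw < 1:
        raise ValueError("time-bandwidth product nw must be >= 1")
    if not np.any(x.samples):
        raise ValueError("all-zero trace: normalization undefined")
    spectra, freqs = _mt_segment_spectra(x.samples, x.fs, window_s, nw, n_tapers)
    power = spectra.mean(axis=0)
    if fmax is not None:
        keep = freqs <= fmax
        freqs, power = freqs[keep], power[keep]
    if normalize:
        power = power / np.trapezoid(power, freqs)
    return Spectrum(freqs, power, normalized=normalize, resolution_hz=nw / window_s)


@dataclass
class CoherenceResult:
    freqs: np.ndarray
    coherence: np.ndarray
    theta_peak: float
    theta_peak_freq: float


def coherence(
    x: LfpChannel, y: LfpChannel, window_s: float = 2.0, band: tuple[float, float] = GC_THETA_BAND
) -> CoherenceResult:
    """Magnitude-squared coherence (Welch) with its theta-band peak.

    The 2 s default window trades frequency resolution (0.5 Hz) for enough
    segments that the coherence bias (~1/K) stays small on minute-long
    traces.
    """
    if x.fs != y.fs:
        raise ValueError(f"sampling rates differ: {x.fs} vs {y.fs}")
    n = min(x.samples.size, y.samples.size)
    nper = int(round(window_s * x.fs))
    freqs, coh = signal.coherence(x.samples[:n], y.samples[:n], fs=x.fs, nperseg=min(nper, n))
    m = (freqs >= band[0]) & (freqs <= band[1])
    if not m.any():
        raise ValueError("no frequency bins inside the theta band")
    i = np.argmax(coh[m])
    return CoherenceResult(freqs, coh, float(coh[m][i]), float(freqs[m][i]))


# ---------------------------------------------------------------------------
# Theta cycle segmentation
# ---------------------------------------------------------------------------

def theta_cycles(
    x: LfpChannel,
    speed: tuple[np.ndarray, np.ndarray] | None = None,
    band: tuple[float, float] = THETA_BAND,
    asym_band: tuple[float, float] = (1.0, 25.0),
) -> pd.DataFrame:
    """Segment the theta-filtered trace into peak-to-peak cycles.

    Cycle boundaries come from peaks of the narrowband (4-12 Hz) filtered
    trace; peak and trough times are then refined on a broadband
    (``asym_band``) filtered copy, because narrowband filtering removes the
    harmonics that carry the ascending/descending asymmetry of theta.

    Returns one row per cycle: peak_time, trough_time, next_peak_time,
    descending_s (peak->trough), ascending_s (trough->peak), frequency_hz,
    and mean_speed (interpolated at the cycle midpoint) if ``speed``
    = (times, values) is supplied. Cycles with implausible periods
    (outside the filter band) are dropped.
    """
    if x.fs <= 2 * band[1]:
        raise ValueError(f"fs={x.fs} too low to filter {band} Hz")
    filt = bandpass(x.samples, x.fs, band)
    broad = bandpass(x.samples, x.fs, asym_band)
    min_dist = int(x.fs / band[1])
    narrow_peaks, _ = signal.find_peaks(filt, distance=min_dist)

    def refine(p: int, period_n: int) -> int:
        lo = max(0, p - period_n // 4)
        hi = min(broad.size, p + period_n // 4 + 1)
        return lo + int(np.argmax(broad[lo:hi]))

    peaks = []
    for i, p in enumerate(narrow_peaks):
        period_n = (
            narrow_peaks[min(i + 1, narrow_peaks.size - 1)]
            - narrow_peaks[max(i - 1, 0)]
        ) // max(1, (2 if 0 < i < narrow_peaks.size - 1 else 1))
        peaks.append(refine(p, max(period_n, min_dist)))
    peaks = np.asarray(sorted(set(peaks)))

    rows = []
    t = x.times
    for p0, p1 in zip(peaks, peaks[1:]):
        period = (p1 - p0) / x.fs
        if not (1.0 / band[1] <= period <= 1.0 / band[0]):
            continue
        trough = p0 + int(np.argmin(broad[p0:p1]))
        if trough in (p0, p1):
            continue
        rows.append(
            {
                "peak_time": t[p0],
                "trough_time": t[trough],
                "next_peak_time": t[p1],
                "descending_s": (trough - p0) / x.fs,
                "ascending_s": (p1 - trough) / x.fs,
                "frequency_hz": 1.0 / period,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "peak_time", "trough_time", "next_peak_time",
            "descending_s", "ascending_s", "frequency_hz",
        ],
    )
    if speed is not None and len(table):
        st, sv = speed
        mid = 0.5 * (table["peak_time"] + table["next_peak_time"])
        table["mean_speed"] = np.interp(mid, st, sv)
    elif speed is not None:
        table["mean_speed"] = pd.Series(dtype=float)
    return table


def cycle_phase_lag(
    hpc: LfpChannel, mb: LfpChannel, band: tuple[float, float] = THETA_BAND
) -> tuple[np.ndarray, float, float]:
    """Signed per-cycle lag of MB theta peaks behind HPC theta peaks.

    For each HPC theta peak the nearest MB peak within half a cycle is
    paired; positive lags mean MB follows HPC. Returns (lags, mean, sd).
    """
    cyc_h = theta_cycles(hpc, band=band)
    cyc_m = theta_cycles(mb, band=band)
    if len(cyc_h) < 10 or len(cyc_m) < 10:
        raise ValueError("fewer than 10 common theta cycles")
    hp = cyc_h["peak_time"].to_numpy()
    mp = cyc_m["peak_time"].to_numpy()
    half = 0.5 / np.median(cyc_h["frequency_hz"])
    idx = np.searchsorted(mp, hp)
    right = mp[np.clip(idx, 0, mp.size - 1)] - hp
    left = mp[np.clip(idx - 1, 0, mp.size - 1)] - hp
    lags = np.where(np.abs(right) <= np.abs(left), right, left)
    lags = lags[np.abs(lags) <= half]
    if lags.size < 10:
        raise ValueError("fewer than 10 paired cycles within half a period")
    return lags, float(lags.mean()), float(lags.std())


def speed_conditioned_theta(
    cycles: pd.DataFrame,
    bins: np.ndarray | None = None,
    min_occupancy_s: float = 1.0,
):
    """Theta frequency vs running speed, with linear-vs-sigmoid selection.

    Speed bins of 1 cm/s over 1-60; a bin counts only if its cycles jointly
    cover >= 1 s. Returns (curve DataFrame, ModelSelection).
    """
    from .tuning import fit_linear_sigmoid, TuningCurve

    if "mean_speed" not in cycles:
        raise ValueError("cycle table lacks speeds")
    if bins is None:
        bins = np.arange(1.0, 61.0, 1.0)
    dur = (cycles["ascending_s"] + cycles["descending_s"]).to_numpy()
    spd = cycles["mean_speed"].to_numpy()
    freq = cycles["frequency_hz"].to_numpy()
    idx = np.digitize(spd, bins) - 1
    nb = bins.size - 1
    occ = np.zeros(nb)
    mean_f = np.full(nb, np.nan)
    for b in range(nb):
        m = idx == b
        occ[b] = dur[m].sum()
        if m.any():
            mean_f[b] = freq[m].mean()
    valid = (occ >= min_occupancy_s) & np.isfinite(mean_f)
    if valid.sum() < 5:
        raise ValueError(f"only {int(valid.sum())} valid speed bins (need >= 5)")
    centers = 0.5 * (bins[:-1] + bins[1:])
    curve = pd.DataFrame(
        {"speed": centers, "frequency_hz": mean_f, "occupancy_s": occ, "valid": valid}
    )
    tc = TuningCurve(centers, mean_f, occ, valid)
    sel = fit_linear_sigmoid(tc, always_try_sigmoid=True)
    return curve, sel


# ---------------------------------------------------------------------------
# Spectral Granger causality
# ---------------------------------------------------------------------------

@dataclass
class GrangerResult:
    freqs: np.ndarray
    gc_xy: np.ndarray  # x -> y
    gc_yx: np.ndarray  # y -> x
    model_order: int
    theta_peak_xy: float
    theta_peak_yx: float
    p_xy: float
    p_yx: float
    significant_xy: bool
    significant_yx: bool


def _autocov(data: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocovariance matrices R[j] = E[x_t x_{t-j}^T]."""
    n, k = data.shape
    data = data - data.mean(axis=0)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(data, nfft, axis=0)
    R = np.empty((max_lag + 1, k, k))
    for a in range(k):
        for b in range(k):
            cc = np.fft.irfft(spec[:, a] * np.conj(spec[:, b]), nfft)
            R[:, a, b] = cc[: max_lag + 1] / n
    return R


def _lwr(R: np.ndarray, order: int):
    """Whittle's multichannel Levinson recursion.

    Returns per-order forward coefficients {p: A (p,k,k)} and forward
    residual covariances {p: Sigma}.
    """
    k = R.shape[1]
    sig_f = R[0].copy()
    sig_b = R[0].copy()
    A: list[np.ndarray] = []
    B: list[np.ndarray] = []
    coeffs: dict[int, np.ndarray] = {}
    sigmas: dict[int, np.ndarray] = {}
    for n in range(order):
        delta = R[n + 1].copy()
        for i, Ai in enumerate(A):
            delta -= Ai @ R[n - i]
        kf = delta @ np.linalg.inv(sig_b)
        kb = delta.T @ np.linalg.inv(sig_f)
        A_new = [Ai - kf @ B[n - 1 - i] for i, Ai in enumerate(A)] + [kf]
        B_new = [Bi - kb @ A[n - 1 - i] for i, Bi in enumerate(B)] + [kb]
        sig_f = sig_f - kf @ delta.T
        sig_b = sig_b - kb @ delta
        A, B = A_new, B_new
        coeffs[n + 1] = np.stack(A)
        sigmas[n + 1] = sig_f.copy()
    return coeffs, sigmas


def _bic_order(sigmas: dict[int, np.ndarray], n_obs: int, k: int = 2) -> int:
    best, best_bic = 1, np.inf
    for p, sig in sigmas.items():
        det = np.linalg.det(sig)
        if det <= 0:
            continue
        bic = np.log(det) + np.log(n_obs) * (k * k * p) / n_obs
        if bic < best_bic:
            best, best_bic = p, bic
    return best


def _granger_f_test(data: np.ndarray, order: int, target: int, source: int) -> float:
    """p-value of the nested-model F-test that `source` Granger-causes `target`."""
    n = data.shape[0]
    y = data[order:, target]
    rows = n - order
    lags_t = np.column_stack([data[order - j : n - j, target] for j in range(1, order + 1)])
    lags_s = np.column_stack([data[order - j : n - j, source] for j in range(1, order + 1)])
    ones = np.ones((rows, 1))
    X_r = np.hstack([ones, lags_t])
    X_f = np.hstack([ones, lags_t, lags_s])
    rss_r = np.sum((y - X_r @ np.linalg.lstsq(X_r, y, rcond=None)[0]) ** 2)
    rss_f = np.sum((y - X_f @ np.linalg.lstsq(X_f, y, rcond=None)[0]) ** 2)
    df2 = rows - X_f.shape[1]
    if rss_f <= 0 or df2 <= 0:
        return 0.0
    F = ((rss_r - rss_f) / order) / (rss_f / df2)
    return float(f_dist.sf(F, order, df2))


def granger_pair(
    x: LfpChannel,
    y: LfpChannel,
    target_fs: float = 120.0,
    max_order: int = 50,
    alpha: float = 0.001,
    n_freqs: int = 256,
) -> GrangerResult:
    """Frequency-domain Granger causality between two LFPs.

    Both traces are anti-alias decimated to ``target_fs``; a bivariate VAR
    is fitted by the Levinson-Wiggins-Robinson recursion at the BIC-optimal
    order (<= ``max_order``); Geweke's spectral measure is computed from the
    transfer function and residual covariance, and time-domain nested-model
    F-tests give the significance flags at ``alpha``.
    """
    if x.fs != y.fs:
        raise ValueError("sampling rates differ")
    if x.duration < 30.0:
        raise ValueError("need at least 30 s of signal")
    q = int(round(x.fs / target_fs))
    if q > 1:
        xs = signal.resample_poly(x.samples, 1, q)
        ys = signal.resample_poly(y.samples, 1, q)
    else:
        xs, ys = x.samples.copy(), y.samples.copy()
    fs = x.fs / q
    n = min(xs.size, ys.size)
    data = np.column_stack([xs[:n], ys[:n]])
    data = (data - data.mean(axis=0)) / data.std(axis=0)
    if np.abs(np.corrcoef(data.T)[0, 1]) > 0.999:
        raise ValueError("signals are (nearly) identical: VAR model singular")

    R = _autocov(data, max_order)
    coeffs, sigmas = _lwr(R, max_order)
    p = _bic_order(sigmas, n)
    A, Sigma = coeffs[p], sigmas[p]

    # companion-matrix stability check
    k = 2
    comp = np.zeros((k * p, k * p))
    comp[:k, :] = np.hstack(list(A))
    if p > 1:
        comp[k:, : k * (p - 1)] = np.eye(k * (p - 1))
    radius = np.abs(np.linalg.eigvals(comp)).max()
    if radius >= 1.0:
        raise ValueError(f"unstable VAR at order {p} (spectral radius {radius:.3f})")

    freqs = np.linspace(0.0, fs / 2.0, n_freqs)
    z = np.exp(-2j * np.pi * np.outer(freqs / fs, np.arange(1, p + 1)))
    Af = np.eye(k)[None] - np.einsum("fp,pij->fij", z, A)
    H = np.linalg.inv(Af)
    S = H @ Sigma[None] @ np.conj(np.transpose(H, (0, 2, 1)))
    sxx = np.real(S[:, 0, 0])
    syy = np.real(S[:, 1, 1])
    # Geweke: contribution of the source's innovations to the target spectrum
    s2_yx = Sigma[1, 1] - Sigma[0, 1] ** 2 / Sigma[0, 0]  # y innovations | x
    s2_xy = Sigma[0, 0] - Sigma[0, 1] ** 2 / Sigma[1, 1]  # x innovations | y
    with np.errstate(divide="ignore", invalid="ignore"):
        gc_yx = np.log(sxx / np.maximum(sxx - s2_yx * np.abs(H[:, 0, 1]) ** 2, 1e-300))
        gc_xy = np.log(syy / np.maximum(syy - s2_xy * np.abs(H[:, 1, 0]) ** 2, 1e-300))
    gc_yx = np.maximum(gc_yx, 0.0)
    gc_xy = np.maximum(gc_xy, 0.0)

    band = (freqs >= GC_THETA_BAND[0]) & (freqs <= GC_THETA_BAND[1])
    theta_xy = float(gc_xy[band].max()) if band.any() else 0.0
    theta_yx = float(gc_yx[band].max()) if band.any() else 0.0
    p_xy = _granger_f_test(data, p, target=1, source=0)
    p_yx = _granger_f_test(data, p, target=0, source=1)
    return GrangerResult(
        freqs, gc_xy, gc_yx, p, theta_xy, theta_yx,
        p_xy, p_yx, p_xy < alpha, p_yx < alpha,
    )
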