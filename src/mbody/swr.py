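"""Sharp-wave ripple detection, validation, and MB-event coupling.

Candidate ripples are peaks of the 150-250 Hz envelope of the hippocampal
LFP exceeding the mean + 4 SD of the SWS-indexed filtered signal, at least
200 ms apart. A candidate is valid when the filtered trace shows at least
five suprathreshold oscillation extrema (both polarities counted) within
a 20 ms window around the peak. MB high-frequency events use the same
machinery in the 100-250 Hz band, and their temporal coupling to ripples
is tested against circularly shifted ripple-time nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LfpChannel, EpochSet, RIPPLE_BAND, MB_EVENT_BAND, bandpass, envelope
from scipy import signal


@dataclass
class RippleEventSet:
    """Detected ripple events with per-event validation bookkeeping."""

    peak_times: np.ndarray
    amplitudes_sd: np.ndarray  # envelope peak in SDs of the filtered trace
    n_oscillations: np.ndarray
    valid: np.ndarray
    edge: np.ndarray
    threshold: float  # detection threshold on the envelope (raw units)
    sd: float  # SD of the SWS-indexed filtered signal

    def valid_times(self) -> np.ndarray:
        return self.peak_times[self.valid]

    def __len__(self) -> int:
        return int(self.peak_times.size)


def _band_stats(
    lfp: LfpChannel, sws: EpochSet, band: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, float, float]:
    filt = bandpass(lfp.samples, lfp.fs, band)
    env = envelope(filt)
    mask = sws.sample_mask(lfp.samples.size, lfp.fs, "SWS", lfp.t0)
    if not mask.any():
        raise ValueError("no SWS samples to compute detection statistics")
    mu = float(filt[mask].mean())
    sd = float(filt[mask].std())
    return filt, env, mu, sd


def detect_ripples(
    hpc: LfpChannel,
    sws: EpochSet,
    band: tuple[float, float] = RIPPLE_BAND,
    thresh_sd: float = 4.0,
    min_sep_ms: float = 200.0,
) -> RippleEventSet:
    """Candidate ripple peaks during SWS (not yet validated).

    Peaks of the bandpassed envelope above mean + ``thresh_sd`` x SD of the
    SWS-indexed filtered signal, with a minimum inter-peak separation of
    200 ms (the larger peak wins a conflict). Amplitudes are reported in
    SDs of the filtered trace.
    """
    if hpc.fs < 600:
        raise ValueError(f"fs={hpc.fs} too low for the {band} Hz band")
    filt, env, mu, sd = _band_stats(hpc, sws, band)
    thresh = mu + thresh_sd * sd
    min_dist = max(1, int(round(min_sep_ms / 1000.0 * hpc.fs)))
    peaks, props = signal.find_peaks(env, height=thresh, distance=min_dist)
    mask = sws.sample_mask(hpc.samples.size, hpc.fs, "SWS", hpc.t0)
    peaks = peaks[mask[peaks]]
    times = hpc.t0 + peaks / hpc.fs
    amps = (env[peaks] - mu) / sd if sd > 0 else np.zeros(peaks.size)
    n = peaks.size
    return RippleEventSet(
        peak_times=times,
        amplitudes_sd=amps,
        n_oscillations=np.zeros(n, dtype=int),
        valid=np.zeros(n, dtype=bool),
        edge=np.zeros(n, dtype=bool),
        threshold=thresh,
        sd=sd,
    )


def validate_ripples(
    candidates: RippleEventSet,
    hpc: LfpChannel,
    sws: EpochSet,
    band: tuple[float, float] = RIPPLE_BAND,
    window_ms: float = 20.0,
    min_oscillations: int = 5,
) -> RippleEventSet:
    """Keep candidates with >= 5 suprathreshold oscillations in 20 ms.

    Counts extrema of the filtered trace (both polarities) whose magnitude
    exceeds the SD threshold inside peak +- window/2. Candidates whose
    window overruns the trace edge are evaluated on the available samples
    and flagged ``edge``.
    """
    filt, _, mu, sd = _band_stats(hpc, sws, band)
    mag_thresh = candidates.threshold - mu  # thresh_sd * sd, on |filt - mu|
    half = int(round(window_ms / 2000.0 * hpc.fs))
    n_osc = np.zeros(len(candidates), dtype=int)
    edge = np.zeros(len(candidates), dtype=bool)
    centered = filt - mu
    for i, t in enumerate(candidates.peak_times):
        c = int(round((t - hpc.t0) * hpc.fs))
        lo, hi = c - half, c + half + 1
        if lo < 0 or hi > centered.size:
            edge[i] = True
            lo, hi = max(lo, 0), min(hi, centered.size)
        seg = centered[lo:hi]
        if seg.size < 3:
            continue
        rect = np.abs(seg)
        ext = signal.argrelextrema(rect, np.greater_equal, order=1)[0]
        # de-duplicate flat runs
        ext = ext[np.concatenate(([True], np.diff(ext) > 1))] if ext.size else ext
        n_osc[i] = int(np.sum(rect[ext] > mag_thresh))
    valid = n_osc >= min_oscillations
    return RippleEventSet(
        peak_times=candidates.peak_times,
        amplitudes_sd=candidates.amplitudes_sd,
        n_oscillations=n_osc,
        valid=valid,
        edge=edge,
        threshold=candidates.threshold,
        sd=candidates.sd,
    )


def detect_mb_events(
    mb: LfpChannel,
    sws: EpochSet,
    band: tuple[float, float] = MB_EVENT_BAND,
    thresh_sd: float = 4.0,
    min_sep_ms: float = 200.0,
) -> np.ndarray:
    """High gamma-ripple band (100-250 Hz) event times in the MB LFP.

    Same detection and validation rules as hippocampal ripples, reused in
    the wider band (no separate parameters are defined for MB events).
    """
    cands = detect_ripples(mb, sws, band=band, thresh_sd=thresh_sd, min_sep_ms=min_sep_ms)
    validated = validate_ripples(cands, mb, sws, band=band)
    return validated.valid_times()


def event_triggered_average(
    x: LfpChannel,
    events: np.ndarray,
    half_window: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Mean event-aligned LFP snippet with its SEM.

    Events whose window would overrun the trace are excluded. Returns
    (lags_s, mean, sem, n_used).
    """
    events = np.asarray(events, dtype=float)
    half = int(round(half_window * x.fs))
    lags = np.arange(-half, half + 1) / x.fs
    snippets = []
    for t in events:
        c = int(round((t - x.t0) * x.fs))
        if c - half < 0 or c + half + 1 > x.samples.size:
            continue
        snippets.append(x.samples[c - half : c + half + 1])
    if not snippets:
        raise ValueError("no events fully inside the trace")
    arr = np.stack(snippets)
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 else np.zeros_like(mean)
    return lags, mean, sem, arr.shape[0]


@dataclass
class CouplingResult:
    observed: int
    null_percentile_99: float
    null_counts: np.ndarray
    significant: bool
    p_value: float


def coupling_test(
    mb_events: np.ndarray,
    ripples: RippleEventSet | np.ndarray,
    sws_span: tuple[float, float],
    window_s: float = 0.025,
    n_shuffle: int = 1000,
    alpha: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> CouplingResult:
    """Are MB events clustered within +-25 ms of hippocampal ripples?

    The null circularly shifts the ripple times within the SWS span by a
    uniform draw from [30 s, span - 30 s] per iteration; significance when
    the observed count exceeds the (1 - alpha) null quantile.
    """
    ripple_times = ripples.valid_times() if isinstance(ripples, RippleEventSet) else np.asarray(ripples)
    mb_events = np.sort(np.asarray(mb_events, dtype=float))
    if ripple_times.size < 10:
        raise ValueError(f"only {ripple_times.size} ripples: coupling test underpowered")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = sws_span
    span = hi - lo

    def count_near(events: np.ndarray, refs: np.ndarray) -> int:
        if events.size == 0 or refs.size == 0:
            return 0
        idx = np.searchsorted(refs, events)
        d_r = np.abs(events - refs[np.clip(idx, 0, refs.size - 1)])
        d_l = np.abs(events - refs[np.clip(idx - 1, 0, refs.size - 1)])
        return int(np.sum(np.minimum(d_r, d_l) <= window_s))

    observed = count_near(mb_events, np.sort(ripple_times))
    shift_lo, shift_hi = (30.0, span - 30.0) if span > 60.0 else (0.1 * span, 0.9 * span)
    null = np.empty(n_shuffle, dtype=int)
    rel = ripple_times - lo
    for i in range(n_shuffle):
        s = rng.uniform(shift_lo, shift_hi)
        shifted = np.sort(np.mod(rel + s, span)) + lo
        null[i] = count_near(mb_events, shifted)
    q99 = float(np.quantile(null, 1.0 - alpha))
    p = float((np.sum(null >= observed) + 1) / (n_shuffle + 1))
    return CouplingResult(observed, q99, null, observed > q99, p)
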