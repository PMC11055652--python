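"""State-conditioned unit activity.

Firing-rate scores contrasting each sleep state with wakefulness, mean
pairwise synchrony of binned spike counts, the sharp-wave-ripple
responsiveness index (RI) against circular-shift nulls, and slow-wave
(1-4 Hz) phase entrainment during SWS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LfpChannel, SpikeTrain, EpochSet, DELTA_BAND
from .swr import RippleEventSet, event_triggered_average
from .tuning import PhaseStats, PhaseInterpolant, phase_entrainment_test


def _rate_in(train: SpikeTrain, intervals: list[tuple[float, float]]) -> float:
    dur = sum(e - s for s, e in intervals)
    if dur <= 0:
        raise ValueError("zero-duration epoch")
    n = sum(
        int(np.searchsorted(train.times, e) - np.searchsorted(train.times, s))
        for s, e in intervals
    )
    return n / dur


def rate_score(state_rate: float, awake_rate: float) -> float:
    """(state - awake)/(state + awake), in [-1, 1]."""
    denom = state_rate + awake_rate
    if denom == 0:
        return float("nan")
    return (state_rate - awake_rate) / denom


def rate_scores(
    trains: list[SpikeTrain],
    rem_block: tuple[tuple[float, float], tuple[float, float], tuple[float, float]],
    awake_epochs: list[tuple[float, float]],
) -> pd.DataFrame:
    """Per-unit firing-rate scores for SWS_pre, REM and SWS_post.

    Units silent in all three sleep states are excluded.
    """
    sws_pre, rem, sws_post = rem_block
    rows = []
    for tr in trains:
        r_awk = _rate_in(tr, awake_epochs)
        r_pre = _rate_in(tr, [sws_pre])
        r_rem = _rate_in(tr, [rem])
        r_post = _rate_in(tr, [sws_post])
        if r_pre == 0 and r_rem == 0 and r_post == 0:
            continue
        rows.append(
            {
                "unit_id": tr.unit_id,
                "region": tr.region,
                "rate_awake_hz": r_awk,
                "score_sws_pre": rate_score(r_pre, r_awk),
                "score_rem": rate_score(r_rem, r_awk),
                "score_sws_post": rate_score(r_post, r_awk),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["unit_id", "region", "rate_awake_hz",
                 "score_sws_pre", "score_rem", "score_sws_post"],
    )


def synchrony(
    trains: list[SpikeTrain],
    epoch: tuple[float, float],
    bin_s: float = 0.1,
) -> tuple[float, int, list[str]]:
    """Mean pairwise Pearson correlation of 100 ms binned spike counts.

    Pairs involving a zero-variance unit in the epoch are skipped and
    logged. Returns (mean correlation, n_pairs, log).
    """
    if len(trains) < 2:
        raise ValueError("need at least 2 units")
    s, e = epoch
    edges = np.arange(s, e + bin_s / 2, bin_s)
    counts = np.stack([np.histogram(tr.times, bins=edges)[0] for tr in trains]).astype(float)
    log: list[str] = []
    corrs = []
    for i in range(len(trains)):
        for j in range(i + 1, len(trains)):
            if counts[i].std() == 0 or counts[j].std() == 0:
                log.append(f"pair ({trains[i].unit_id}, {trains[j].unit_id}) skipped: zero variance")
                continue
            corrs.append(float(np.corrcoef(counts[i], counts[j])[0, 1]))
    if not corrs:
        return float("nan"), 0, log
    return float(np.mean(corrs)), len(corrs), log


# ---------------------------------------------------------------------------
# SWR responsiveness
# ---------------------------------------------------------------------------

@dataclass
class SwrResponse:
    unit_id: int | str
    psth_edges: np.ndarray  # s relative to ripple peak
    psth_rate: np.ndarray  # Hz per bin, pooled over events
    ri: float  # observed window rate minus mean shuffle window rate
    null: np.ndarray  # leave-one-out centered shuffle RIs
    p5: float
    p95: float
    classification: str  # "positive" | "negative" | "ns"
    n_events: int


def _window_rate(times: np.ndarray, events: np.ndarray, half: float) -> float:
    """Mean firing rate inside +-half of the events, pooled."""
    lo = np.searchsorted(times, events - half)
    hi = np.searchsorted(times, events + half)
    return float((hi - lo).sum()) / (events.size * 2 * half)


def swr_ri(
    train: SpikeTrain,
    ripples: RippleEventSet | np.ndarray,
    half_psth: float = 0.5,
    psth_bin: float = 0.02,
    ri_half_window: float = 0.125,
    n_shuffle: int = 1000,
    shift_range: tuple[float, float] = (-5.0, 5.0),
    min_events: int = 20,
    seed: int | np.random.Generator = 0,
) -> SwrResponse:
    """SWR responsiveness index with a leave-one-out shuffle null.

    RI_obs is the unit's mean rate within +-125 ms of the true ripple peaks
    minus the mean of the same statistic over circularly shifted ripple
    sets (uniform shift in +-5 s, 1000 iterations). Each shuffle's own RI
    is its window rate minus the mean of the other 999 shuffles' rates;
    the observed RI is classified against the null's 5th/95th percentiles.
    """
    events = ripples.valid_times() if isinstance(ripples, RippleEventSet) else np.asarray(ripples)
    events = np.sort(events)
    if events.size < min_events:
        raise ValueError(f"only {events.size} ripples (need >= {min_events})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = train.session_duration

    edges = np.arange(-half_psth, half_psth + psth_bin / 2, psth_bin)
    rel = train.times[None, :] - events[:, None]
    psth_counts = np.histogram(rel[np.abs(rel) <= half_psth + psth_bin], bins=edges)[0]
    psth_rate = psth_counts / (events.size * psth_bin)

    obs_rate = _window_rate(train.times, events, ri_half_window)
    shifts = rng.uniform(shift_range[0], shift_range[1], size=n_shuffle)
    shuffle_rates = np.empty(n_shuffle)
    for i, s in enumerate(shifts):
        shuffle_rates[i] = _window_rate(train.times, np.sort(np.mod(events + s, T)), ri_half_window)
    ri_obs = obs_rate - shuffle_rates.mean()
    # leave-one-out centering of each shuffle against the other n-1
    total = shuffle_rates.sum()
    loo_mean = (total - shuffle_rates) / (n_shuffle - 1)
    null = shuffle_rates - loo_mean
    p5, p95 = np.quantile(null, [0.05, 0.95])
    if ri_obs > p95:
        cls = "positive"
    elif ri_obs < p5:
        cls = "negative"
    else:
        cls = "ns"
    return SwrResponse(
        train.unit_id, edges, psth_rate, float(ri_obs), null,
        float(p5), float(p95), cls, events.size,
    )


def slow_wave_phase(
    train: SpikeTrain,
    lfp: LfpChannel | PhaseInterpolant,
    sws: EpochSet,
    n_shuffle: int = 1000,
    min_sws_s: float = 100.0,
    min_spikes: int = 50,
    seed: int | np.random.Generator = 0,
) -> PhaseStats:
    """Slow-wave (1-4 Hz) phase entrainment during SWS.

    Same Hilbert/interpolation machinery as theta phase locking, run on the
    delta-filtered LFP and restricted to spikes inside SWS epochs. Under
    the peak-zero convention, the slow-wave downstate (trough) is +-pi.
    """
    if sws.total_duration("SWS") < min_sws_s:
        raise ValueError("need >= 100 s of SWS")
    mask = sws.mask_times(train.times, "SWS")
    sub = SpikeTrain(train.unit_id, train.times[mask], train.session_duration, train.region)
    interp = lfp if isinstance(lfp, PhaseInterpolant) else PhaseInterpolant(lfp, DELTA_BAND)
    return phase_entrainment_test(
        sub, interp, n_shuffle=n_shuffle, min_spikes=min_spikes, seed=seed
    )


def burst_triggered_average(
    bursts,
    lfps: list[LfpChannel],
    half_window: float = 0.5,
):
    """Burst-center triggered LFP averages, one per channel.

    Returns {region: (lags, mean, sem, n)} via the event-triggered
    averaging used for ripples.
    """
    if bursts.n_bursts == 0:
        raise ValueError("no bursts to trigger on")
    return {
        lfp.region: event_triggered_average(lfp, bursts.centers, half_window)
        for lfp in lfps
    }
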