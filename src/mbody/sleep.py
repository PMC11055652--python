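"""Arousal-state scoring from the hippocampal theta/delta ratio.

Windows of 10 s (6 s hop, i.e. 4 s overlap) are scored by the ratio of
theta-band (4-12 Hz) to delta-band (1-4 Hz) power of a smoothed,
maximum-normalized, squared multitaper spectrum. Low ratio -> SWS; high
ratio with movement -> AWK; high ratio without movement (< 4 cm/s) -> REM.
The split threshold defaults to an Otsu cut of the log-ratio distribution
and can be overridden with a manually chosen value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LfpChannel, EpochSet, THETA_BAND, DELTA_BAND, moving_average
from .spectral import _mt_segment_spectra

SPEED_THRESHOLD_CM_S = 4.0
WINDOW_S = 10.0
HOP_S = 6.0


@dataclass
class StateLabels:
    table: pd.DataFrame  # window_start_s, td_ratio, speed, label
    window_s: float = WINDOW_S
    hop_s: float = HOP_S
    threshold: float = 1.0

    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()


def theta_delta_ratio(
    x: LfpChannel,
    window_s: float = WINDOW_S,
    hop_s: float = HOP_S,
    nw: float = 3.0,
    n_tapers: int = 5,
    smooth_bins: int = 3,
) -> pd.DataFrame:
    """Per-window theta/delta power ratio series.

    Each 10 s window's multitaper spectrum is smoothed with a 3-bin moving
    average, maximum-normalized and squared before integrating the 4-12 Hz
    and 1-4 Hz bands. Windows with zero delta power get an infinite ratio
    and a ``flagged`` mark.
    """
    if x.duration < 20.0:
        raise ValueError("need at least 20 s of signal to score states")
    from scipy.signal.windows import dpss

    nper = int(round(window_s * x.fs))
    hop = int(round(hop_s * x.fs))
    tapers = dpss(nper, nw, Kmax=n_tapers)
    freqs = np.fft.rfftfreq(nper, 1.0 / x.fs)
    th = (freqs >= THETA_BAND[0]) & (freqs <= THETA_BAND[1])
    de = (freqs >= DELTA_BAND[0]) & (freqs <= DELTA_BAND[1])
    starts, ratios, flags = [], [], []
    pos = 0
    while pos + nper <= x.samples.size:
        seg = x.samples[pos : pos + nper]
        seg = seg - seg.mean()
        spec = (np.abs(np.fft.rfft(tapers * seg[None, :], axis=1)) ** 2).mean(axis=0)
        spec = moving_average(spec, smooth_bins)
        peak = spec.max()
        q = (spec / peak) ** 2 if peak > 0 else spec
        p_th = np.trapezoid(q[th], freqs[th])
        p_de = np.trapezoid(q[de], freqs[de])
        starts.append(x.t0 + pos / x.fs)
        if p_de <= 0:
            ratios.append(np.inf)
            flags.append(True)
        else:
            ratios.append(p_th / p_de)
            flags.append(False)
        pos += hop
    return pd.DataFrame({"window_start_s": starts, "td_ratio": ratios, "flagged": flags})


def otsu_threshold(ratios: np.ndarray) -> float:
    """Otsu split of the log theta/delta ratio distribution."""
    from skimage.filters import threshold_otsu

    finite = ratios[np.isfinite(ratios) & (ratios > 0)]
    if finite.size < 4 or np.ptp(np.log(finite)) < 1e-12:
        return float(np.median(finite)) if finite.size else 1.0
    return float(np.exp(threshold_otsu(np.log(finite))))


def classify_states(
    ratio_table: pd.DataFrame,
    speed: tuple[np.ndarray, np.ndarray] | None,
    td_threshold: float | None = None,
    speed_threshold: float = SPEED_THRESHOLD_CM_S,
    window_s: float = WINDOW_S,
    hop_s: float = HOP_S,
) -> StateLabels:
    """Label each window AWK / REM / SWS.

    ratio < threshold -> SWS; otherwise REM if the window's mean speed is
    below ``speed_threshold`` (4 cm/s), else AWK. Windows without speed data
    are labelled UNKNOWN and excluded downstream.
    """
    ratios = ratio_table["td_ratio"].to_numpy(dtype=float)
    starts = ratio_table["window_start_s"].to_numpy(dtype=float)
    if td_threshold is None:
        td_threshold = otsu_threshold(ratios)
    win_speed = np.full(starts.size, np.nan)
    if speed is not None:
        st, sv = speed
        for i, s in enumerate(starts):
            m = (st >= s) & (st < s + window_s)
            if m.any():
                win_speed[i] = float(np.mean(sv[m]))
    labels = np.empty(starts.size, dtype=object)
    for i, (r, v) in enumerate(zip(ratios, win_speed)):
        if r < td_threshold:
            labels[i] = "SWS"
        elif np.isnan(v):
            labels[i] = "UNKNOWN"
        elif v < speed_threshold:
            labels[i] = "REM"
        else:
            labels[i] = "AWK"
    table = pd.DataFrame(
        {"window_start_s": starts, "td_ratio": ratios, "speed": win_speed, "label": labels}
    )
    return StateLabels(table, window_s, hop_s, float(td_threshold))


def build_epochs(labels: StateLabels, merge_gap: float = 60.0) -> EpochSet:
    """Merge same-state windows into epochs when gaps are under ``merge_gap``."""
    out: dict[str, list[tuple[float, float]]] = {}
    tbl = labels.table
    for state in ("AWK", "REM", "SWS"):
        ivals: list[tuple[float, float]] = []
        for s in tbl.loc[tbl["label"] == state, "window_start_s"]:
            win = (float(s), float(s) + labels.window_s)
            if ivals and win[0] - ivals[-1][1] < merge_gap:
                ivals[-1] = (ivals[-1][0], max(ivals[-1][1], win[1]))
            else:
                ivals.append(win)
        if ivals:
            out[state] = ivals
    return EpochSet(out, merge_gap=merge_gap)


def select_rem_block(
    epochs: EpochSet, min_rem_s: float = 30.0, slack_s: float = WINDOW_S
) -> tuple[tuple[float, float], tuple[float, float], tuple[float, float]] | None:
    """Longest REM epoch (>= 30 s) with flanking SWS epochs, or None.

    Returns (SWS_pre, REM, SWS_post) where the flanks are the nearest SWS
    epochs ending before the REM start / starting after the REM end.
    Because scoring windows overlap, epochs of different states may overlap
    by up to one window; ``slack_s`` tolerates that at the boundaries.
    """
    sws = epochs.get("SWS")
    candidates = []
    for rem in epochs.get("REM"):
        if rem[1] - rem[0] < min_rem_s:
            continue
        pre = [e for e in sws if e[1] <= rem[0] + slack_s and e[0] < rem[0]]
        post = [e for e in sws if e[0] >= rem[1] - slack_s and e[1] > rem[1]]
        if pre and post:
            candidates.append((pre[-1], rem, post[0]))
    if not candidates:
        return None
    return max(candidates, key=lambda trip: trip[1][1] - trip[1][0])
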