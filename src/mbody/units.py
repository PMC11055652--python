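"""Spike-train housekeeping and per-unit descriptors.

Duplicate-cluster removal (>5% shared spike times), the <1 Hz rate filter,
normalized autocorrelograms, probability-normalized log-ISI histograms,
waveform features (peak-normalized 50-sample templates), and the
pyramidal/interneuron split of hippocampal units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SpikeTrain

WAVEFORM_DT_MS = 0.04  # 50 samples at 0.04 ms/bin


# ---------------------------------------------------------------------------
# Train filters
# ---------------------------------------------------------------------------

def _coincident_fraction(a: SpikeTrain, b: SpikeTrain, tol: float) -> float:
    """Fraction of the smaller train's spikes coincident within +-tol."""
    small, big = (a, b) if a.n_spikes <= b.n_spikes else (b, a)
    if small.n_spikes == 0:
        return 0.0
    idx = np.searchsorted(big.times, small.times)
    d_r = np.abs(small.times - big.times[np.clip(idx, 0, big.n_spikes - 1)])
    d_l = np.abs(small.times - big.times[np.clip(idx - 1, 0, big.n_spikes - 1)])
    return float(np.mean(np.minimum(d_r, d_l) <= tol))


def dedupe_units(
    trains: list[SpikeTrain],
    overlap_threshold: float = 0.05,
    tol: float = 0.0005,
) -> tuple[list[SpikeTrain], list[dict]]:
    """Drop the lower-rate member of every pair sharing > 5% spike times.

    Overlap is the coincident fraction relative to the smaller train, with
    coincidence within +-tol (default 0.5 ms). Pairs are resolved greedily,
    highest overlap first; rate ties keep the lower unit_id. Idempotent.
    Returns (kept trains, removal log).
    """
    alive = {i: tr for i, tr in enumerate(trains)}
    removed: list[dict] = []
    while True:
        pairs = []
        keys = sorted(alive)
        for ii, i in enumerate(keys):
            for j in keys[ii + 1 :]:
                frac = _coincident_fraction(alive[i], alive[j], tol)
                if frac > overlap_threshold:
                    pairs.append((frac, i, j))
        if not pairs:
            break
        frac, i, j = max(pairs, key=lambda p: (p[0], -p[1], -p[2]))
        a, b = alive[i], alive[j]
        if a.n_spikes == b.n_spikes:
            drop = i if str(a.unit_id) > str(b.unit_id) else j
        else:
            drop = i if a.n_spikes < b.n_spikes else j
        removed.append(
            {"unit_id": alive[drop].unit_id, "overlap": frac, "kept": alive[i if drop == j else j].unit_id}
        )
        del alive[drop]
    return [alive[k] for k in sorted(alive)], removed


def rate_filter(trains: list[SpikeTrain], min_rate: float = 1.0) -> list[SpikeTrain]:
    """Keep units with mean firing rate >= 1 Hz over the session."""
    return [tr for tr in trains if tr.mean_rate >= min_rate]


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------

@dataclass
class Autocorrelogram:
    lags_ms: np.ndarray  # bin centers, symmetric about 0
    counts: np.ndarray  # normalized: sums to 1
    bin_ms: float

    def __post_init__(self) -> None:
        total = self.counts.sum()
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError("autocorrelogram bins must sum to 1")


def autocorrelogram(
    train: SpikeTrain, max_lag: float = 0.5, bin_ms: float = 1.0
) -> Autocorrelogram:
    """Spike-train autocorrelogram over +-max_lag, bins summing to 1.

    Counts all ordered spike pairs per signed lag bin; the zero-lag
    self-pairs are excluded.
    """
    if train.n_spikes < 2:
        raise ValueError(f"unit {train.unit_id}: need >= 2 spikes")
    t = train.times
    bw = bin_ms / 1000.0
    edges = np.arange(-max_lag, max_lag + bw / 2, bw)
    # pair enumeration restricted to |lag| <= max_lag via searchsorted windows
    lo = np.searchsorted(t, t - max_lag, side="left")
    hi = np.searchsorted(t, t + max_lag, side="right")
    chunks = [t[lo[i] : hi[i]] - t[i] for i in range(t.size)]
    lags = np.concatenate(chunks) if chunks else np.empty(0)
    lags = lags[lags != 0.0]
    counts = np.histogram(lags, bins=edges)[0].astype(float)
    total = counts.sum()
    if total > 0:
        counts = counts / total
    centers = 0.5 * (edges[:-1] + edges[1:]) * 1000.0
    return Autocorrelogram(centers, counts, bin_ms)


@dataclass
class LogIsiHistogram:
    edges_s: np.ndarray  # log-spaced over 0.001-10 s
    mass: np.ndarray  # probability-normalized
    n_dropped: int  # ISIs outside the range

    @property
    def centers_s(self) -> np.ndarray:
        return np.sqrt(self.edges_s[:-1] * self.edges_s[1:])


def logisi_histogram(train: SpikeTrain, n_bins: int = 100) -> LogIsiHistogram:
    """Probability-normalized log-ISI histogram over 0.001-10 s."""
    if train.n_spikes < 2:
        raise ValueError(f"unit {train.unit_id}: need >= 2 spikes")
    isis = np.diff(train.times)
    edges = np.logspace(np.log10(0.001), np.log10(10.0), n_bins + 1)
    in_range = (isis >= edges[0]) & (isis <= edges[-1])
    counts = np.histogram(isis[in_range], bins=edges)[0].astype(float)
    total = counts.sum()
    mass = counts / total if total > 0 else counts
    return LogIsiHistogram(edges, mass, int((~in_range).sum()))


# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------

@dataclass
class WaveformFeatures:
    waveform: np.ndarray  # peak-normalized
    asymmetry: float  # min before peak - min after peak (normalized units)
    peak_trough_width_ms: float


def waveform_features(waveform: np.ndarray, dt_ms: float = WAVEFORM_DT_MS) -> WaveformFeatures:
    """Peak-normalize a mean waveform and extract asymmetry and width.

    Asymmetry is the difference of the pre-peak and post-peak minima;
    width is the time from the peak to the post-peak minimum.
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1 or w.size < 3:
        raise ValueError("waveform must be 1-D with >= 3 samples")
    if np.ptp(w) == 0:
        raise ValueError("flat waveform: no peak")
    peak = int(np.argmax(w))
    if peak in (0, w.size - 1):
        raise ValueError("peak at waveform edge: no pre/post minima")
    w = w / w[peak]
    min_before = float(w[:peak].min())
    after = w[peak + 1 :]
    min_after = float(after.min())
    trough = peak + 1 + int(np.argmin(after))
    width = (trough - peak) * dt_ms
    if not 0.0 < width < 2.0:
        raise ValueError(f"peak-trough width {width:.3f} ms outside (0, 2) ms")
    return WaveformFeatures(w, min_before - min_after, width)


def classify_pyr_int(
    waveforms: np.ndarray,
    mean_rates: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Split hippocampal units into putative pyramidal cells and interneurons.

    2-means on [PC1, PC2 of the peak-normalized waveforms, z(mean rate)];
    the cluster with the higher mean rate is labelled INT (narrow-waveform
    check reported; rate wins a disagreement). Returns (labels, warnings).
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    waveforms = np.asarray(waveforms, dtype=float)
    mean_rates = np.asarray(mean_rates, dtype=float)
    n = waveforms.shape[0]
    warnings: list[str] = []
    if n < 4:
        warnings.append(f"only {n} HPC units: all labelled PYR")
        return np.array(["PYR"] * n, dtype=object), warnings
    peaks = waveforms.max(axis=1, keepdims=True)
    peaks[peaks == 0] = 1.0
    norm = waveforms / peaks
    if np.allclose(norm, norm[0]) and np.ptp(mean_rates) < 1e-12:
        warnings.append("all units identical: single effective cluster, all PYR")
        return np.array(["PYR"] * n, dtype=object), warnings
    pcs = PCA(n_components=2, random_state=seed).fit_transform(norm)
    z = (mean_rates - mean_rates.mean()) / (mean_rates.std() or 1.0)
    feats = np.column_stack([pcs, z])
    feats = (feats - feats.mean(axis=0)) / np.where(feats.std(axis=0) > 0, feats.std(axis=0), 1.0)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(feats)
    rates0 = mean_rates[km.labels_ == 0].mean()
    rates1 = mean_rates[km.labels_ == 1].mean()
    int_cluster = 0 if rates0 > rates1 else 1
    # diagnostic: the INT cluster should also be the narrow-waveform one
    widths = []
    for i in range(2):
        ws = []
        for w in norm[km.labels_ == i]:
            try:
                ws.append(waveform_features(w).peak_trough_width_ms)
            except ValueError:
                pass
        widths.append(np.mean(ws) if ws else np.nan)
    if np.isfinite(widths[int_cluster]) and np.isfinite(widths[1 - int_cluster]):
        if widths[int_cluster] > widths[1 - int_cluster]:
            warnings.append("rate and width disagree on the INT cluster; rate wins")
    labels = np.where(km.labels_ == int_cluster, "INT", "PYR").astype(object)
    return labels, warnings


def feature_table(
    trains: list[SpikeTrain], waveforms: dict, labels: dict | None = None
) -> pd.DataFrame:
    """Tidy per-unit table: unit_id, region, rate_hz, width_ms, asymmetry, label."""
    rows = []
    for tr in trains:
        row = {"unit_id": tr.unit_id, "region": tr.region, "rate_hz": tr.mean_rate,
               "width_ms": np.nan, "asymmetry": np.nan,
               "label": (labels or {}).get(tr.unit_id, "")}
        if tr.unit_id in waveforms:
            try:
                wf = waveform_features(waveforms[tr.unit_id])
                row["width_ms"] = wf.peak_trough_width_ms
                row["asymmetry"] = wf.asymmetry
            except ValueError:
                pass
        rows.append(row)
    return pd.DataFrame(rows)
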