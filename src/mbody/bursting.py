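"""Burst detection, DB/SB classification, and theta cycle skipping.

A burst opens on an interspike interval <= 6 ms, extends while ISIs stay
<= 8 ms, and counts only with >= 3 spikes. Burst probability is
n_bursts / (n_bursts + n_spikes). Units are split into dominantly (DB)
versus sparsely bursting (SB) classes by Ward clustering of principal
components of their log-ISI histograms and short-lag autocorrelograms.
The cycle skipping index (CSI) contrasts the secondary (~0.2-0.3 s) and
primary (~0.1-0.15 s) theta peaks of the autocorrelogram; CSI > 0 marks
units that fire on alternate theta cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .core import SpikeTrain
from .units import Autocorrelogram, LogIsiHistogram


@dataclass
class BurstSet:
    unit_id: int | str
    starts: np.ndarray  # first-spike time of each burst
    n_spikes: np.ndarray  # spikes per burst (>= 3)
    centers: np.ndarray  # median spike time of each burst
    n_spikes_total: int  # all spikes in the session

    @property
    def n_bursts(self) -> int:
        return int(self.starts.size)

    @property
    def burst_probability(self) -> float:
        denom = self.n_bursts + self.n_spikes_total
        return self.n_bursts / denom if denom else float("nan")


def detect_bursts(
    train: SpikeTrain,
    start_isi: float = 0.006,
    continue_isi: float = 0.008,
    min_spikes: int = 3,
) -> BurstSet:
    """Left-to-right burst scan with open/extend ISI criteria.

    An ISI <= ``start_isi`` opens a candidate; subsequent ISIs <=
    ``continue_isi`` extend it; candidates with >= ``min_spikes`` spikes
    are kept. Each spike belongs to at most one burst.
    """
    t = train.times
    starts, ns, centers = [], [], []
    i = 0
    n = t.size
    while i < n - 1:
        if t[i + 1] - t[i] <= start_isi:
            j = i + 1
            while j < n - 1 and t[j + 1] - t[j] <= continue_isi:
                j += 1
            count = j - i + 1
            if count >= min_spikes:
                starts.append(t[i])
                ns.append(count)
                centers.append(float(np.median(t[i : j + 1])))
            i = j + 1
        else:
            i += 1
    return BurstSet(
        train.unit_id,
        np.asarray(starts), np.asarray(ns, dtype=int), np.asarray(centers),
        n_spikes_total=n,
    )


def burst_probability(bursts: BurstSet) -> float:
    """n_bursts / (n_bursts + n_spikes); undefined (NaN) for empty trains."""
    return bursts.burst_probability


# ---------------------------------------------------------------------------
# DB / SB classification
# ---------------------------------------------------------------------------

@dataclass
class BurstClassResult:
    labels: np.ndarray  # "DB" | "SB" per unit
    features: np.ndarray  # [LogISI PC1-3, ACG PC1], standardized
    linkage: np.ndarray  # scipy-style linkage record of the Ward tree
    burst_prob_db: float
    burst_prob_sb: float
    warnings: list[str]


def classify_db_sb(
    logisis: list[LogIsiHistogram],
    acgs: list[Autocorrelogram],
    burst_probs: np.ndarray,
    acg_lag_ms: float = 20.0,
    min_units: int = 10,
) -> BurstClassResult:
    """Ward clustering of units into dominantly vs sparsely bursting.

    PCA runs separately on the stacked log-ISI histograms and on the
    0-20 ms positive-lag autocorrelogram segments; the feature vector
    [LogISI PC1-3, ACG PC1] (standardized) is cut into 2 Ward clusters.
    The cluster with the higher mean burst probability is DB.
    """
    from scipy.cluster.hierarchy import cut_tree, linkage
    from sklearn.decomposition import PCA

    n = len(logisis)
    if n < min_units or n != len(acgs) or n != burst_probs.size:
        raise ValueError(f"need >= {min_units} units with matching features, got {n}")
    iso = np.stack([h.mass for h in logisis])
    acg_mat = []
    for a in acgs:
        m = (a.lags_ms > 0) & (a.lags_ms <= acg_lag_ms)
        acg_mat.append(a.counts[m])
    acg_mat = np.stack(acg_mat)

    pc_isi = PCA(n_components=3, random_state=0).fit_transform(iso)
    pc_acg = PCA(n_components=1, random_state=0).fit_transform(acg_mat)
    feats = np.column_stack([pc_isi, pc_acg])
    sd = feats.std(axis=0)
    feats = (feats - feats.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    Z = linkage(feats, method="ward")
    labels01 = cut_tree(Z, n_clusters=2).ravel()
    p0 = float(burst_probs[labels01 == 0].mean())
    p1 = float(burst_probs[labels01 == 1].mean())
    db_cluster = 0 if p0 > p1 else 1
    labels = np.where(labels01 == db_cluster, "DB", "SB").astype(object)
    p_db, p_sb = max(p0, p1), min(p0, p1)
    warnings = []
    if p_db - p_sb < 0.02:
        warnings.append("no burst structure: DB/SB burst-probability gap ~ 0")
    return BurstClassResult(labels, feats, Z, p_db, p_sb, warnings)


# ---------------------------------------------------------------------------
# Cycle skipping
# ---------------------------------------------------------------------------

@dataclass
class CycleSkipResult:
    a1: float  # primary theta peak (~0.1-0.15 s lag)
    a2: float  # secondary peak (~0.2-0.3 s lag)
    csi: float
    defined: bool
    reason: str = ""


def csi(
    acg: Autocorrelogram,
    primary_window: tuple[float, float] = (0.09, 0.16),
    secondary_window: tuple[float, float] = (0.19, 0.31),
    smooth_sigma_ms: float = 10.0,
    formula: str = "max",  # (A2-A1)/max(A1,A2); "sum" -> (A2-A1)/(A1+A2)
) -> CycleSkipResult:
    """Cycle skipping index from a smoothed autocorrelogram.

    A1 and A2 are the maxima of the Gaussian-smoothed (sigma = 10 ms)
    autocorrelogram in the primary and secondary lag windows; CSI =
    (A2 - A1)/max(A1, A2) (or /(A1 + A2) with ``formula='sum'``). CSI > 0
    indicates firing on alternate theta cycles. Intended for units with a
    significant theta index (gate applied by the caller).
    """
    lags_s = acg.lags_ms / 1000.0
    smooth = gaussian_filter1d(acg.counts, smooth_sigma_ms / acg.bin_ms)
    m1 = (lags_s >= primary_window[0]) & (lags_s <= primary_window[1])
    m2 = (lags_s >= secondary_window[0]) & (lags_s <= secondary_window[1])
    if not m1.any() or not m2.any():
        return CycleSkipResult(np.nan, np.nan, np.nan, False, "lag windows outside ACG")
    a1 = float(smooth[m1].max())
    a2 = float(smooth[m2].max())
    denom = max(a1, a2) if formula == "max" else a1 + a2
    if denom <= 0:
        return CycleSkipResult(a1, a2, np.nan, False, "no mass in either window")
    return CycleSkipResult(a1, a2, (a2 - a1) / denom, True)


# ---------------------------------------------------------------------------
# Interburst-interval band analysis
# ---------------------------------------------------------------------------

@dataclass
class LogIbiResult:
    freq_centers_hz: np.ndarray  # 1/IBI axis of the histogram
    mass: np.ndarray  # probability-normalized
    theta_band_integral: float  # 6-12 Hz
    half_theta_band_integral: float  # 4-6 Hz
    band_ratio: float  # theta / half-theta


def logibi_analysis(
    bursts: BurstSet,
    n_bins: int = 60,
    freq_range: tuple[float, float] = (0.5, 40.0),
    min_bursts: int = 5,
) -> LogIbiResult:
    """Log interburst-interval histogram with theta / half-theta integrals.

    IBIs between consecutive burst centers are histogrammed on a log
    1/IBI (Hz) axis; the probability masses inside 6-12 Hz and 4-6 Hz
    quantify cycle-by-cycle versus cycle-skipping bursting.
    """
    if bursts.n_bursts < min_bursts:
        raise ValueError(f"only {bursts.n_bursts} bursts (need >= {min_bursts})")
    ibis = np.diff(bursts.centers)
    freqs = 1.0 / ibis[ibis > 0]
    edges = np.logspace(np.log10(freq_range[0]), np.log10(freq_range[1]), n_bins + 1)
    counts = np.histogram(freqs, bins=edges)[0].astype(float)
    total = counts.sum()
    mass = counts / total if total > 0 else counts
    centers = np.sqrt(edges[:-1] * edges[1:])
    theta = float(mass[(centers >= 6.0) & (centers <= 12.0)].sum())
    half = float(mass[(centers >= 4.0) & (centers < 6.0)].sum())
    ratio = theta / half if half > 0 else np.inf
    return LogIbiResult(centers, mass, theta, half, ratio)
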