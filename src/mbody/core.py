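"""Core containers and shared signal utilities.

The package analyses paired local-field-potential (LFP) recordings from the
hippocampus (HPC) and the medial mammillary body (MB) together with sorted
single-unit spike trains and head tracking. Every downstream module consumes
the containers defined here.

Time is always seconds from the session start (``t0``); voltages are in
arbitrary units (all analyses are either normalized or threshold-relative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

THETA_BAND = (4.0, 12.0)
DELTA_BAND = (1.0, 4.0)
RIPPLE_BAND = (150.0, 250.0)
MB_EVENT_BAND = (100.0, 250.0)

STATES = ("AWK", "REM", "SWS")


@dataclass(frozen=True)
class LfpChannel:
    """One uniformly sampled voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage samples, arbitrary units.
    fs : float
        Sampling rate in Hz.
    region : str
        ``"HPC"`` or ``"MB"``.
    t0 : float
        Session time of the first sample, seconds.
    """

    samples: np.ndarray
    fs: float
    region: str = "HPC"
    t0: float = 0.0
    channel_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("LFP trace must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("LFP trace contains non-finite samples")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def index_of(self, t: float | np.ndarray) -> np.ndarray:
        """Nearest sample index for session time(s) ``t``."""
        idx = np.rint((np.asarray(t) - self.t0) * self.fs).astype(np.int64)
        return np.clip(idx, 0, self.samples.size - 1)

    def crop(self, start: float, end: float) -> "LfpChannel":
        """Sub-trace covering [start, end) in session time."""
        i0 = int(self.index_of(start))
        i1 = int(self.index_of(end))
        return LfpChannel(self.samples[i0:i1], self.fs, self.region,
                          self.t0 + i0 / self.fs, self.channel_id)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one unit over a session."""

    unit_id: int | str
    times: np.ndarray
    session_duration: float
    region: str = "MB"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        if times.ndim != 1:
            raise ValueError("spike times must be 1-D")
        if times.size and (np.any(np.diff(times) <= 0)):
            raise ValueError(f"unit {self.unit_id}: spike times not strictly increasing")
        if times.size and (times[0] < 0 or times[-1] >= self.session_duration):
            raise ValueError(f"unit {self.unit_id}: spikes outside [0, duration)")
        object.__setattr__(self, "times", times)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def mean_rate(self) -> float:
        return self.n_spikes / self.session_duration

    def shifted(self, shift: float) -> "SpikeTrain":
        """Circularly shift spike times within the session (wraps)."""
        t = np.sort(np.mod(self.times + shift, self.session_duration))
        return SpikeTrain(self.unit_id, t, self.session_duration, self.region)


@dataclass
class EpochSet:
    """Per-state merged analysis intervals ``{state: [(start, end), ...]}``."""

    epochs: dict[str, list[tuple[float, float]]]
    merge_gap: float = 60.0

    def __post_init__(self) -> None:
        for state, ivals in self.epochs.items():
            ivals.sort()
            for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
                if b0 < a1:
                    raise ValueError(f"{state}: overlapping epochs {a1} > {b0}")
            for a0, a1 in ivals:
                if a1 <= a0:
                    raise ValueError(f"{state}: empty epoch ({a0}, {a1})")

    def get(self, state: str) -> list[tuple[float, float]]:
        return self.epochs.get(state, [])

    def total_duration(self, state: str) -> float:
        return float(sum(e - s for s, e in self.get(state)))

    def mask_times(self, times: np.ndarray, state: str) -> np.ndarray:
        """Boolean mask of which ``times`` fall inside the state's epochs."""
        times = np.asarray(times)
        mask = np.zeros(times.shape, dtype=bool)
        for s, e in self.get(state):
            mask |= (times >= s) & (times < e)
        return mask

    def sample_mask(self, n: int, fs: float, state: str, t0: float = 0.0) -> np.ndarray:
        """Boolean mask over ``n`` samples at rate ``fs`` for the state."""
        t = t0 + np.arange(n) / fs
        return self.mask_times(t, state)


def intervals_from_labels(
    starts: np.ndarray, labels: Sequence[str], window_len: float
) -> dict[str, list[tuple[float, float]]]:
    """Convert per-window labels to raw per-state intervals (no merging)."""
    out: dict[str, list[tuple[float, float]]] = {}
    for s, lab in zip(starts, labels):
        out.setdefault(lab, []).append((float(s), float(s + window_len)))
    for lab, ivals in out.items():
        merged: list[tuple[float, float]] = []
        for a, b in sorted(ivals):
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        out[lab] = merged
    return out


# ---------------------------------------------------------------------------
# Filtering / envelope helpers (3rd-order zero-phase Butterworth throughout)
# ---------------------------------------------------------------------------

def bandpass(x: np.ndarray, fs: float, band: tuple[float, float], order: int = 3) -> np.ndarray:
    """Zero-phase forward-backward Butterworth bandpass."""
    lo, hi = band
    nyq = fs / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz not representable at fs={fs} Hz")
    sos = signal.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    return signal.sosfiltfilt(sos, x)


def envelope(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal."""
    return np.abs(signal.hilbert(x))


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Unwrapped Hilbert phase; 0 = signal peak, ±pi = trough."""
    return np.unwrap(np.angle(signal.hilbert(x)))


def phase_at_times(
    lfp: LfpChannel, band: tuple[float, float], times: np.ndarray
) -> np.ndarray:
    """Bandpass-filtered Hilbert phase interpolated at event times.

    Piecewise-cubic interpolation of the unwrapped instantaneous phase,
    rewrapped to [-pi, pi). Convention: 0 = filtered-signal peak.
    Times outside the trace support are dropped (caller sees the reduced set).
    """
    from scipy.interpolate import PchipInterpolator

    times = np.asarray(times, dtype=np.float64)
    filt = bandpass(lfp.samples, lfp.fs, band)
    phase = instantaneous_phase(filt)
    t = lfp.times
    keep = (times >= t[0]) & (times <= t[-1])
    interp = PchipInterpolator(t, phase, extrapolate=False)
    wrapped = np.mod(interp(times[keep]) + np.pi, 2 * np.pi) - np.pi
    return wrapped


def moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average with edge shrinkage (window clipped at edges)."""
    if n <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(n)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


# ---------------------------------------------------------------------------
# Session I/O: flat float32 binary + JSON sidecar for LFP, CSV for the rest
# ---------------------------------------------------------------------------

def write_session(
    path: str | Path,
    lfps: Iterable[LfpChannel],
    trains: Iterable[SpikeTrain],
    tracking: pd.DataFrame,
    manifest: dict | None = None,
) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, lfp in enumerate(lfps):
        stem = f"lfp_{lfp.region.lower()}_{i}"
        lfp.samples.astype(np.float32).tofile(path / f"{stem}.dat")
        (path / f"{stem}.json").write_text(
            json.dumps({"fs": lfp.fs, "region": lfp.region, "t0": lfp.t0})
        )
    rows = [
        {"unit_id": tr.unit_id, "time_s": t, "region": tr.region}
        for tr in trains
        for t in tr.times
    ]
    spikes = pd.DataFrame(rows, columns=["unit_id", "time_s", "region"])
    spikes.to_csv(path / "spikes.csv", index=False)
    tracking.to_csv(path / "tracking.csv", index=False)
    if manifest is not None:
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def read_session(path: str | Path) -> tuple[list[LfpChannel], list[SpikeTrain], pd.DataFrame]:
    path = Path(path)
    lfps = []
    for sidecar in sorted(path.glob("lfp_*.json")):
        meta = json.loads(sidecar.read_text())
        samples = np.fromfile(sidecar.with_suffix(".dat"), dtype=np.float32)
        lfps.append(
            LfpChannel(samples.astype(np.float64), meta["fs"], meta["region"],
                       meta.get("t0", 0.0), channel_id=sidecar.stem)
        )
    spikes = pd.read_csv(path / "spikes.csv")
    tracking = pd.read_csv(path / "tracking.csv")
    duration = max(lfp.duration for lfp in lfps) if lfps else float(tracking["t"].iloc[-1])
    trains = []
    if len(spikes):
        for uid, grp in spikes.groupby("unit_id", sort=True):
            region = str(grp["region"].iloc[0]) if "region" in grp else "MB"
            trains.append(SpikeTrain(uid, np.sort(grp["time_s"].to_numpy()), duration, region))
    return lfps, trains, tracking
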