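"""Synthetic session generator with ground truth.

Builds complete fake recording sessions — an HPC/MB LFP pair, head tracking,
and spike trains — whose statistical structure matches what the analysis
stages assume: state-scheduled oscillations (speed-dependent theta in
wake/REM, delta plus sharp-wave ripples in SWS), running bouts and head
turns, and units with configurable conjunctive tuning (speed, angular head
velocity, theta phase locking, bursting, cycle skipping, ripple-coupled
rate modulation).

Spikes are drawn by thinning a product intensity

    lambda(t) = B(t) * g_state(t) * g_phase(phi(t)) * g_swr(t) * g_skip(t)

where ``B`` is the behavioural rate (base rate plus additive speed and AHV
tuning, in Hz), ``g_phase`` a mean-one von Mises factor against the
generator's own theta phase, ``g_swr`` a gain inside +-125 ms of ripple
peaks, and ``g_skip`` a Bernoulli gate on alternate theta cycles. Bursting
units have each accepted event replaced by a short spike cluster at ~6 ms
intra-burst intervals. All randomness flows from one seed through a fixed
spawn order, so identical (config, seed) reproduce sessions bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import i0

from .core import LfpChannel, SpikeTrain, STATES

SWR_WINDOW_S = 0.125  # ripple-coupled gain applies within +-125 ms of peaks


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateSchedule:
    """Non-overlapping (start, end, label) intervals tiling [0, duration]."""

    intervals: tuple[tuple[float, float, str], ...]
    duration: float

    def __post_init__(self) -> None:
        ivals = tuple((float(s), float(e), str(lab)) for s, e, lab in self.intervals)
        object.__setattr__(self, "intervals", ivals)
        prev = 0.0
        for s, e, lab in ivals:
            if lab not in STATES:
                raise ValueError(f"unknown state label {lab!r}")
            if abs(s - prev) > 1e-9 or e <= s:
                raise ValueError("intervals must tile [0, duration] in order")
            prev = e
        if abs(prev - self.duration) > 1e-9:
            raise ValueError("intervals do not cover the full duration")

    def state_at(self, t: np.ndarray) -> np.ndarray:
        """State label per time point (array of 'AWK'/'REM'/'SWS')."""
        edges = np.array([s for s, _, _ in self.intervals] + [self.duration])
        labels = np.array([lab for _, _, lab in self.intervals])
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(labels) - 1)
        return labels[idx]

    def intervals_of(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, lab in self.intervals if lab == label]


def default_schedule(duration: float, awake_frac: float = 0.5) -> StateSchedule:
    """Awake block followed by SWS/REM alternation (REM ~20% of sleep)."""
    t_awk = round(duration * awake_frac, 3)
    intervals: list[tuple[float, float, str]] = []
    if t_awk > 0:
        intervals.append((0.0, t_awk, "AWK"))
    t = t_awk
    # SWS/REM alternation; REM bouts exceed the 60 s epoch-merge gap so
    # they separate neighbouring SWS epochs, and sleep always ends on SWS
    cycle = [("SWS", 150.0), ("REM", 90.0)]
    i = 0
    while t < duration - 1e-9:
        lab, length = cycle[i % 2]
        end = min(t + length, duration)
        intervals.append((t, end, lab))
        t = end
        i += 1
    if len(intervals) > 1 and intervals[-1][2] == "REM":
        s, e, _ = intervals.pop()
        if intervals and intervals[-1][2] == "SWS":
            ps, _, _ = intervals.pop()
            intervals.append((ps, e, "SWS"))
        else:
            intervals.append((s, e, "SWS"))
    return StateSchedule(tuple(intervals), duration)


@dataclass(frozen=True)
class UnitSpec:
    """True tuning parameters of one synthetic unit.

    speed_model: None, ("linear", slope_hz_per_cm_s, intercept_hz) or
        ("sigmoid", a, b, k, v0) giving rate a + b/(1+exp(-k(v-v0))).
    ahv_model: None or (cw_slope, ccw_slope) in Hz/(rad/s); clockwise is
        negative AHV, so the CW term ramps with -omega.
    phase_lock: None or (preferred_phase_rad, kappa) against HPC theta.
    burst_mode: "tonic" or "bursting" (events become ~6 ms ISI clusters).
    cycle_skip_prob: probability that an odd theta cycle is silenced.
    swr_gain: multiplicative rate factor within +-125 ms of ripple peaks.
    """

    unit_id: int
    base_rate: float = 5.0
    speed_model: tuple | None = None
    ahv_model: tuple[float, float] | None = None
    phase_lock: tuple[float, float] | None = None
    burst_mode: str = "tonic"
    intra_burst_isi_ms: float = 5.0
    spikes_per_burst: tuple[int, int] = (3, 6)
    cycle_skip_prob: float = 0.0
    # slow drift of the unit's oscillator against the LFP (rad, OU process);
    # gives the autocorrelogram comb its realistic decay across theta cycles
    phase_jitter_sd: float = 1.3
    phase_jitter_tau: float = 0.3
    swr_gain: float = 1.0
    state_rate_factors: tuple[float, float, float] = (1.0, 1.0, 1.0)  # AWK, REM, SWS
    region: str = "MB"

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        if not 0.0 <= self.cycle_skip_prob <= 1.0:
            raise ValueError("cycle_skip_prob must lie in [0, 1]")
        if self.swr_gain < 0:
            raise ValueError("swr_gain must be >= 0")
        if self.phase_lock is not None and self.phase_lock[1] < 0:
            raise ValueError("von Mises kappa must be >= 0")

    def behavioural_rate(self, speed: np.ndarray, ahv: np.ndarray) -> np.ndarray:
        """Rate B(v, omega) in Hz before multiplicative factors."""
        if self.speed_model is None:
            rate = np.full_like(speed, self.base_rate, dtype=float)
        elif self.speed_model[0] == "linear":
            _, slope, intercept = self.speed_model
            rate = intercept + slope * speed
        elif self.speed_model[0] == "sigmoid":
            _, a, b, k, v0 = self.speed_model
            rate = a + b / (1.0 + np.exp(-k * (speed - v0)))
        else:
            raise ValueError(f"unknown speed model {self.speed_model[0]!r}")
        if self.ahv_model is not None:
            cw, ccw = self.ahv_model
            rate = rate + cw * np.maximum(-ahv, 0.0) + ccw * np.maximum(ahv, 0.0)
        return np.maximum(rate, 0.0)


@dataclass(frozen=True)
class SessionConfig:
    duration: float = 1200.0
    lfp_fs: float = 1200.0
    tracking_fs: float = 10.0
    schedule: StateSchedule | None = None
    awake_frac: float = 0.5
    units: tuple[UnitSpec, ...] = ()
    # theta: frequency saturates with running speed
    theta_f0: float = 7.0
    theta_fgain: float = 1.5
    theta_vsat: float = 15.0
    theta_speed_linear: float | None = None  # Hz per cm/s, overrides saturation
    theta_amp: float = 2.0
    # descending (peak->trough) fraction of the theta cycle vs speed
    asym_d0: float = 0.5
    asym_dslope: float = -0.002
    delta_freq: float = 2.5
    delta_amp: float = 2.5
    noise_sd: float = 1.0
    mb_lag_s: float = 0.012
    mb_theta_amp: float = 1.6  # MB<->HPC coupling strength (free parameter)
    ripple_rate_hz: float = 0.35
    ripple_amp_sd: float = 8.0
    ripple_freq: float = 200.0
    ripple_dur_ms: float = 50.0
    mb_response_gain: float = 0.0  # MB LFP response events after each ripple
    mb_response_lag_s: float = 0.040
    # Ornstein-Uhlenbeck speed process (AWK)
    speed_mean: float = 18.0
    speed_sd: float = 12.0
    speed_tau: float = 4.0
    ahv_sd: float = 1.8
    ahv_tau: float = 0.5


@dataclass
class GroundTruthManifest:
    """True parameters and event/state times of one synthetic session."""

    seed: int
    schedule: StateSchedule
    unit_specs: tuple[UnitSpec, ...]
    ripple_times: np.ndarray
    speed_trace_params: dict

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "schedule": {
                "duration": self.schedule.duration,
                "intervals": [list(iv) for iv in self.schedule.intervals],
            },
            "unit_specs": [asdict(u) for u in self.unit_specs],
            "ripple_times": [float(t) for t in self.ripple_times],
            "speed_trace_params": self.speed_trace_params,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SyntheticSession:
    hpc: LfpChannel
    mb: LfpChannel
    tracking: pd.DataFrame
    trains: list[SpikeTrain]
    manifest: GroundTruthManifest
    truth: dict  # generator-internal traces: theta_phase, speed, ahv, ...


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def ou_process(
    n: int, dt: float, mean: float, sd: float, tau: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path."""
    x = np.empty(n)
    x[0] = mean + sd * rng.standard_normal()
    a = np.exp(-dt / tau)
    b = sd * np.sqrt(1.0 - a * a)
    eps = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        x[i] = mean + a * (x[i - 1] - mean) + b * eps[i - 1]
    return x


def _warp_phase(phase: np.ndarray, desc_frac: np.ndarray) -> np.ndarray:
    """Map linear cycle phase to an asymmetric waveform phase.

    ``desc_frac`` is the fraction of the cycle spent descending
    (peak -> trough). The returned phase drives cos(): the descending half
    [0, pi) occupies desc_frac of each cycle, the ascending half the rest.
    """
    cyc = np.mod(phase, 2 * np.pi) / (2 * np.pi)  # [0,1) within cycle, 0=peak
    d = np.clip(desc_frac, 0.2, 0.8)
    out = np.where(cyc < d, cyc / d * np.pi, np.pi + (cyc - d) / (1 - d) * np.pi)
    return out + 2 * np.pi * np.floor(phase / (2 * np.pi))


def inject_ripples(
    lfp: LfpChannel,
    times: Sequence[float],
    amp_sd: float,
    freq: float = 200.0,
    dur_ms: float = 50.0,
    sharp_wave_amp: float = 2.0,
) -> LfpChannel:
    """Add Gaussian-windowed ripple bursts on sharp-wave deflections.

    ``amp_sd`` is the target peak amplitude of the oscillation in units of
    the standard deviation of the input trace's 150-250 Hz band. The input
    channel is not modified.
    """
    from .core import bandpass, RIPPLE_BAND

    if not 150.0 <= freq <= 250.0:
        raise ValueError(f"ripple frequency {freq} Hz outside [150, 250]")
    times = np.asarray(times, dtype=float)
    for i, t in enumerate(times):
        if not (lfp.t0 <= t <= lfp.t0 + lfp.duration):
            raise ValueError(f"ripple time at index {i} ({t} s) outside trace")
    out = lfp.samples.copy()
    if times.size == 0 or amp_sd == 0:
        return LfpChannel(out, lfp.fs, lfp.region, lfp.t0, lfp.channel_id)

    band_sd = float(bandpass(lfp.samples, lfp.fs, RIPPLE_BAND).std())
    if band_sd == 0:
        band_sd = float(lfp.samples.std()) or 1.0
    raw_sd = float(lfp.samples.std()) or 1.0
    amp = amp_sd * band_sd
    sigma = dur_ms / 1000.0 / 4.0
    half = int(round(3 * sigma * lfp.fs))
    rel = np.arange(-half, half + 1) / lfp.fs
    burst = amp * np.exp(-(rel**2) / (2 * sigma**2)) * np.cos(2 * np.pi * freq * rel)
    sw_sigma = 2.0 * sigma
    sharp = -sharp_wave_amp * raw_sd * np.exp(-(rel**2) / (2 * sw_sigma**2))
    template = burst + sharp
    for t in times:
        c = int(round((t - lfp.t0) * lfp.fs))
        lo, hi = c - half, c + half + 1
        tlo, thi = max(0, -lo), len(rel) - max(0, hi - out.size)
        out[max(lo, 0) : min(hi, out.size)] += template[tlo:thi]
    return LfpChannel(out, lfp.fs, lfp.region, lfp.t0, lfp.channel_id)


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------

def _behaviour(
    cfg: SessionConfig, schedule: StateSchedule, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Speed (cm/s), angular velocity (rad/s), HD (rad) at tracking_fs."""
    dt = 1.0 / cfg.tracking_fs
    n = int(round(cfg.duration * cfg.tracking_fs))
    t = np.arange(n) * dt
    speed = ou_process(n, dt, cfg.speed_mean, cfg.speed_sd, cfg.speed_tau, rng)
    speed = np.clip(speed, 0.0, 60.0)
    ahv = ou_process(n, dt, 0.0, cfg.ahv_sd, cfg.ahv_tau, rng)
    ahv = np.clip(ahv, -5.0, 5.0)
    asleep = schedule.state_at(t) != "AWK"
    speed[asleep] = np.abs(0.2 * rng.standard_normal(asleep.sum()))
    ahv[asleep] *= 0.05
    hd = np.mod(np.cumsum(ahv) * dt, 2 * np.pi)
    return t, speed, ahv, hd


def _draw_ripple_times(
    cfg: SessionConfig, schedule: StateSchedule, rng: np.random.Generator
) -> np.ndarray:
    times: list[float] = []
    for s, e in schedule.intervals_of("SWS"):
        lo, hi = s + 0.5, e - 0.5
        if hi <= lo:
            continue
        n = rng.poisson(cfg.ripple_rate_hz * (hi - lo))
        times.extend(rng.uniform(lo, hi, size=n))
    times = np.sort(np.asarray(times))
    # enforce a comfortable minimum separation so events stay resolvable
    keep: list[float] = []
    for t in times:
        if not keep or t - keep[-1] >= 0.3:
            keep.append(float(t))
    return np.asarray(keep)


def _unit_spikes(
    spec: UnitSpec,
    cfg: SessionConfig,
    schedule: StateSchedule,
    beh_t: np.ndarray,
    speed: np.ndarray,
    ahv: np.ndarray,
    phase_t: np.ndarray,
    theta_phase: np.ndarray,
    theta_on: np.ndarray,
    ripple_times: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thinned inhomogeneous Poisson spikes (burst expansion included)."""
    T = cfg.duration
    b_grid = spec.behavioural_rate(speed, ahv)
    factors = dict(zip(STATES, spec.state_rate_factors))
    state_grid = np.array([factors[s] for s in schedule.state_at(beh_t)])

    # per-unit oscillator drift against the LFP phase (stationary OU, rad)
    uses_phase = spec.phase_lock is not None or spec.cycle_skip_prob > 0
    if uses_phase and spec.phase_jitter_sd > 0:
        drift = ou_process(beh_t.size, float(beh_t[1] - beh_t[0]) if beh_t.size > 1 else 0.1,
                           0.0, spec.phase_jitter_sd, spec.phase_jitter_tau, rng)
    else:
        drift = np.zeros(beh_t.size)

    # cycle gate: odd theta cycles silenced with prob cycle_skip_prob;
    # cycles are re-aligned so the preferred phase sits mid-cycle
    phi0 = spec.phase_lock[0] if spec.phase_lock is not None else 0.0
    n_cycles = int(np.ceil((theta_phase[-1] + 4 * np.pi) / (2 * np.pi))) + 2
    gate = np.ones(n_cycles)
    if spec.cycle_skip_prob > 0:
        odd = np.arange(1, n_cycles, 2)
        gate[odd] = (rng.random(odd.size) >= spec.cycle_skip_prob).astype(float)
        gate_mean = gate.mean() if gate.mean() > 0 else 1.0
    else:
        gate_mean = 1.0

    if spec.phase_lock is not None:
        _, kappa = spec.phase_lock
        phase_max = float(np.exp(kappa) / i0(kappa))
    else:
        phase_max = 1.0

    mean_burst = (
        0.5 * (spec.spikes_per_burst[0] + spec.spikes_per_burst[1])
        if spec.burst_mode == "bursting"
        else 1.0
    )
    event_scale = 1.0 / mean_burst

    lam_max = (
        float(b_grid.max() * state_grid.max())
        * phase_max
        * max(1.0, spec.swr_gain)
        / gate_mean
        * event_scale
    )
    lam_max = max(lam_max, 1e-6)
    n_cand = rng.poisson(lam_max * T)
    cand = np.sort(rng.uniform(0.0, T, size=n_cand))
    u = rng.random(n_cand)

    lam = np.interp(cand, beh_t, b_grid) * np.interp(cand, beh_t, state_grid)
    lam *= event_scale
    if uses_phase:
        psi = np.interp(cand, phase_t, theta_phase) + np.interp(cand, beh_t, drift)
        on = np.interp(cand, phase_t, theta_on.astype(float)) > 0.5
    if spec.phase_lock is not None:
        _, kappa = spec.phase_lock
        vm = np.exp(kappa * np.cos(psi - phi0)) / i0(kappa)
        lam = np.where(on, lam * vm, lam)
    if spec.cycle_skip_prob > 0:
        k = np.clip(((psi - phi0 + np.pi) // (2 * np.pi)).astype(int) + 2, 0, n_cycles - 1)
        lam = np.where(on, lam * gate[k] / gate_mean, lam)
    if spec.swr_gain != 1.0 and ripple_times.size:
        idx = np.searchsorted(ripple_times, cand)
        near_r = np.abs(cand - ripple_times[np.clip(idx, 0, ripple_times.size - 1)])
        near_l = np.abs(cand - ripple_times[np.clip(idx - 1, 0, ripple_times.size - 1)])
        near = np.minimum(near_r, near_l) <= SWR_WINDOW_S
        lam = np.where(near, lam * spec.swr_gain, lam)

    events = cand[u < lam / lam_max]

    if spec.burst_mode == "bursting":
        spikes: list[np.ndarray] = []
        lo, hi = spec.spikes_per_burst
        ns = rng.integers(lo, hi + 1, size=events.size)
        for t0, n in zip(events, ns):
            isis = np.empty(n - 1)
            isis[0] = rng.uniform(0.003, 0.006)
            if n > 2:
                isis[1:] = rng.uniform(0.003, 0.008, size=n - 2)
            spikes.append(t0 + np.concatenate(([0.0], np.cumsum(isis))))
        times = np.concatenate(spikes) if spikes else np.empty(0)
    else:
        times = events

    times = np.sort(times[(times >= 0) & (times < T)])
    if times.size > 1:  # 1 ms refractory floor keeps times strictly increasing
        keep = np.concatenate(([True], np.diff(times) >= 0.001))
        times = times[keep]
    return times


def generate_session(config: SessionConfig, seed: int) -> SyntheticSession:
    """Build one complete synthetic session deterministically from the seed."""
    cfg = config
    if cfg.duration <= 0:
        raise ValueError("duration must be positive")
    if cfg.lfp_fs < 600:
        raise ValueError(f"lfp_fs={cfg.lfp_fs} cannot represent 250 Hz ripples (need >= 600)")

    schedule = cfg.schedule or default_schedule(cfg.duration, cfg.awake_frac)
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(4 + len(cfg.units))
    rng_beh = np.random.default_rng(streams[0])
    rng_lfp = np.random.default_rng(streams[1])
    rng_rip = np.random.default_rng(streams[2])
    rng_mb = np.random.default_rng(streams[3])

    beh_t, speed, ahv, hd = _behaviour(cfg, schedule, rng_beh)

    # --- HPC LFP ---------------------------------------------------------
    n = int(round(cfg.duration * cfg.lfp_fs))
    t = np.arange(n) / cfg.lfp_fs
    state = schedule.state_at(t)
    theta_on = state != "SWS"
    v_lfp = np.interp(t, beh_t, speed)
    if cfg.theta_speed_linear is not None:
        f_theta = cfg.theta_f0 + cfg.theta_speed_linear * v_lfp
    else:
        f_theta = cfg.theta_f0 + cfg.theta_fgain * (1.0 - np.exp(-v_lfp / cfg.theta_vsat))
    theta_phase = 2 * np.pi * np.cumsum(f_theta) / cfg.lfp_fs
    desc = cfg.asym_d0 + cfg.asym_dslope * v_lfp
    theta_wave = np.cos(_warp_phase(theta_phase, desc))
    # the carrier phase units lock to is defined the way it is measured:
    # Hilbert phase of the theta-bandpassed waveform (0 = peak). With an
    # asymmetric wave this differs slightly from the linear cycle phase.
    from .core import THETA_BAND, bandpass, instantaneous_phase

    lock_phase = instantaneous_phase(bandpass(theta_wave, cfg.lfp_fs, THETA_BAND))
    lock_phase = np.maximum.accumulate(lock_phase)  # monotone for cycle counts

    delta_phase = 2 * np.pi * cfg.delta_freq * t
    hpc = cfg.noise_sd * pink_noise(n, rng_lfp)
    hpc[theta_on] += cfg.theta_amp * theta_wave[theta_on]
    sws = ~theta_on
    hpc[sws] += cfg.delta_amp * np.cos(delta_phase[sws])

    ripple_times = _draw_ripple_times(cfg, schedule, rng_rip)
    hpc_ch = LfpChannel(hpc, cfg.lfp_fs, "HPC", 0.0, "hpc0")
    if ripple_times.size:
        hpc_ch = inject_ripples(
            hpc_ch, ripple_times, cfg.ripple_amp_sd, cfg.ripple_freq, cfg.ripple_dur_ms
        )

    # --- MB LFP: lagged copy of the HPC oscillations + own noise ---------
    lag_n = int(round(cfg.mb_lag_s * cfg.lfp_fs))
    theta_lagged = np.roll(theta_wave, lag_n)
    mb = cfg.noise_sd * pink_noise(n, rng_mb)
    mb[theta_on] += cfg.mb_theta_amp * theta_lagged[theta_on]
    mb[sws] += 0.8 * cfg.delta_amp * np.cos(delta_phase[sws] - 2 * np.pi * cfg.delta_freq * cfg.mb_lag_s)
    mb_ch = LfpChannel(mb, cfg.lfp_fs, "MB", 0.0, "mb0")
    if cfg.mb_response_gain > 0 and ripple_times.size:
        resp_t = ripple_times + cfg.mb_response_lag_s
        resp_t = resp_t[resp_t < cfg.duration - 0.2]
        samples = mb_ch.samples.copy()
        half = int(round(0.06 * cfg.lfp_fs))
        rel = np.arange(-half, half + 1) / cfg.lfp_fs
        # slow trough lags the ripple by mb_response_lag_s; the fast
        # (100-250 Hz) component rides the ripple onset much earlier
        trough = -cfg.mb_response_gain * np.exp(-(rel**2) / (2 * 0.015**2))
        fast_lag = -0.6 * cfg.mb_response_lag_s  # relative to the trough
        fast = 0.5 * cfg.mb_response_gain * np.exp(
            -((rel - fast_lag) ** 2) / (2 * 0.008**2)
        ) * np.cos(2 * np.pi * 140.0 * (rel - fast_lag))
        for rt in resp_t:
            c = int(round(rt * cfg.lfp_fs))
            lo, hi = c - half, c + half + 1
            if lo >= 0 and hi <= samples.size:
                samples[lo:hi] += trough + fast
        mb_ch = LfpChannel(samples, cfg.lfp_fs, "MB", 0.0, "mb0")

    # --- spikes ----------------------------------------------------------
    trains: list[SpikeTrain] = []
    for spec, stream in zip(cfg.units, streams[4:]):
        rng_u = np.random.default_rng(stream)
        times = _unit_spikes(
            spec, cfg, schedule, beh_t, speed, ahv, t, lock_phase, theta_on,
            ripple_times, rng_u,
        )
        trains.append(SpikeTrain(spec.unit_id, times, cfg.duration, spec.region))

    # --- tracking table --------------------------------------------------
    dt = 1.0 / cfg.tracking_fs
    dx = speed * dt * np.cos(hd)
    dy = speed * dt * np.sin(hd)
    x = 65.0 + np.cumsum(dx) - dx[0]
    y = 65.0 + np.cumsum(dy) - dy[0]
    led = 2.0  # cm half-spacing of the two head LEDs
    tracking = pd.DataFrame(
        {
            "t": beh_t,
            "x": x,
            "y": y,
            "x1": x + led * np.cos(hd),
            "y1": y + led * np.sin(hd),
            "x2": x - led * np.cos(hd),
            "y2": y - led * np.sin(hd),
            "hd_rad": hd,
            "speed_cm_s": speed,
        }
    )

    manifest = GroundTruthManifest(
        seed=seed,
        schedule=schedule,
        unit_specs=tuple(cfg.units),
        ripple_times=ripple_times,
        speed_trace_params={
            "mean": cfg.speed_mean, "sd": cfg.speed_sd, "tau": cfg.speed_tau,
            "ahv_sd": cfg.ahv_sd, "ahv_tau": cfg.ahv_tau,
        },
    )
    truth = {
        "t_lfp": t,
        "theta_phase": lock_phase,
        "theta_phase_linear": theta_phase,
        "theta_on": theta_on,
        "theta_freq": f_theta,
        "t_beh": beh_t,
        "speed": speed,
        "ahv": ahv,
        "hd": hd,
        "state": state,
    }
    return SyntheticSession(hpc_ch, mb_ch, tracking, trains, manifest, truth)
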