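"""Configuration-driven orchestration of the full analysis suite.

Stages run in dependency order: channel selection -> sleep scoring ->
(ripples, tuning) -> bursting -> sleep dynamics, each writing tidy CSV
tables plus a JSON manifest of the configuration. Independent stages
continue when one fails; failures are recorded in the log.
"""

from __future__ import annotations

import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import sleep, spectral, swr, tuning, units as unit_prep, bursting, sleep_dynamics
from .config import PipelineConfig
from .core import LfpChannel, SpikeTrain, EpochSet, THETA_BAND, DELTA_BAND
from .synthetic import SessionConfig, SyntheticSession, UnitSpec, generate_session


@dataclass
class SessionBundle:
    lfps: list[LfpChannel]
    trains: list[SpikeTrain]
    tracking: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def select_channels(
    bundle: SessionBundle,
    sws: EpochSet | None = None,
    cfg: PipelineConfig | None = None,
) -> tuple[LfpChannel, LfpChannel]:
    """Pick the working HPC and MB channels.

    The HPC channel maximizes the sum of its rank by awake theta power and
    its rank by SWS ripple count; the MB channel maximizes theta power
    alone. With a single candidate per region the choice is trivial.
    """
    cfg = cfg or PipelineConfig()
    hpcs = [l for l in bundle.lfps if l.region == "HPC"]
    mbs = [l for l in bundle.lfps if l.region == "MB"]
    if not hpcs or not mbs:
        raise ValueError("need at least one channel per region")

    def theta_power(ch: LfpChannel) -> float:
        """Theta fraction of the normalized spectrum; 0 when undetectable.

        Detectability = theta-band mass at least half of what a flat
        spectrum would put there.
        """
        try:
            spec = spectral.multitaper_psd(ch, cfg.psd_nw, cfg.psd_n_tapers,
                                           min(cfg.psd_window_s, ch.duration / 2))
        except ValueError:
            return 0.0
        frac = spec.band_power(THETA_BAND)
        span = spec.freqs[-1] - spec.freqs[0]
        flat = (THETA_BAND[1] - THETA_BAND[0]) / span if span > 0 else 1.0
        return frac if frac > 0.5 * flat else 0.0

    tp = {id(ch): theta_power(ch) for ch in bundle.lfps}
    if all(p <= 0 for p in tp.values()):
        raise ValueError("no channel with detectable theta power")
    mb = max(mbs, key=lambda ch: tp[id(ch)])
    if len(hpcs) == 1:
        return hpcs[0], mb
    ripple_counts = {}
    for ch in hpcs:
        try:
            if sws is None:
                raise ValueError
            cands = swr.detect_ripples(ch, sws, cfg.swr_band, cfg.swr_thresh_sd, cfg.swr_min_sep_ms)
            ripple_counts[id(ch)] = int(swr.validate_ripples(cands, ch, sws, cfg.swr_band).valid.sum())
        except ValueError:
            ripple_counts[id(ch)] = 0
    theta_rank = {id(ch): r for r, ch in enumerate(sorted(hpcs, key=lambda c: tp[id(c)]))}
    ripple_rank = {id(ch): r for r, ch in enumerate(sorted(hpcs, key=lambda c: ripple_counts[id(c)]))}
    # rank sum decides; ties go to the channel with more ripples, then theta
    hpc = max(hpcs, key=lambda ch: (theta_rank[id(ch)] + ripple_rank[id(ch)],
                                    ripple_counts[id(ch)], tp[id(ch)]))
    return hpc, mb


def default_unit_population(n_units: int = 24, seed: int = 0) -> tuple[UnitSpec, ...]:
    """A mixed synthetic population covering every tuning class."""
    rng = np.random.default_rng(seed)
    specs: list[UnitSpec] = []
    for i in range(n_units):
        kind = i % 6
        base = float(rng.uniform(3.0, 8.0))
        speed_model = None
        ahv_model = None
        phase = None
        burst = "tonic"
        skip = 0.0
        gain = 1.0
        if kind == 0:
            speed_model = ("linear", float(rng.uniform(0.1, 0.3)), base)
        elif kind == 1:
            speed_model = ("sigmoid", base, float(rng.uniform(4.0, 8.0)),
                           float(rng.uniform(0.3, 0.6)), float(rng.uniform(15.0, 30.0)))
        elif kind == 2:
            phase = (float(rng.uniform(-np.pi, np.pi)), float(rng.uniform(2.0, 4.0)))
        elif kind == 3:
            phase = (float(rng.uniform(-np.pi, np.pi)), 3.0)
            burst = "bursting"
            skip = float(rng.choice([0.0, 0.85]))
        elif kind == 4:
            ahv_model = (float(rng.uniform(0.8, 1.5)), 0.0) if i % 2 else (0.0, float(rng.uniform(0.8, 1.5)))
        else:
            gain = float(rng.choice([3.0, 0.0]))
        specs.append(UnitSpec(
            unit_id=i, base_rate=base, speed_model=speed_model, ahv_model=ahv_model,
            phase_lock=phase, burst_mode=burst, cycle_skip_prob=skip, swr_gain=gain,
        ))
    return tuple(specs)


def run(
    config: PipelineConfig,
    session: SessionBundle | str | Path | None,
    out_dir: str | Path,
    synthetic_config: SessionConfig | None = None,
) -> dict:
    """Run every enabled stage and write result tables under ``out_dir``.

    ``session`` may be a SessionBundle, a session directory path, or None
    to generate a synthetic session (``synthetic_config`` or defaults).
    Returns a summary dict; per-stage failures are caught and logged.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    summary: dict = {"seed": config.seed}

    def stage(name):
        def wrap(fn):
            def runner():
                t0 = time.perf_counter()
                try:
                    fn()
                    log.append({"stage": name, "status": "ok",
                                "elapsed_s": round(time.perf_counter() - t0, 3)})
                except Exception as exc:  # independent stages continue
                    log.append({"stage": name, "status": "failed", "error": str(exc),
                                "trace": traceback.format_exc(limit=3),
                                "elapsed_s": round(time.perf_counter() - t0, 3)})
            return runner
        return wrap

    # --- load / generate -------------------------------------------------
    if session is None:
        syn_cfg = synthetic_config or SessionConfig(
            duration=600.0, mb_response_gain=3.0,
            units=default_unit_population(seed=config.seed))
        syn = generate_session(syn_cfg, config.seed)
        bundle = SessionBundle([syn.hpc, syn.mb], syn.trains, syn.tracking,
                               {"synthetic": True})
        (out / "manifest_truth.json").write_text(syn.manifest.to_json())
    elif isinstance(session, SessionBundle):
        bundle = session
    else:
        from .core import read_session

        lfps, trains, tracking = read_session(session)
        bundle = SessionBundle(lfps, trains, tracking, {"path": str(session)})

    duration = max(l.duration for l in bundle.lfps)

    # --- unit housekeeping ----------------------------------------------
    trains, removal_log = unit_prep.dedupe_units(
        bundle.trains, config.dedupe_overlap, config.dedupe_tol_s)
    trains = unit_prep.rate_filter(trains, config.min_rate_hz)
    summary["n_units_in"] = len(bundle.trains)
    summary["n_units_kept"] = len(trains)

    # --- behaviour -------------------------------------------------------
    speed = tuning.speed_trace(bundle.tracking)
    hd_t = bundle.tracking["t"].to_numpy(dtype=float)
    hd = bundle.tracking["hd_rad"].to_numpy(dtype=float) if "hd_rad" in bundle.tracking else None

    # --- sleep scoring ---------------------------------------------------
    state: dict = {}

    @stage("sleep")
    def _sleep():
        hpc0 = next(l for l in bundle.lfps if l.region == "HPC")
        ratio = sleep.theta_delta_ratio(hpc0, config.sleep_window_s,
                                        config.sleep_window_s - config.sleep_overlap_s)
        labels = sleep.classify_states(ratio, speed, config.td_threshold,
                                       config.speed_threshold_cm_s,
                                       config.sleep_window_s,
                                       config.sleep_window_s - config.sleep_overlap_s)
        epochs = sleep.build_epochs(labels, config.merge_gap_s)
        state["labels"] = labels
        state["epochs"] = epochs
        labels.table.to_csv(out / "hypnogram.csv", index=False)
        rows = [{"state": st, "start_s": s, "end_s": e}
                for st in ("AWK", "REM", "SWS") for s, e in epochs.get(st)]
        pd.DataFrame(rows, columns=["state", "start_s", "end_s"]).to_csv(
            out / "epochs.csv", index=False)
        summary["td_threshold"] = labels.threshold

    if config.run_sleep:
        _sleep()

    epochs: EpochSet | None = state.get("epochs")
    hpc, mb = select_channels(bundle, epochs, config)
    summary["hpc_channel"] = hpc.channel_id
    summary["mb_channel"] = mb.channel_id

    # --- ripples ---------------------------------------------------------
    swr_state: dict = {}

    @stage("swr")
    def _swr():
        cands = swr.detect_ripples(hpc, epochs, config.swr_band,
                                   config.swr_thresh_sd, config.swr_min_sep_ms)
        events = swr.validate_ripples(cands, hpc, epochs, config.swr_band,
                                      config.swr_validate_window_ms, config.swr_min_osc)
        swr_state["ripples"] = events
        pd.DataFrame({
            "peak_s": events.peak_times,
            "amplitude_sd": events.amplitudes_sd,
            "n_osc": events.n_oscillations,
            "valid": events.valid,
        }).to_csv(out / "ripples.csv", index=False)
        summary["n_ripples_valid"] = int(events.valid.sum())
        mb_events = swr.detect_mb_events(mb, epochs, config.mb_event_band,
                                         config.swr_thresh_sd, config.swr_min_sep_ms)
        swr_state["mb_events"] = mb_events
        summary["n_mb_events"] = int(mb_events.size)
        sws_ivals = epochs.get("SWS")
        if sws_ivals and events.valid.sum() >= 10:
            span = (sws_ivals[0][0], sws_ivals[-1][1])
            coup = swr.coupling_test(
                mb_events, events, span, config.coupling_window_ms / 1000.0,
                config.coupling_n_shuffle, config.coupling_alpha,
                seed=np.random.default_rng(config.seed + 1))
            summary["mb_swr_coupling"] = {
                "observed": coup.observed, "null_p99": coup.null_percentile_99,
                "significant": bool(coup.significant), "p": coup.p_value}

    if config.run_swr and epochs is not None and epochs.get("SWS"):
        _swr()

    # --- per-unit analyses -----------------------------------------------
    unit_rows: list[dict] = []
    acgs, logisis, bursts_by_unit = {}, {}, {}
    theta_phase = tuning.PhaseInterpolant(hpc, THETA_BAND)

    awk_epochs = epochs.get("AWK") if epochs is not None else [(0.0, duration)]
    rng = np.random.default_rng(config.seed + 2)

    for tr in trains:
        row: dict = {"unit_id": tr.unit_id, "region": tr.region, "rate_hz": tr.mean_rate}
        if config.run_bursting and tr.n_spikes >= 2:
            bs = bursting.detect_bursts(tr, config.burst_start_isi_ms / 1000.0,
                                        config.burst_continue_isi_ms / 1000.0,
                                        config.burst_min_spikes)
            bursts_by_unit[tr.unit_id] = bs
            row["n_bursts"] = bs.n_bursts
            row["burst_prob"] = bs.burst_probability
        if tr.n_spikes >= 2:
            acgs[tr.unit_id] = unit_prep.autocorrelogram(tr, config.acg_max_lag_s,
                                                         config.acg_bin_ms)
            logisis[tr.unit_id] = unit_prep.logisi_histogram(tr, config.logisi_bins)
        if config.run_tuning:
            try:
                ps = tuning.phase_entrainment_test(
                    tr, theta_phase, config.phase_n_shuffle, config.phase_shift_s,
                    seed=rng)
                row.update(mrv=ps.mrv, pref_phase_rad=ps.preferred_phase,
                           entrained=bool(ps.entrained), rayleigh_z=ps.rayleigh_z)
            except ValueError as exc:
                row["phase_note"] = str(exc)
            try:
                curve = tuning.speed_tuning(tr, speed, min_occupancy_s=config.min_occupancy_s)
                sel = tuning.fit_linear_sigmoid(curve)
                row.update(speed_class=(f"{sel.chosen}{'+' if sel.direction == 'positive' else '-'}"
                                        if sel.chosen != "none" else "none"),
                           speed_slope=sel.slope, speed_p=sel.p_linear,
                           bicw_linear=sel.bicw_linear, bicw_sigmoid=sel.bicw_sigmoid)
            except ValueError as exc:
                row["speed_note"] = str(exc)
            if hd is not None:
                try:
                    ahv = tuning.ahv_series(hd_t, hd)
                    ares = tuning.ahv_tuning_and_test(
                        tr, ahv, n_shuffle=config.ahv_n_shuffle,
                        shift_range=config.ahv_shift_s, seed=rng)
                    row.update(ahv_class=ares.classification,
                               ahv_cw_slope=ares.cw_slope, ahv_ccw_slope=ares.ccw_slope)
                except ValueError as exc:
                    row["ahv_note"] = str(exc)
            if tr.unit_id in acgs:
                ti, fpk = tuning.theta_index(acgs[tr.unit_id])
                row.update(theta_index=ti, theta_peak_hz=fpk)
        if config.run_bursting and tr.n_spikes >= 2:
            acg_fine = unit_prep.autocorrelogram(tr, config.acg_max_lag_s,
                                                 config.csi_acg_bin_ms)
            cs = bursting.csi(acg_fine)
            if cs.defined:
                row["csi"] = cs.csi
            bs = bursts_by_unit.get(tr.unit_id)
            if bs is not None and bs.n_bursts >= 5:
                ibi = bursting.logibi_analysis(bs)
                row["theta_band_ibi"] = ibi.theta_band_integral
                row["half_theta_band_ibi"] = ibi.half_theta_band_integral
        unit_rows.append(row)

    # --- DB / SB ---------------------------------------------------------
    @stage("db_sb")
    def _dbsb():
        mb_units = [tr for tr in trains
                    if tr.region == "MB" and tr.unit_id in logisis and tr.unit_id in bursts_by_unit]
        if len(mb_units) < 10:
            raise ValueError(f"only {len(mb_units)} MB units for DB/SB clustering")
        res = bursting.classify_db_sb(
            [logisis[tr.unit_id] for tr in mb_units],
            [acgs[tr.unit_id] for tr in mb_units],
            np.array([bursts_by_unit[tr.unit_id].burst_probability for tr in mb_units]))
        lab = dict(zip([tr.unit_id for tr in mb_units], res.labels))
        for row in unit_rows:
            if row["unit_id"] in lab:
                row["db_sb"] = lab[row["unit_id"]]
        summary["n_db"] = int(np.sum(res.labels == "DB"))
        summary["n_sb"] = int(np.sum(res.labels == "SB"))

    if config.run_bursting:
        _dbsb()

    # --- sleep dynamics --------------------------------------------------
    @stage("sleep_dynamics")
    def _dyn():
        ripples = swr_state.get("ripples")
        if ripples is not None and ripples.valid.sum() >= 20:
            ri_rows = {}
            for tr in trains:
                try:
                    resp = sleep_dynamics.swr_ri(
                        tr, ripples, config.psth_half_window_ms / 1000.0,
                        ri_half_window=config.ri_window_ms / 2000.0,
                        n_shuffle=config.ri_n_shuffle,
                        shift_range=config.ri_shift_s, seed=rng)
                    ri_rows[tr.unit_id] = (resp.ri, resp.classification)
                except ValueError:
                    continue
            for row in unit_rows:
                if row["unit_id"] in ri_rows:
                    row["swr_ri"], row["swr_class"] = ri_rows[row["unit_id"]]
            summary["n_swr_modulated"] = sum(
                1 for v in ri_rows.values() if v[1] != "ns")
        block = sleep.select_rem_block(epochs, config.min_rem_s) if epochs else None
        if block is not None:
            scores = sleep_dynamics.rate_scores(trains, block, epochs.get("AWK"))
            scores.to_csv(out / "rate_scores.csv", index=False)
            sync_rows = []
            for name, ep in zip(("SWS_pre", "REM", "SWS_post"), block):
                try:
                    s_val, n_pairs, _ = sleep_dynamics.synchrony(
                        trains, ep, config.synchrony_bin_ms / 1000.0)
                    sync_rows.append({"state": name, "synchrony": s_val, "n_pairs": n_pairs})
                except ValueError:
                    continue
            pd.DataFrame(sync_rows, columns=["state", "synchrony", "n_pairs"]).to_csv(
                out / "synchrony.csv", index=False)

    if config.run_sleep_dynamics and epochs is not None:
        _dyn()

    units_table = pd.DataFrame(unit_rows)
    units_table.to_csv(out / "units.csv", index=False)

    # --- spectral summary ------------------------------------------------
    @stage("spectral")
    def _spec():
        # theta comparisons on the longest awake block (sharp waves during
        # SWS leak into the theta band and corrupt cycle pairing)
        awk = max(awk_epochs, key=lambda iv: iv[1] - iv[0]) if awk_epochs else (0.0, duration)
        hpc_awk, mb_awk = hpc.crop(*awk), mb.crop(*awk)
        coh = spectral.coherence(hpc_awk, mb_awk)
        summary["theta_coherence_peak"] = coh.theta_peak
        try:
            lags, mean_lag, sd_lag = spectral.cycle_phase_lag(hpc_awk, mb_awk)
            summary["cycle_lag_mean_s"] = mean_lag
            summary["cycle_lag_sd_s"] = sd_lag
        except ValueError as exc:
            summary["cycle_lag_note"] = str(exc)
        gr = spectral.granger_pair(hpc, mb, config.granger_fs,
                                   config.granger_max_order, config.granger_alpha)
        summary["granger"] = {
            "order": gr.model_order,
            "theta_peak_hpc_to_mb": gr.theta_peak_xy,
            "theta_peak_mb_to_hpc": gr.theta_peak_yx,
            "significant_hpc_to_mb": bool(gr.significant_xy),
            "significant_mb_to_hpc": bool(gr.significant_yx),
        }

    if config.run_spectral:
        _spec()

    manifest = {"config": config.to_dict(), "log": log, "summary": summary}
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return summary
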