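"""Pipeline configuration with every analysis default in one place."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All thresholds, bands and shuffle counts used by the pipeline.

    Defaults are the values the analyses were designed around; any field
    can be overridden from a YAML mapping.
    """

    seed: int = 0

    # sleep scoring
    sleep_window_s: float = 10.0
    sleep_overlap_s: float = 4.0  # => 6 s hop
    speed_threshold_cm_s: float = 4.0
    td_threshold: float | None = None  # None -> automatic Otsu split
    merge_gap_s: float = 60.0
    min_rem_s: float = 30.0

    # SWR detection
    swr_band: tuple[float, float] = (150.0, 250.0)
    mb_event_band: tuple[float, float] = (100.0, 250.0)
    swr_thresh_sd: float = 4.0
    swr_min_sep_ms: float = 200.0
    swr_validate_window_ms: float = 20.0
    swr_min_osc: int = 5
    coupling_window_ms: float = 25.0
    coupling_n_shuffle: int = 1000
    coupling_alpha: float = 0.01

    # unit housekeeping
    dedupe_overlap: float = 0.05
    dedupe_tol_s: float = 0.0005
    min_rate_hz: float = 1.0
    acg_bin_ms: float = 1.0
    acg_max_lag_s: float = 0.5
    csi_acg_bin_ms: float = 0.5
    logisi_bins: int = 100

    # tuning
    speed_bin_cm_s: float = 1.0
    speed_range: tuple[float, float] = (1.0, 60.0)
    min_occupancy_s: float = 1.0
    ahv_bin_rad_s: float = 0.1
    ahv_range: tuple[float, float] = (-5.0, 5.0)
    ahv_window_s: float = 0.4
    ahv_n_shuffle: int = 500
    ahv_shift_s: tuple[float, float] = (20.0, 100.0)
    phase_n_shuffle: int = 1000
    phase_shift_s: tuple[float, float] = (-5.0, 5.0)

    # bursting
    burst_start_isi_ms: float = 6.0
    burst_continue_isi_ms: float = 8.0
    burst_min_spikes: int = 3

    # sleep dynamics
    synchrony_bin_ms: float = 100.0
    psth_half_window_ms: float = 500.0
    ri_window_ms: float = 250.0
    ri_n_shuffle: int = 1000
    ri_shift_s: tuple[float, float] = (-5.0, 5.0)

    # spectral
    psd_window_s: float = 10.0
    psd_nw: float = 3.0
    psd_n_tapers: int = 5
    granger_fs: float = 120.0
    granger_max_order: int = 50
    granger_alpha: float = 0.001

    # stage switches
    run_sleep: bool = True
    run_swr: bool = True
    run_tuning: bool = True
    run_bursting: bool = True
    run_sleep_dynamics: bool = True
    run_spectral: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        valid = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for k, v in raw.items():
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
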