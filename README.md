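# mbody

Analysis suite for paired **medial mammillary body (MB)** and **hippocampal
(HPC)** extracellular recordings across the sleep–wake cycle, together with a
synthetic-session generator that provides ground truth for every stage.

The medial mammillary bodies sit between the hippocampal formation and the
anterior thalamus and are implicated in spatial memory. Characterizing their
physiology in freely moving animals requires a long chain of LFP and
spike-train analyses; this package implements that chain as tested, reusable
components:

- **Spectral** (`mbody.spectral`) — multitaper power spectra normalized by
  their integral, magnitude-squared coherence, theta (4–12 Hz) cycle
  segmentation with ascending/descending asymmetry, per-cycle HPC↔MB phase
  lag, and spectral Granger causality from a bivariate VAR fitted with the
  Levinson–Wiggins–Robinson recursion (BIC order selection ≤ 50, Geweke's
  frequency-domain measure, F-test significance at α = 0.001).
- **Sleep scoring** (`mbody.sleep`) — theta/delta ratio in 10 s windows with
  6 s hop; ratio < threshold → SWS, else REM/AWK split at 4 cm/s; epochs
  merged across gaps < 60 s; REM-flanked-by-SWS block selection.
- **Sharp-wave ripples** (`mbody.swr`) — 150–250 Hz envelope peaks above
  mean + 4 SD of the SWS-indexed filtered signal, ≥ 200 ms apart, validated
  by ≥ 5 suprathreshold oscillations within 20 ms; MB high-frequency
  (100–250 Hz) events and their ±25 ms coupling to ripples against
  circular-shift nulls.
- **Unit housekeeping** (`mbody.units`) — duplicate-cluster removal (> 5 %
  shared spikes), < 1 Hz rate filter, normalized autocorrelograms, log-ISI
  histograms (0.001–10 s), waveform width/asymmetry, PYR/INT split.
- **Tuning** (`mbody.tuning`) — running-speed curves (1 cm/s bins, 1–60,
  ≥ 1 s occupancy) with linear-vs-sigmoid BIC-weight selection, spikes per
  theta cycle, theta phase entrainment (MRV vs 1000 circular shifts within
  ±5 s), MRV-vs-speed, spectral theta index, and AHV tuning (0.1 rad/s bins,
  ±5 rad/s, 400 ms slope windows, 500 shifts of 20–100 s).
- **Bursting** (`mbody.bursting`) — burst scan (open ISI ≤ 6 ms, extend
  ≤ 8 ms, ≥ 3 spikes), burst probability n_b/(n_b + n_spikes), DB/SB Ward
  clustering of [log-ISI PC1–3, 0–20 ms autocorrelogram PC1], cycle skipping
  index CSI = (A₂ − A₁)/max(A₁, A₂), and log inter-burst-interval band
  analysis (6–12 vs 4–6 Hz).
- **Sleep dynamics** (`mbody.sleep_dynamics`) — firing-rate scores
  (state − wake)/(state + wake), pairwise synchrony of 100 ms binned counts,
  SWR responsiveness index against a leave-one-out shuffle null, slow-wave
  (1–4 Hz) phase entrainment during SWS.
- **Synthetic sessions** (`mbody.synthetic`) — state-scheduled LFP (speed-
  dependent asymmetric theta, delta, injected ripples and MB response
  events), OU running speed and head turns, and spike trains realized by
  thinning a product intensity with configurable speed/AHV/phase/burst/
  cycle-skip/SWR-gain structure; bit-exact reproducible from (config, seed).
- **Pipeline** (`mbody.pipeline`, CLI `mbody`) — configuration-driven
  orchestration writing tidy CSV tables and a JSON run manifest.

## Worked example

```python
import numpy as np
from mbody import SessionConfig, UnitSpec, generate_session
from mbody import tuning

cfg = SessionConfig(
    duration=600.0,
    units=(UnitSpec(0, base_rate=5.0, phase_lock=(np.pi / 2, 4.0)),
           UnitSpec(1, base_rate=4.0, speed_model=("linear", 0.2, 1.0))),
)
session = generate_session(cfg, seed=42)

ps = tuning.phase_entrainment_test(session.trains[0], session.hpc, seed=1)
print(f"unit 0: MRV={ps.mrv:.3f}, preferred={ps.preferred_phase:.2f} rad, "
      f"entrained={ps.entrained}")

speed = (session.truth["t_beh"], session.truth["speed"])
sel = tuning.fit_linear_sigmoid(tuning.speed_tuning(session.trains[1], speed))
print(f"unit 1: slope={sel.slope:.3f} Hz/(cm/s), BICw(linear)={sel.bicw_linear:.2f}")
```

Output:

```
unit 0: MRV=0.238, preferred=1.56 rad, entrained=True
unit 1: slope=0.182 Hz/(cm/s), BICw(linear)=0.93
```

Unit 0 was built to prefer theta phase π/2 ≈ 1.57 with κ = 4; the measured
preferred phase (1.56 rad) recovers it and the shuffle test flags the unit
entrained (the MRV is diluted below the Bessel-ratio ceiling by the unit's
oscillator drift and by sleep-state spikes, which carry no theta). Unit 1
was built with a 0.2 Hz/(cm/s) linear speed gain; five awake minutes
recover the slope within ~9 % and the BIC weights favour the line over the
sigmoid (0.93 vs 0.07).

The full pipeline, from raw session to tidy tables:

```bash
mbody run --synthetic --seed 3 --out results/demo
mbody report results/demo
```

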