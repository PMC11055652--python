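# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic-data model used to validate every
stage, and the numerical choices made where the design was genuinely open.

## Signal path and conventions

All LFP filtering uses zero-phase forward–backward 3rd-order Butterworth
filters (`scipy.signal.sosfiltfilt`), in the bands: theta 4–12 Hz, delta
1–4 Hz, ripple 150–250 Hz, MB high-frequency events 100–250 Hz. Instantaneous
phase is the angle of the analytic (Hilbert) signal of the filtered trace,
unwrapped, interpolated at spike times (piecewise-cubic for one-off calls,
linear inside the reusable `PhaseInterpolant`, whose error at ≥ 600 Hz
sampling is negligible against a 4–12 Hz phase), and rewrapped to [−π, π).
**Phase convention: 0 = peak of the filtered signal, ±π = trough.** The
slow-wave "downstate" therefore sits at ±π.

Times are seconds from session start; voltages are arbitrary units — every
analysis is normalized (integral-1 spectra) or threshold-relative (SD
multiples), so gains cancel.

## Spectral analyses

*Multitaper PSD.* Slepian tapers (`scipy.signal.windows.dpss`), defaults
NW = 3, 5 tapers, 10 s non-overlapping windows (≈ 0.3 Hz half-bandwidth);
spectra averaged over tapers and windows, then divided by their trapezoidal
integral so channels with different electrode impedances are comparable.
The defaults mirror the common chronux-style configuration.

*Coherence.* Welch magnitude-squared coherence with 2 s segments: K ≈ 30
segments on a minute of signal keeps the |coherence|² bias (~1/K) well
below the 0.2 level used to interpret theta-band peaks.

*Theta cycles.* Cycle boundaries are peaks of the 4–12 Hz filtered trace
(minimum spacing one period at the upper band edge); peak and trough times
are then refined on a 1–25 Hz filtered copy. The broadband refinement is
essential for the ascending/descending asymmetry: narrowband filtering
discards the harmonics that carry waveform skew, so durations measured on
the 4–12 Hz trace alone are symmetric by construction. Cycles with periods
outside the band and cycles inside the ~1 s edge transient of the 1 Hz
highpass are unreliable; the cycle table keeps only plausible periods.

*Cycle-by-cycle phase lag.* For each HPC theta peak, the signed time to the
nearest MB theta peak within half a cycle (ties toward smaller |lag|);
positive = MB follows HPC. This is one reasonable per-cycle estimator; the
session statistic is its mean ± SD. In the pipeline it runs on the longest
awake block, because sharp-wave deflections during SWS leak into the theta
band and corrupt pairing.

*Granger causality.* Both channels are polyphase-decimated to 120 Hz,
standardized, and a bivariate VAR is fitted with Whittle's multichannel
Levinson (LWR) recursion on biased sample autocovariances — this yields
coefficients and residual covariances for every order ≤ 50 in one pass; BIC
(penalty 4p ln N / N) picks the order. The recursion was verified
coefficient-for-coefficient against OLS VAR (statsmodels) in the tests.
Spectral GC is Geweke's measure computed from the transfer function
H = (I − ΣAₖe^{−iωk})⁻¹ and the residual covariance; significance is the
time-domain nested-model F-test at α = 0.001. Near-identical inputs
(|r| > 0.999) and unstable fits (companion spectral radius ≥ 1) are
rejected with informative errors.

## Sleep scoring

Each 10 s window (6 s hop = 4 s overlap) gets a theta/delta ratio from its
multitaper spectrum after a 3-bin moving-average smooth, maximum
normalization and squaring (the squaring sharpens the contrast between
theta- and delta-dominated windows; the exact smoothing in the original
procedure is under-specified, so this pipeline is fixed, documented, and
configurable). Ratio < threshold → SWS; otherwise REM when window mean
speed < 4 cm/s, else AWK. The threshold defaults to an Otsu split of the
log-ratio distribution — an automatic, reproducible stand-in for the manual
global threshold used with real recordings — and can be overridden.
Same-state windows merge into epochs across gaps < 60 s; a REM bout shorter
than the merge gap is therefore legitimately absorbed into the surrounding
SWS epoch (realistic REM bouts exceed 60 s). The REM analysis block is the
longest REM epoch ≥ 30 s with SWS epochs before and after; because windows
overlap, epochs of different states may overlap by up to one window, and
the flank test tolerates that slack.

## Sharp-wave ripples

Candidates are envelope (analytic-signal magnitude) peaks of the 150–250 Hz
filtered HPC trace exceeding mean + 4 SD, where mean and SD come from
SWS-indexed filtered samples only; peaks closer than 200 ms are resolved in
favour of the larger. Validation counts extrema of the filtered trace —
both polarities, since a 20 ms window at 150–250 Hz holds only 3–5 full
cycles and single-polarity peaks could never reach five — whose magnitude
exceeds the same SD threshold within ±10 ms; valid events need ≥ 5.
Detection is invariant to positive rescaling of the trace. MB events reuse
the identical rules in the 100–250 Hz band (no separate parameters are
defined for them; both the band and threshold are configurable). Coupling
of MB events to ripples counts MB events within ±25 ms of any ripple
against 1000 circular shifts of the ripple times within the SWS span,
drawn uniformly from [30 s, span − 30 s] to avoid near-identity shifts;
significance is the 99th null percentile.

## Unit-level analyses

*Housekeeping.* Trains sharing > 5 % coincident spikes (±0.5 ms; the
tolerance is an assumption, configurable) lose the lower-rate member,
greedily from the highest overlap; the procedure is idempotent. Units under
1 Hz are dropped. Autocorrelograms cover ±0.5 s (1 ms bins; 0.5 ms for
cycle-skipping), exclude the zero-lag self-pairs, and are normalized to sum
to one. Log-ISI histograms use 100 log-uniform bins over 0.001–10 s.

*Speed.* The speed trace is the two-LED midpoint displacement rate,
resampled to 100 Hz and smoothed with a 100 ms moving average (100 Hz
retains everything in 10 Hz tracking at a fraction of the original
2.4 kHz-resampling cost; the rate is configurable). Tracking gaps > 1 s are
masked, not interpolated. Tuning curves use 1 cm/s bins over 1–60 with
≥ 1 s occupancy; occupancy is histogrammed from the same linearly
interpolated path used to attribute spike speeds (raw 10 Hz samples
over-represent excursion extrema and bias the upper bins downward).

*Linear-vs-sigmoid selection.* A conventional linear regression decides
whether a unit is speed-modulated (p < 0.05); only then is the sigmoid
r(v) = a + b/(1 + e^{−k(v−v0)}) fitted, by multi-start nonlinear least
squares (k ∈ {0.1, 0.3, 1} signed by the linear slope, v0 ∈ {10, 20, 30}
cm/s). Both fits and the BIC comparison are **occupancy-weighted**: a
binned rate's sampling variance scales as 1/occupancy, and unweighted
least squares lets the ~1 s tail bins (rate SD of several Hz) reward the
sigmoid's two extra parameters for chasing noise. BIC uses the Gaussian
residual likelihood with n = number of valid bins; weights
w_i = exp(−ΔBIC_i/2)/Σ. The reported slope, intercept and p-value remain
the unweighted regression.

*Phase statistics.* MRV length R = |mean unit phasor| (the literal reading
of "square root of the sum of the sin and cosine components" omits the
squaring and averaging; the standard R is implemented). Entrainment
compares the observed MRV with the 95th percentile of MRVs from 1000
circular shifts of the whole train, uniform in ±5 s, wrapping within the
session. Caveat (also logged): against a *constant-frequency* carrier a
global shift rotates all phases equally and leaves R unchanged, so the
null only has power because real (and synthetic) theta wanders in
frequency; likewise shifts shorter than the train's autocorrelation width
leave residual structure.

*Theta index.* FFT of the mean-subtracted ±0.5 s autocorrelogram; the
index is the power within ±1 Hz of the 4–12 Hz peak over total power. The
criterion for a *significant* index is not pinned down by the procedures
this follows; a circular shift of the whole train cannot serve as the null
because all pairwise lags — hence the autocorrelogram — are unchanged. The
package uses an independent per-spike jitter null (U(−5, 5) s, wrapping,
95th percentile), which destroys rhythmicity while preserving slow rate
structure.

*AHV.* Head direction is unwrapped, resampled to 100 Hz, smoothed (100 ms),
and AHV is the least-squares slope over a centred 400 ms window
(edge-masked). Tuning uses 0.1 rad/s bins over ±5 rad/s with ≥ 1 s
occupancy; separate regressions on the negative-AHV ([−5, 0], clockwise)
and positive-AHV ([0, 5]) halves. The shuffle circularly shifts the train
by U(20, 100) s, 500 times. One-sided tails are oriented so that *firing
that grows with angular speed in that direction* is detected — lower tail
for the negative-AHV slope, upper tail for the positive — at α = 0.01 per
direction; symmetric two-sided outcomes are reported alongside for
sensitivity.

*Bursting.* The burst scan opens on an ISI ≤ 6 ms, extends while ISIs stay
≤ 8 ms, keeps complexes of ≥ 3 spikes; each spike belongs to at most one
burst; the scan is verified against an exhaustive brute-force oracle on
1000 random trains. Burst probability divides bursts by bursts + *all*
spikes (documented reading; configurable). Burst centres are median spike
times (robust for burst-triggered averages). DB/SB classification runs PCA
separately on stacked log-ISI histograms (components 1–3) and 0–20 ms
autocorrelogram segments (component 1), standardizes the four features,
and cuts a Ward tree at two clusters; DB is the cluster with the higher
mean burst probability, and a near-zero DB−SB gap triggers a "no burst
structure" warning.

*Cycle skipping.* The CSI compares the smoothed (Gaussian σ = 10 ms)
autocorrelogram maxima in the primary (0.09–0.16 s) and secondary
(0.19–0.31 s) lag windows: CSI = (A₂ − A₁)/max(A₁, A₂), positive when the
unit fires on alternate theta cycles; (A₂ − A₁)/(A₁ + A₂) is available as
an option and both windows are configurable (the published windows are
approximate). The CSI is meaningful only for theta-rhythmic units; the
caller gates on the theta index. Log-IBI histograms (log 1/IBI axis,
0.5–40 Hz, probability-normalized) report integrals over 6–12 Hz
(cycle-by-cycle bursting) and 4–6 Hz (cycle skipping) and their ratio.

## Sleep dynamics

Rate scores (state − wake)/(state + wake) are computed for SWS-pre, REM
and SWS-post of the selected block; units silent in all three sleep states
are excluded. Synchrony is the mean within-region Pearson correlation of
non-overlapping 100 ms binned counts (zero-variance pairs skipped and
logged). The SWR responsiveness index is the unit's mean rate within
±125 ms of ripple peaks minus the mean of the same statistic over 1000
circular shifts (±5 s); the null distribution applies leave-one-out
centring — each shuffle's rate minus the mean of the other 999 — exactly
as specified, and the observed RI is classified against the null's 5th and
95th percentiles. PSTH rates pool spikes across events and divide by
(n events × window). Slow-wave phase entrainment reuses the theta
machinery on the 1–4 Hz band restricted to SWS spikes.

## The synthetic-session model

The generator exists to give every analysis a recoverable ground truth; it
is first-class, tested code.

*Behaviour.* Running speed is a stationary Ornstein–Uhlenbeck process
(mean 18 cm/s, SD 12, τ = 4 s) clipped to [0, 60] cm/s during wake and
≈ 0 during sleep; angular velocity is an OU process (SD 1.8 rad/s,
τ = 0.5 s) clipped to ±5 rad/s, integrated into head direction; x/y and
two LED positions are integrated from speed and heading. These choices
cover the analysis bins (1–60 cm/s, ±5 rad/s) with realistic occupancy.

*LFP.* 1/f (pink) background noise plus band-limited oscillations; default
1200 Hz sampling (configurable; ≥ 600 Hz enforced so the ripple band is
representable). Theta frequency saturates with speed,
f(v) = 7 + 1.5(1 − e^{−v/15}) Hz, and the waveform is asymmetric via a
piecewise-linear phase warp whose descending fraction falls with speed
(d = 0.5 − 0.002v). During SWS a 2.5 Hz delta oscillation replaces theta
and ripples (Gaussian-windowed 200 Hz bursts on slow negative sharp waves,
8 SD amplitude in band-SD units, ~0.35 Hz, ≥ 300 ms apart) are injected at
Poisson times. The MB channel carries the HPC oscillations lagged 12 ms
plus independent noise; its theta amplitude is the free MB↔HPC coupling
knob. Optional MB response events follow each ripple: a slow trough 40 ms
after the ripple peak with a faster 140 Hz component riding its rising
edge.

*Spikes.* Thinning of a product intensity
λ(t) = B(v, ω) · g_state · g_phase(ψ) · g_swr · g_skip, with B the
behavioural rate in Hz (base, or linear/sigmoid speed tuning, plus
additive per-direction AHV slopes), g_phase a mean-one von Mises factor,
g_swr a gain inside ±125 ms of ripple peaks, and g_skip a Bernoulli gate
silencing odd theta cycles with the skip probability (cycles re-aligned so
the preferred phase sits mid-cycle). Bursting units have each accepted
event replaced by a 3–6 spike cluster at 3–8 ms ISIs; a 1 ms refractory
floor keeps trains strictly increasing.

Two deliberate realism choices matter for validation. First, the carrier
phase units lock to is defined the way it is measured — the Hilbert phase
of the theta-bandpassed waveform — because for an asymmetric wave the
linear cycle phase and the measured phase disagree by up to ~0.25 rad, and
ground truth must live in the measurement convention. Second, each unit's
oscillator drifts against the LFP (stationary OU phase noise, SD 1.3 rad,
τ = 0.3 s): a unit locked to a globally coherent phase produces an
autocorrelogram comb with *no* decay across lags, which is
unphysiological and makes the CSI of non-skipping units a coin flip; the
drift reproduces the decaying comb of real theta cells.

*Determinism.* All randomness descends from one `SeedSequence(seed)`
spawned in fixed order (behaviour, HPC noise, ripples, MB noise, then one
stream per unit); identical (config, seed) reproduce sessions bit-exactly.

*What the generator does not emulate.* Spike waveform synthesis beyond
template + noise, volume conduction, biophysical neuron models,
non-stationary electrode drift, and realistic spike-sorting errors beyond
simple duplicated clusters. Passing validation therefore demonstrates that
the analyses recover the statistical structures they assume, not that they
are robust to every artefact of real recordings.

## Validation problem sizes

`mbody.validation` fixes the simulation scales: 1000 trains for the
burst-scan oracle; 500 null units per shuffle-calibration (300 s sessions;
600 s for the ripple-RI test with 80 events); 100 phase-locked units
(κ ∈ [2, 4], four 600 s sessions) for phase recovery; 20 units each
(900 s) for slope recovery and for each branch of the model-selection
check; 200+ injected ripples plus one clean 600 s trace for detector
precision/recall; 50 seeded 16-unit populations (240 s, 600 Hz LFP) for
DB/SB accuracy; 20 simulations per skip probability (600 s, 12 Hz bursting
theta units) for the CSI signs; 100 coupled and 1000 independent VAR pairs
(30 s at 120 Hz) for Granger direction and null calibration; one 900 s
session for sleep scoring; and two identically seeded 600 s pipeline runs
for determinism. These sizes keep the full validation around ten minutes
on one CPU while leaving comfortable margins on every criterion.

## Known limitations

- The per-cycle phase-lag estimator (nearest-peak pairing) is one of
  several defensible definitions; alternatives (e.g., instantaneous phase
  difference at peaks) would shift the per-session SD.
- The automatic Otsu threshold assumes a bimodal log theta/delta
  distribution; recordings dominated by a single state need a manual
  threshold.
- Granger significance uses the asymptotic F distribution; heavy
  autocorrelation at very low model orders can make it mildly liberal.
- The entrainment shuffle has no power against constant-frequency
  carriers (see above) — a property of the method, not the implementation.
- `fit_linear_sigmoid` treats binned rates as Gaussian; at very low rates
  a Poisson GLM would be more faithful.
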