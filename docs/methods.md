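# Methods

This note documents the models behind `cifes`: what each component assumes,
which parameters matter, how the synthetic data generator relates to real
recordings, and where the design was genuinely open.

## The virtual patient

### Gait kinematics

A subject is a `SubjectProfile`: normal laws for the per-cycle maximum ankle
angle (MaxAA), minimum ankle angle (MinAA) and gait-cycle duration (GCD),
one set for the affected side and one contralateral ("healthy") reference
set. Defaults:

| parameter | foot-drop (affected) | healthy reference | units |
|---|---|---|---|
| MaxAA mean / var | 105.53 / 28.84 | 100.72 / 10 | deg / deg² |
| MinAA mean / var | 80 / 16 | 70 / 8 | deg / deg² |
| GCD mean / var | 1.3 / 0.02 | 1.1 / 0.005 | s / s² |

The foot-drop MaxAA law and the healthy mean are the published operating
points this simulator is built around; the remaining values are not
published and were chosen once as physiologically plausible: foot-drop
patients dorsiflex less (higher MinAA), walk slower and more variably, and
healthy distributions are visibly more concentrated (variance well below the
patient's 17.71 assisted value).

Each cycle is rendered as two half raised-cosine segments
(peak → trough → next peak), so peaks and troughs are smooth and
unambiguous; the waveform shape between the summary statistics is free and
this choice makes peak-finding exact. Troughs are floored 6° below their
flanking peaks — a cycle whose trough nearly reaches its peaks has no
dorsiflexion excursion and is not a gait cycle; at the defaults this
touches < 0.2 % of draws and does not measurably move the MinAA law.
Half-cycle lead-in/out segments keep every peak interior to the trace.
Cycle durations are floored at 0.4 s.

The two IMU attitude traces are emitted as an even split of
`(ankle − 90°)`, so the reconstruction `IMU_up + IMU_down + 90°` is exact by
construction. Ground-truth swing onsets (the MaxAA instants, i.e. toe-off)
are annotated per side; the right side is phase-shifted half a cycle.

### Gait-locked sEMG

Muscle activity is modeled as 20–450 Hz band-limited Gaussian noise under a
burst-amplitude envelope (Hann lobes, 0.25 s wide) over a 0.02 V noise
floor. The RF fires a main lobe at each swing onset plus a 0.6-amplitude
stance lobe mid-cycle (patients lift the leg with normal or even stronger
RF drive); the TA fires one lobe per cycle around the dorsiflexion trough.
Default burst amplitudes: RF 0.9 V (foot drop) / 0.8 V (healthy), TA 0.8 V
healthy side, 0.3 V affected side — the affected TA attenuation is the
signature the switch-side electrode placement relies on. The noise floor is
sized so the default envelope stays below the 0.15 V trigger threshold
between bursts; the suite verifies no false triggering over hundreds of
cycles.

What this generator does **not** emulate: motor-unit structure, electrode
impedance drift, powerline interference, movement artifacts, inter-subject
waveform variability, or stimulation crosstalk into the recording
electrodes (a distance-attenuation artifact exists in hardware; electrode
separation makes it negligible and it is not modeled). Passing tests
therefore demonstrate the *logic* of the chain — thresholds, timing,
modulation, convergence — not robustness to every artifact of a clinical
recording.

### Stimulation plant

Delivered peak voltage V produces an assistance (degrees)

    a(V) = s_f · G · V² / (V² + V₅₀²)

with `G = 4.81°` (the unassisted-to-healthy MaxAA gap), `V₅₀ = 175.31 V`,
and `s_f ∈ (0, 1]` the fatigue response scale. The squared-Hill form gives
the observed "slight incline then saturation" of dorsiflexion vs.
intensity; frequency dependence is weak over the usable range and the plant
is fixed at the 33 Hz operating point. The assisted per-cycle law is

    MaxAA ~ N(m − f·(m − m_h),  v·(1 − 0.6825·f)),   f = a(V)/G,

and MinAA/GCD means shift toward the healthy reference by the same fraction
`f`. The mean can never overshoot below the healthy reference because
`f ≤ 1`. `V₅₀` and the variance-shrink coefficient are solved so that at a
200 V operating point (mid-range of the deliverable 138–240 V span) a fresh
plant reproduces the assisted law N(102.81°, 17.71) exactly — the
calibration identity the test suite pins.

### Fatigue

Each stimulation site accumulates load `L` with first-order recovery,
`dL/dt = rate − L/τ`, τ = 600 s, and the response scale is
`s_f = exp(−k·max(L))` with `k` set so that 900 s of continuous single-site
stimulation at unit exposure rate drops the response by 25 % — the
qualitative gap between single- and dual-channel fatigue runs. Because only
the *maximum* per-site load matters, splitting a fixed total exposure over
n sites always yields a response scale at least as high as one site taking
it all; the suite checks this on a load grid.

## Signal chains

**Envelope** (`emg.envelope`): gain → |·| → 2nd-order causal Butterworth
low-pass (10 Hz) → trailing windowed mean (50 ms), then an optional 3.3 V
acquisition clamp (on by default, matching a 0–3.3 V ADC stage). The stage
list is the hardware's; orders and cutoffs are unpublished, so a 2nd-order
filter and 50/100 ms windows were chosen to turn one physiological burst
into one smooth peak. Anchors tested: zero in/zero out, constant A →
gain·A, zero-mean sine of amplitude A → gain·2A/π within 2 %, sign-flip
invariance, degree-1 homogeneity.

**Switch** (`switching.threshold_switch`): a crossing is a sample strictly
beyond the threshold preceded by at least one sample on the other side
(deterministic on discrete samples; a trace that starts beyond the
threshold does not trigger). The on-state persists for
max(countdown, time-beyond-threshold); onsets within the refractory of the
previous onset are ignored. Defaults: countdown 0.8 s (covers a swing phase
at the default GCDs), refractory 0.3 s. No hysteresis by default (single
published thresholds); a release threshold is available.

**Stimulus** (`stim`): counts→voltage is linear between the two published
anchors (20, 138 V) and (140, 255 V), clamped outside; the intermediate
curve is unpublished. Pulses are biphasic 1:2 (200 µs anodic at +V, 400 µs
cathodic); the cathodic amplitude is V/2 so phase charges cancel exactly on
the sample grid — standard safe-stimulation practice; the hardware's actual
cathodic amplitude is unpublished, and `equal_amplitude=True` renders the
non-balanced ±V variant. The 16.67 kHz / 83.3 % carrier is an implementation
detail of the boost stage and is off by default (rendering it demands
≥ 167 kHz sampling); the envelope-level waveform is used everywhere else.
Intensity is sampled-and-held at each pulse onset.

## The controller

Per cycle: record the healthy TA envelope while above T1 = 0.15 V (first
maximal supra-threshold segment), resample it to 100 points, peak-normalize
— the intensity template (storage is released after each use, as in the
embedded implementation). On the affected RF envelope crossing T2 = T1,
drive `counts(t) = clamp(count_min + gain·template(t)·(count_max −
count_min), 0, count_max)` over the 0.8 s stimulation window and deliver
`min(map(counts), 240 V)` to the plant.

The gain law is the genuinely open design point: the hardware burns a
"multiplier" from host feedback without publishing the rule. Chosen here: a
clamped multiplicative proportional update,

    gain' = clamp(gain · (1 + η·(mean(MaxAA over last 5 cycles) − target)))

with η = 0.02 /deg, bounds [0, 2], target = the healthy reference mean
100.72°, and a ±2° deadband in which the gain is held. Multiplicative
updates are scale-invariant and bounded; MaxAA above target (insufficient
assistance) raises the gain. With η = 0 the loop reduces exactly to
open-loop template-modulated FES (ablation identity, tested). On a healthy
profile the MaxAA already sits inside the deadband, so the gain holds
still — no wind-up on normal gait.

Because the plant saturates near 102.4° at the 240 V cap while the deadband
edge is 102.72°, the converged loop hovers at the deadband edge with the
gain near its rail; fatigue over a 300-step run (response scale ≈ 0.89)
lands the final-window statistics on the assisted law. In the loop the
delivered peak is computed through the calibration map and cap without
rendering each 200 µs pulse on a dense grid — the plant responds to the
peak voltage only, and full-rate rendering is available through the `stim`
module and CLI. Simulation sampling rate defaults to 1 kHz (enough for
20–450 Hz sEMG content).

## Gait analytics

Cycle segmentation uses peak finding with 3° prominence and a minimum peak
separation of 0.4× the expected GCD (both unpublished in the source
system; these defaults suppress noise-induced double peaks at the default
profiles). One cycle per adjacent-peak pair: MaxAA is the opening peak,
MinAA the deepest interior trough, GCD the inter-peak spacing, and the
maximum angular velocity is taken over the dorsiflexion interval
(trough → closing peak), with velocity from a central finite difference.
Distribution summaries bin at a fixed width (5° default) aligned to
bin-width multiples, but the reported mean and variance are computed from
the raw values (unbiased, n−1 divisor — the divisor is unpublished), so
they are invariant to binning.

## Rehabilitation SVM

The 8-D feature matrix pairs left/right cycles by index (unpaired trailing
cycles dropped, logged) in a fixed column order. The classifier is an RBF
SVM whose kernel scale follows the median heuristic,
γ = 1/(2·median(pairwise distance)²), on standardized rows — "median
Gaussian kernel" names a library preset, not a formula, so the standard
heuristic is declared. Standardization was added (unmentioned in the
source) because the features mix degrees, deg/s and seconds, and a
distance-based kernel would otherwise be dominated by the angle columns.
Both the scaler and the median are fit per fold on training rows only; a
leakage probe test (a wild-scale noise column) verifies validation rows
cannot influence the kernel scale. Cross-validation is stratified k-fold
(k = 10), accuracy the average of fold accuracies, confusion from pooled
out-of-fold predictions, ROC one-vs-rest from decision values. The
rehabilitation trend scores each treatment session by the binary
session-vs-reference CV accuracy; clinical accuracies (93.3 % six-class,
100→92.5 % day series) depend on unavailable patient recordings and are
covered by property-level surrogates instead: separable → 1.0, identical →
chance, and a synthetic recovery schedule decays monotonically in
expectation.

## fNIRS

Motion correction: artifact samples are those whose centered 1 s moving SD
exceeds 3× the trace's median moving SD; runs closer than 1.5 detection
windows are merged (a boxcar artifact spikes the variance only at its
edges). Within each segment a cubic smoothing spline (smoothing level set
to the clean-noise power) is subtracted and the segment re-leveled onto the
line joining its clean neighbors; everything else is untouched. The method
is idempotent on its own output, and all of window/threshold/smoothing are
declared choices — the source names only "spline interpolation".

Band-pass: 3rd-order Butterworth 0.01–0.2 Hz applied forward-backward
(zero-phase); DC is rejected, the 0.05 Hz mid-band is preserved within 5 %,
and the 1 Hz cardiac band is attenuated > 90 %.

Beer–Lambert: per sample, the 2×2 system
`ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ)` is solved for the
concentration changes (reported in µmol/L); HbT = HbO + HbR. Bundled
defaults — 760/850 nm extinction coefficients (0.586/1.548 and 0.691/1.058
mM⁻¹cm⁻¹ for HbO/HbR), d = 3 cm, DPF = 6 — are standard literature values;
the source device's wavelengths and coefficients are unpublished, and all
are overridable. (The source text prints HbO ranges in inconsistent units —
mmol L⁻¹ mm⁻¹ in one place, µmol L⁻¹ in another; this implementation
reports µmol/L throughout.) Block averaging subtracts each block's onset
value before averaging; the task-window variance is the unbiased variance
over the first 45 s of task.

## Problem sizes and numerical choices

The test suite exercises walks of 10–250 steps, 300-step closed-loop runs
over 20 seeds, a 50-seed convergence sweep at 100 steps, 1,000-cycle
generator recovery at 200 Hz, and 600-row CV problems — sizes chosen so the
whole suite runs in under a minute on one core while keeping every
statistical bound at least 3 standard errors wide. Kinematics-only checks
run at 200 Hz; anything touching sEMG runs at 1 kHz; pulse-train rendering
tests run at 100–500 kHz for microsecond-phase resolution. Stochastic
assertions fix their seeds; generator determinism (equal seed → bit-equal
output) is itself under test.

## Known limitations

- The plant is statistical, not biomechanical: stimulation shifts the
  moments of per-cycle draws; it does not simulate muscle dynamics within a
  cycle, spasticity, or voluntary compensation.
- Fatigue is a single scalar per site with exponential recovery; real
  fatigue shows slow/fast components and history effects beyond first
  order.
- The gain law is this package's design; the embedded original is
  unpublished, so quantitative gain trajectories are not comparable —
  only the converged statistics are.
- Sensor transport (WiFi in hardware) is an in-process call with an
  optional pure delay, default 0 s; packet loss and jitter are not modeled.
- fNIRS processing is per-channel; no optode geometry, short-channel
  regression or cortical mapping.
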