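# Methods

## Scope and design

The package simulates, offline, a real-time system: closed-loop auditory
stimulation (CLAS) of rat sleep slow waves. The online side (staging gate,
phase detector, trigger logic) is implemented as a streaming algorithm —
causal filters with carried state, trailing windows, per-sample decisions —
so that chunked and single-pass processing are sample-identical, and the
whole loop is deterministic given its inputs. The offline side reproduces
the analysis pipelines that quantify what the loop did. Inferential
statistics that standard software performs on the exported tables
(RM-ANOVA, mixed count models, post-hocs) are out of scope by design; the
package computes their inputs.

## Online staging and calibration

Staging statistics are band rms values on 1 s windows of causally filtered
signal: EEG delta 0.5–4 Hz and high-beta 20–30 Hz (second-order Butterworth
band-passes, i.e. two cascaded biquads — steep enough to keep cross-band
leakage of a pure in-band tone below ~2 %), and EMG 5 Hz–min(525, 0.45·fs)
Hz with a 50 Hz notch (≥40 dB). The EMG upper edge follows the acquisition
chain's anti-aliasing limit of 45 % of the sampling rate; at the native
610.35 Hz a 525 Hz edge is above Nyquist and is applied by hardware before
digitization in the real system. The broadband EEG chain (0.1–36 Hz) is a
single biquad, as in the reference hardware.

Calibration uses *stepped* (non-overlapping) 1 s windows, assigning each
window to the 4 s scoring epoch containing its midpoint; the online gate
uses *sliding* (trailing per-sample) windows. Whether the reference system
stepped or slid during calibration is not documented; the stepped choice
makes calibration values independent and the sliding choice makes the gate
react with 1-sample granularity. Thresholds are mean + 1 SD (NREMratio) and
mean − 1 SD (EMG rms, clipped at 0) over plain (non-artifact) NREM epochs,
with the sample SD (n − 1): the convention of common statistical software.
Under normality these sit at the 84.1 % and 15.9 % percentiles
(`zscore_percentile`). Artifact-flagged NREM epochs are excluded so that
perturbations do not shape the gates.

## Phase detection and trigger logic

The phase detector operates on a second-order resonator (peak filter)
centered at the nominal component frequency f₀ = 1 Hz with 0.6 Hz
bandwidth (the reference system documents only a "very narrow band-pass").
Phase is a linear ramp from each rising zero-crossing at 360·f₀ degrees per
second, clamped below 360°, undefined before the first crossing. The ramp
deliberately uses the *nominal* frequency, not the instantaneous period:
rat slow oscillations peak near 1.35 Hz, so real cycles outrun the ramp and
achieved phase overshoots the target. This bias is a property of the
method being modeled and is reproduced, not corrected.

One trigger at most is emitted per zero-crossing-delimited cycle, at the
first sample where the ramp has reached the target *and* the gate holds;
the detector re-arms at the next rising crossing. Logged onset = crossing
time + configurable latency (default 0 for algorithm testing; a 29.3 ms
preset mirrors the reference hardware's mean detection-to-trigger delay).
The mock condition runs the identical loop with the mute flag set. No
minimum gate dwell is imposed before the first trigger (not documented in
the reference; configurable by pre-gating the decisions).

The stimulus is a peak-normalized pink-noise (1/f amplitude) burst, 30 ms
with 2 ms linear ramps; its sound level (35 dB SPL) is metadata, since
free-field calibration is a hardware property. The 30 ms duration follows
from scaling the 50 ms human protocol at 0.8 Hz to the rat's 1.35 Hz peak
(`scale_stimulus_duration`).

## Offline validation

Per-second gate decisions are grouped into non-overlapping blocks of four;
a block is online-NREM iff ≥ 2 seconds were true. Sensitivity, specificity
and precision are computed against the reference hypnogram with plain N as
the positive class; artifact-flagged epochs count as negatives (they are
not sustained NREM) and are reported separately in the trigger breakdown.
On default synthetic data the pipeline sits in the intended strict-gate
regime: specificity near 1, sensitivity of a few percent, trigger
proportions strongly enriched in NREM relative to time in NREM.

## Spectral pipeline

EEG is resampled to 300 Hz (polyphase), edge-tapered, and band-limited
0.5–48 Hz with zero-phase equiripple FIR filters (orders 1880/398 as in the
reference chain; achieved half-amplitude cutoffs 0.284/49.15 Hz against the
documented 0.28/49.12 Hz). The edge taper is a Fermi (logistic) window
w(n) = 1/(1 + exp(5 − n/50)) over the first and last 600 samples (2 s),
passing 0.5 at n = 250; the published formula is typographically garbled
and this is the only reading that attenuates the edges gradually.
Forward–backward FIR filtering is implemented with FFT convolution
(mathematically identical to filtfilt with the same kernel, O(N log N) at
multi-thousand-tap orders).

Within plain-NREM epochs, runs of fewer than 10 consecutive samples
exceeding ±8× the interquartile range are repaired by cubic-spline
interpolation from up to 8 flanking samples per side; longer runs are
logged untouched. The IQR is local: computed over NREM samples within ±1 h
of 10 min grid centers, nearest-center lookup (the reference describes a
2 h sliding inspection window without a step size).

Spectra are 4 s Hamming periodograms at 2 s hops, averaged within each
scoring epoch (segments are assigned to the epoch containing their
midpoint, so interior epochs average two segments), giving 0.25 Hz bins.
Each epoch's bins are normalized by its total power over 0.5–30 Hz; a
per-day normalization denominator is an alternative reading of the source
("daily total power") and can be obtained by aggregating the raw spectra,
but per-epoch is the default because it is robust to within-day
nonstationarity. Bands are half-open (low, high], assigned by bin center:
delta 0.5–4, theta 4–8, alpha 8–11, sigma 11–16, beta 16–20 Hz (default),
with a 16–30 Hz beta variant (`WIDE_BANDS`) because the source uses both.
Artifact epochs are excluded from spectral averages but count toward NREM
minutes. Change from baseline is 100·(x − x_BL)/x_BL per matched day/hour
key; contrasts between change series are reported in percentage points.
The fragmentation index is NREM bouts (maximal runs of NREM epochs) per
NREM epoch.

## Trigger and ERP analyses

Trains are maximal runs of triggers with consecutive gaps ≤ 1 s (0.8 s
preset available; the source uses both thresholds in different places),
sizes ≥ 5 pooled; the histogram conserves the trigger count. ISIs are
binned into a probability density over log-spaced default edges
0.5–256 s (the source leaves bin sizes open). ERPs are 3.5 s windows
(−1.5/+2.0 s; the source fixes the total length and the 2 s post-stimulus
cutoff, leaving 1.5 s pre-stimulus) around NREM triggers with post-ISI
> 1 s, band-passed 0.5–2 Hz zero-phase (FIR orders 3758/3861; achieved
−6 dB cutoffs 0.390/1.910 Hz vs the documented 0.39/1.91).

Phase at trigger onsets is the Hilbert angle of the 0.5–2 Hz component
mapped to the slow-wave convention (+90°, putting the positive peak at 90°
and the trough at 270°), summarized by the circular mean and resultant
length R, with dispersion reported both as circular SD √(−2 ln R) and as
1 − R (plus the angular deviation √(2(1 − R)) in degrees), because the
source's "Var" in degrees is ambiguous between conventions. Histograms use
six 60° bins normalized per subject.

## Behavior

Success/fail rates default to successes (fails) per attempt, drop-ins
excluded from the numerators but retained in the denominator; a
"per 100 possible attempts" mode implements the alternative definition in
the source protocol. Intra-session change is log₂(last-bin/first-bin
successes). The exclusion rule removes an animal only if SR < 10 % on
*every* motor-training day from day 2 onward; exactly 10 % keeps. The
ANOVA sample-size routine evaluates noncentral-F power with
λ = n·Σ(μᵢ − μ̄)²/σ² (df₁ = k − 1, df₂ = k(n − 1)) — the convention of R's
`power.anova.test`, verified to give n = 8 for the study design — and
returns the smallest n reaching the target power.

## Synthetic data

The generator emulates exactly the features downstream stages consume.
Stages follow a semi-Markov chain (exponential dwells; W→N, N→{W with 0.8,
R with 0.2}, R→W; W→R excluded as physiologically rare in rats) quantized
to 4 s epochs; dwell means 200/250/80 s for W/N/R give roughly half the
time asleep. The chain starts in wake (animals are awake at recording
onset), so short simulations can contain little or no sleep — calibration
requires a duration of several dwell cycles. NREM EEG is an amplitude-modulated sinusoidal slow oscillation
at 1.35 Hz (45 µV, ±25 % envelope at 0.05 Hz) — a sinusoid rather than a
sawtooth because the phase detector and ERP analysis only assume a dominant
~1 Hz component — plus sigma-band spindle bursts (90 µV, 0.4 s⁻¹, 0.7 s)
over a 1/f background (60 µV rms; 70 in wake) and a 50 µV broadband noise
floor; REM adds 7 Hz theta (60 µV); EMG is band-limited noise with
per-stage rms 60/12/6 µV and a ±40 % slow tone drift (0.015 Hz) that gives
staging statistics realistic persistence. These amplitudes put NREM
relative delta power near 0.5 of the 0.5–30 Hz total, in the physiological
range for rat NREM, and absolute scales are arbitrary (the source gives no
amplitude units for rat EEG); all analyses are gain-invariant by
construction. Ground-truth slow-oscillation phase is exported per sample
(0° rising zero-crossing; ramp restarts at each NREM segment).

`delta_gain` scales the whole NREM delta-band amplitude (slow oscillation
plus the background's delta portion), defining the injection used in
parameter-recovery checks: +10 % amplitude is read out as ≈ +8 % relative
delta power, the attenuation coming from the normalization denominator.
Artifacts are injected at two scales: epoch-level flags (rate 0.002) and
brief high-amplitude transients inside NREM (< 10 samples at 300 Hz after
resampling) that exercise the 8×IQR repair rule.

What the generator does *not* emulate — sawtooth slow-wave asymmetry,
ultradian/circadian structure, state transitions inside epochs, real
artifact morphology, inter-animal variability — bounds what passing tests
show: they validate the algorithms' correctness and calibration logic, not
the physiological effect sizes of stimulation, which are properties of real
recordings.

## Problem sizes and numerics

Tests run on minutes-to-an-hour of synthetic signal (the parameter-recovery
check uses a 1 h block), chosen as the smallest sizes at which the
stochastic properties under test are stable. Degenerate inputs are flagged
rather than guessed: NREMratio is NaN where beta rms is 0, confusion ratios
are NaN on zero denominators, circular mean is NaN at R = 0, fragmentation
is NaN without NREM, change-from-baseline is NaN on zero baselines. EDF
writing quantizes to 16 bits over each channel's physical range and
zero-pads the final data record; readers trim via the stored sample count.
Large FIR designs are cached per (order, edges, rate).
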