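# ratclas

Phase-targeted closed-loop auditory stimulation (CLAS) of sleep slow waves
in rats, as an offline/streaming simulator with the full analysis stack
around it. The package is for sleep and systems neuroscientists who want to
prototype, validate or re-analyze rodent CLAS experiments: it implements the
online method (real-time NREM staging and slow-wave phase detection driving
trigger emission), the baseline calibration that parameterizes it, and the
offline pipelines that quantify what it did (staging validation, EEG
spectra, trigger trains/ISI, evoked potentials, circular phase statistics,
reaching-task metrics). A synthetic polysomnography generator with
ground-truth hypnogram and slow-oscillation phase makes every stage testable
without any recordings.

## The method

During a scored 24 h baseline, two gates are calibrated from EEG/EMG
statistics computed on 1 s windows:

* **NREMratio** = rms(EEG 0.5–4 Hz) / rms(EEG 20–30 Hz); threshold =
  mean + 1 SD over NREM epochs (the 84.1th percentile under normality);
* **EMG rms**; threshold = mean − 1 SD over NREM epochs (15.9th percentile).

During stimulation the engine runs three features in parallel over the
stream: the gate (NREMratio above threshold ∧ EMG below threshold, trailing
1 s windows), and a phase detector on a very-narrow band-pass around the
~1 Hz slow-oscillation component. At every rising zero-crossing the detector
resets to 0° and maps elapsed samples to phase at the nominal component
frequency f₀:

φ(k) = 360° · f₀ · (k − k_zc) / fs, clamped to [0°, 360°),

with 0° the rising zero-crossing, 90° the positive peak, 270° the trough.
A pink-noise click (30 ms, 2 ms ramps) is triggered at most once per cycle,
at the first gated sample where the ramp reaches the target phase (60°
up-phase, 180° down-phase, or a muted mock run). Because rat slow waves
peak near 1.35 Hz while the ramp assumes 1 Hz, achieved phase
systematically overshoots the target — a property of the method that the
offline circular statistics quantify.

## Worked example

`python examples/closed_loop_stimulation.py` simulates 30 min of rat
polysomnography, calibrates, and runs up-phase CLAS at 60°:

```
50 triggers in 30 min (up-phase, target 60 deg, latency 29.3 ms)
trigger proportions by stage: {'W': 0.0, 'N': 0.94, 'R': 0.06, 'artifact': 0.0, 'unlabeled': 0.0}
(time in NREM was only 29% - the gate strongly enriches NREM)
achieved phase: mean 144.6 deg, R 0.33, circular SD 85.3 deg
```

94 % of triggers fell in true NREM although only 29 % of time was NREM —
the strict thresholds trade sensitivity for specificity by design. The
achieved-phase mean overshoots the 60° target because real (here:
synthetic) slow waves run faster than the 1 Hz ramp and hardware latency
adds lag; on clean 1 Hz input the loop hits the target within a degree
(`examples/trigger_trains_and_erp.py` shows mean 60.7°, circular SD 8.8°).

`python examples/spectral_analysis.py` runs the offline spectral pipeline
and recovers an injected +10 % NREM delta-amplitude increase as a +8.6 %
rise in relative delta power — less than the +21 % power change because the
0.5–30 Hz normalization denominator rises too.

Other examples: `simulate_and_calibrate.py` (threshold derivation),
`staging_validation.py` (sensitivity/specificity/precision of the online
stager), `reaching_task_power.py` (reaching-task metrics and the ANOVA
power calculation).

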