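"""Run phase-targeted closed-loop stimulation over a synthetic recording.

Calibrates on the same day (for brevity), runs the up-phase paradigm at the
60 degree target, and reports where the triggers landed: sleep-stage
breakdown and the achieved slow-wave phase from the offline Hilbert analysis.
"""

import ratclas as rc

cfg = rc.SynthConfig()
hyp = rc.generate_hypnogram(cfg, duration_s=1800, seed=5)
rec, _ = rc.synthesize_recording(hyp, cfg, seed=5)
thr = rc.calibrate_thresholds(rc.compute_staging_series(rec), hyp)

engine = rc.EngineConfig(target_phase_deg=60.0, condition="up",
                         latency_s=rc.HARDWARE_LATENCY_S)
result = rc.run_closed_loop(rec, thr, engine)
log = result.trigger_log
print(f"{len(log)} triggers in {rec.duration/60:.0f} min (up-phase, target 60 deg, "
      f"latency {engine.latency_s*1e3:.1f} ms)")

breakdown = rc.trigger_stage_breakdown(log, hyp)
frac_n = (hyp.states() == "N").mean()
print(f"trigger proportions by stage: { {k: round(v, 3) for k, v in breakdown['proportions'].items()} }")
print(f"(time in NREM was only {frac_n:.0%} - the gate strongly enriches NREM)")

x300 = rc.preprocess_eeg(rec.eeg(), rec.fs)
phases = rc.phase_at_triggers(x300, log)
st = phases["stats"]
print(f"achieved phase: mean {st.mean_deg:.1f} deg, R {st.R:.2f}, "
      f"circular SD {st.circ_sd_deg:.1f} deg")
print("The mean overshoots the 60 deg target and is dispersed: the ramp assumes")
print("a 1 Hz component while the synthetic slow waves run at 1.35 Hz over a")
print("noisy background, and 29.3 ms of latency adds further phase lag - all")
print("properties of the online method that this offline analysis quantifies.")
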