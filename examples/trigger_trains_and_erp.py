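"""Trigger-train, ISI and evoked-response analyses of a closed-loop run.

Runs the loop on clean synthetic NREM, then summarizes the trigger stream
(trains of triggers <= 1 s apart, interstimulus intervals) and the evoked
slow-wave response (0.5-2 Hz ERP and circular phase statistics).
"""

import numpy as np

import ratclas as rc

cfg = rc.SynthConfig(so_freq=1.0, background_amp={"W": 0, "N": 15, "R": 0},
                     white_amp=10, spindle_amp=0, spindle_rate=0,
                     artifact_epoch_rate=0, transient_rate=0)
hyp = rc.Hypnogram(["N"] * 60)  # 4 min of NREM
rec, _ = rc.synthesize_recording(hyp, cfg, seed=3)
open_gate = rc.CalibrationThresholds(-np.inf, np.inf, {})
result = rc.run_closed_loop(rec, open_gate, rc.EngineConfig(target_phase_deg=60.0))
log = result.trigger_log
print(f"{len(log)} triggers on {hyp.duration/60:.0f} min of NREM")

trains = rc.train_histogram(log.onsets)
print(f"train sizes (gap <= {trains.gap_s} s): "
      f"{ {k: v for k, v in trains.counts.items()} } (5 = five or more)")
density, edges = rc.isi_histogram(log.onsets)
print(f"ISI density over {edges[0]}-{edges[-1]} s bins: {np.round(density, 3)}")

x300 = rc.preprocess_eeg(rec.eeg(), rec.fs)
erps = rc.extract_erps(x300, log, hyp)
print(f"{len(erps['snippets'])} ERP snippets of {erps['snippets'].shape[1]} samples "
      f"({erps['t'][0]:.1f} to {erps['t'][-1]:.1f} s around onset)")
peak = erps["average"].max()
print(f"mean evoked slow-wave amplitude peak: {peak:.1f} uV")

phases = rc.phase_at_triggers(x300, log)
st = phases["stats"]
print(f"phase at onset: mean {st.mean_deg:.1f} deg, circular SD {st.circ_sd_deg:.1f} deg")
print(f"60-deg-bin histogram (per-subject normalized): {np.round(phases['hist'], 2)}")
print("Consecutive triggers sit about one slow-wave cycle apart, so most trains")
print("are short runs; the phase histogram concentrates around the target.")
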