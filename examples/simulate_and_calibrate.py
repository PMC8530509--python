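"""Simulate a baseline recording and derive the online staging thresholds.

Generates 20 min of synthetic rat polysomnography, computes the per-second
NREMratio (delta rms / high-beta rms) and EMG rms, and calibrates the two
gates: NREMratio mean + 1 SD and EMG mean - 1 SD over scored NREM.
"""

import ratclas as rc

cfg = rc.SynthConfig()
hyp = rc.generate_hypnogram(cfg, duration_s=1200, seed=7)
rec, _ = rc.synthesize_recording(hyp, cfg, seed=7)
print(f"simulated {rec.duration:.0f} s at {rec.fs} Hz; "
      f"{sum(s == 'N' for s in hyp.states())} of {len(hyp)} epochs are NREM")

series = rc.compute_staging_series(rec)
thr = rc.calibrate_thresholds(series, hyp)
print(f"NREMratio threshold: {thr.nrem_ratio_thr:.3f} "
      f"(mean {thr.provenance['nrem_ratio']['mean']:.3f} + "
      f"SD {thr.provenance['nrem_ratio']['sd']:.3f}; the ~84.1th percentile)")
print(f"EMG threshold: {thr.emg_thr:.2f} uV "
      f"(mean - SD of NREM EMG rms; the ~15.9th percentile)")
print("A 1 s window opens the stimulation gate only when the NREMratio exceeds")
print("the first threshold while EMG rms stays below the second - sustained NREM.")
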