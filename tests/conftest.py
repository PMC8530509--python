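import numpy as np
import pytest

import ratclas as rc


@pytest.fixture(scope="session")
def default_synth():
    """20 min of default-parameter synthetic polysomnography (seed 11)."""
    cfg = rc.SynthConfig()
    hyp = rc.generate_hypnogram(cfg, 1200, seed=11)
    rec, phase = rc.synthesize_recording(hyp, cfg, seed=11)
    return cfg, hyp, rec, phase


@pytest.fixture(scope="session")
def clean_nrem():
    """3 min of noise-free 1 Hz slow oscillation scored all-NREM."""
    cfg = rc.SynthConfig(
        so_freq=1.0, so_mod_depth=0.0, spindle_amp=0.0, spindle_rate=0.0,
        background_amp={"W": 0.0, "N": 0.0, "R": 0.0}, white_amp=0.0,
        theta_amp=0.0, artifact_epoch_rate=0.0, transient_rate=0.0,
    )
    hyp = rc.Hypnogram(["N"] * 45)
    rec, phase = rc.synthesize_recording(hyp, cfg, seed=2)
    return cfg, hyp, rec, phase


@pytest.fixture
def open_gate():
    """Thresholds that the gate always passes (for phase-detector tests)."""
    return rc.CalibrationThresholds(
        nrem_ratio_thr=-np.inf, emg_thr=np.inf, provenance={}
    )
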