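"""Streaming closed-loop engine: NREM gate, slow-wave phase detector, triggers.

The method runs three real-time features in parallel over the EEG/EMG
stream and fires an auditory trigger whenever their conjunction — the
stimulatory truth function — is satisfied:

* **NREM gate** — trailing 1 s rms of the delta (0.5–4 Hz) and high-beta
  (20–30 Hz) EEG bands; gate true iff their ratio (NREMratio) exceeds the
  baseline-calibrated threshold while the EMG rms stays below its threshold.
* **Phase detector** — a very narrow band-pass isolates the ~1 Hz
  slow-oscillation component; at every rising (negative-to-positive)
  zero-crossing of that component the detector resets to 0° and maps elapsed
  samples to phase at the *nominal* component frequency:
  phase(k) = 360·f0·(k − k_zc)/fs, clamped to [0, 360).  Because the rat
  slow-oscillation peak sits near 1.35 Hz while f0 defaults to 1 Hz, real
  cycles run ahead of the ramp — a systematic overshoot of achieved phase
  that is a property of the method and is reproduced, not corrected.
* **Trigger logic** — one trigger at most per detected cycle, at the first
  sample where the gate holds and the ramp has reached the target phase;
  logged onset = crossing time + hardware latency.  In the mock condition
  the identical loop runs with the speaker muted.

Phase convention throughout: 0° = rising zero-crossing, 90° = positive
peak, 270° = trough.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .calibration import CalibrationThresholds, staging_filter_bank
from .containers import Recording, TriggerLog

#: Mean detection-to-trigger delay of the reference hardware chain (s).
HARDWARE_LATENCY_S = 0.0293


@dataclass
class StimulusConfig:
    """Auditory click: pink-noise burst with linear on/off ramps."""

    duration_s: float = 0.030
    ramp_s: float = 0.002
    level_db: float = 35.0

    def __post_init__(self) -> None:
        if self.duration_s <= 2 * self.ramp_s:
            raise ValueError("stimulus duration must exceed twice the ramp time")


@dataclass
class EngineConfig:
    """Parameters of one closed-loop run."""

    target_phase_deg: float = 60.0
    condition: str = "up"
    so_component_freq: float = 1.0     # nominal tracked component (Hz)
    narrow_bw: float = 0.6             # band-pass bandwidth around it (Hz)
    latency_s: float = 0.0
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    eeg_channel: str = "EEG1"

    def __post_init__(self) -> None:
        if not 0 <= self.target_phase_deg < 360:
            raise ValueError("target phase must lie in [0, 360)")
        if self.latency_s < 0:
            raise ValueError("latency must be non-negative")


def narrowband_sos(fs: float, f0: float = 1.0, bw: float = 0.6) -> np.ndarray:
    """Second-order resonator (peak filter) isolating the slow-wave component."""
    b, a = signal.iirpeak(f0, Q=f0 / bw, fs=fs)
    return signal.tf2sos(b, a)


class StreamingFilters:
    """Causal filter bank with state carried between chunks.

    Processing a signal chunk-by-chunk through :meth:`process` yields
    sample-for-sample the same output as a single pass, whatever the
    chunking — the property a real-time implementation needs.
    """

    def __init__(self, fs: float, f0: float = 1.0, bw: float = 0.6):
        if fs < 2 * 36.0:
            raise ValueError("sampling rate too low for the 0.1-36 Hz EEG band")
        self.fs = fs
        bank = staging_filter_bank(fs)
        self._sos = {
            "eeg_broad": signal.butter(1, [0.1, 36.0], btype="bandpass", fs=fs, output="sos"),
            "delta": bank["delta"],
            "beta": bank["beta"],
            "narrow": narrowband_sos(fs, f0, bw),
            "emg_band": bank["emg"],
            "emg_notch": bank["emg_notch"],
        }
        self._zi = {k: np.zeros((s.shape[0], 2)) for k, s in self._sos.items()}

    def _run(self, key: str, x: np.ndarray) -> np.ndarray:
        y, self._zi[key] = signal.sosfilt(self._sos[key], x, zi=self._zi[key])
        return y

    def process(self, eeg: np.ndarray, emg: np.ndarray) -> dict[str, np.ndarray]:
        """Filter one chunk; returns the five filtered streams."""
        emg_b = self._run("emg_band", emg)
        return {
            "eeg_broad": self._run("eeg_broad", eeg),
            "delta": self._run("delta", eeg),
            "beta": self._run("beta", eeg),
            "narrow": self._run("narrow", eeg),
            "emg": self._run("emg_notch", emg_b),
        }


def trailing_rms(x: np.ndarray, fs: float, window_s: float = 1.0) -> np.ndarray:
    """Causal rms over the trailing ``window_s`` seconds, per sample.

    The first ``window_s`` of output uses the partial window available.
    """
    w = max(1, int(round(window_s * fs)))
    c = np.cumsum(np.concatenate([[0.0], x.astype(float) ** 2]))
    k = np.arange(len(x))
    lo = np.maximum(k - w + 1, 0)
    return np.sqrt((c[k + 1] - c[lo]) / (k - lo + 1))


def detect_phase(narrowband: np.ndarray, fs: float, f0: float = 1.0) -> np.ndarray:
    """Per-sample phase from the zero-crossing + sample-count rule.

    phase(k) = 360·f0·(k − k_zc)/fs clamped below 360°, where k_zc is the
    most recent negative-to-positive zero-crossing; NaN before the first
    crossing.
    """
    x = np.asarray(narrowband, dtype=float)
    n = len(x)
    pos = x >= 0
    crossings = np.flatnonzero(~pos[:-1] & pos[1:]) + 1
    last = np.full(n, -1, dtype=np.int64)
    last[crossings] = crossings
    np.maximum.accumulate(last, out=last)
    phase = np.full(n, np.nan)
    ok = last >= 0
    phase[ok] = 360.0 * f0 * (np.arange(n)[ok] - last[ok]) / fs
    np.clip(phase, None, np.nextafter(360.0, 0.0), out=phase)
    return phase


def nrem_gate(
    nrem_ratio: np.ndarray, emg_rms: np.ndarray, thresholds: CalibrationThresholds
) -> np.ndarray:
    """Elementwise gate: NREMratio above threshold AND EMG rms below threshold."""
    ratio = np.asarray(nrem_ratio, dtype=float)
    with np.errstate(invalid="ignore"):
        return (ratio > thresholds.nrem_ratio_thr) & (
            np.asarray(emg_rms, dtype=float) < thresholds.emg_thr
        )


@dataclass
class ClosedLoopResult:
    """Everything a run exports for offline analysis."""

    trigger_log: TriggerLog
    decisions_1s: np.ndarray    # gate state sampled at the end of each second
    gate: np.ndarray            # per-sample gate
    phase: np.ndarray           # per-sample phase-detector output (deg)
    narrowband: np.ndarray


def run_closed_loop(
    recording: Recording,
    thresholds: CalibrationThresholds,
    config: EngineConfig,
) -> ClosedLoopResult:
    """Simulate the closed loop sample-by-sample over a recording.

    Deterministic: identical inputs give an identical trigger log.  The
    mock condition runs the same loop and logs muted triggers.
    """
    fs = recording.fs
    filt = StreamingFilters(fs, config.so_component_freq, config.narrow_bw)
    streams = filt.process(recording.channel(config.eeg_channel), recording.emg())

    rms_d = trailing_rms(streams["delta"], fs)
    rms_b = trailing_rms(streams["beta"], fs)
    rms_e = trailing_rms(streams["emg"], fs)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rms_b > 0, rms_d / rms_b, np.nan)
    gate = nrem_gate(ratio, rms_e, thresholds)

    nb = streams["narrow"]
    phase = detect_phase(nb, fs, config.so_component_freq)
    pos = nb >= 0
    crossings = np.flatnonzero(~pos[:-1] & pos[1:]) + 1

    target = config.target_phase_deg
    samples_to_target = int(np.ceil(target / (360.0 * config.so_component_freq) * fs))
    onsets = []
    bounds = np.concatenate([crossings, [len(nb)]])
    for c0, c1 in zip(bounds[:-1], bounds[1:]):
        k0 = c0 + samples_to_target
        if k0 >= c1:
            continue  # cycle ended before the ramp reached the target
        window = gate[k0:c1]
        hit = np.argmax(window)
        if window[hit]:
            onsets.append((k0 + hit) / fs + config.latency_s)

    n_seconds = int(recording.duration)
    dec_idx = np.minimum((np.arange(1, n_seconds + 1) * fs).astype(int) - 1, len(gate) - 1)
    decisions = gate[dec_idx]

    log = TriggerLog(
        onsets=np.asarray(onsets),
        target_phase_deg=target,
        condition=config.condition,
        muted=(config.condition == "mock"),
    )
    return ClosedLoopResult(
        trigger_log=log, decisions_1s=decisions, gate=gate, phase=phase, narrowband=nb
    )


def _pink(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise, unit peak, for the stimulus click."""
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = shape * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n)
    return x / np.abs(x).max()


def make_stimulus_waveform(
    stimulus: StimulusConfig, audio_fs: float, seed: int = 0
) -> np.ndarray:
    """Pink-noise click with linear rising/falling ramps, peak-normalized.

    The SPL level is metadata (free-field calibration happens at the
    speaker); the returned waveform has unit peak.
    """
    if audio_fs < 8000:
        raise ValueError("audio sampling rate must be at least 8 kHz")
    n = int(round(stimulus.duration_s * audio_fs))
    nr = int(round(stimulus.ramp_s * audio_fs))
    x = _pink(n, np.random.default_rng(seed))
    ramp = np.linspace(0.0, 1.0, nr, endpoint=False)
    env = np.ones(n)
    env[:nr] = ramp
    env[-nr:] = ramp[::-1]
    y = x * env
    return y / np.abs(y).max()


def scale_stimulus_duration(
    reference_duration_s: float = 0.050,
    reference_freq_hz: float = 0.8,
    target_freq_hz: float = 1.35,
    round_to_s: float = 0.010,
) -> float:
    """Scale a stimulus duration to a faster slow-oscillation rhythm.

    The human protocol uses 50 ms clicks for a 0.8 Hz dominant component;
    keeping the same fraction of the ongoing cycle at the rat's 1.35 Hz
    peak gives 50·0.8/1.35 ≈ 29.6 ms → 30 ms at 10 ms granularity.
    """
    scaled = reference_duration_s * reference_freq_hz / target_freq_hz
    return round(scaled / round_to_s) * round_to_s
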