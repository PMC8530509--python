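"""Synthetic rat polysomnography with ground-truth hypnogram and slow-wave phase.

The generator emulates the stage-dependent spectral structure the online
stager and phase detector rely on: NREM epochs carry an amplitude-modulated
slow oscillation near 1.35 Hz (the rat slow-oscillation peak) plus
intermittent sigma-band spindle bursts over a 1/f background, REM is
theta-dominated, wake is broadband with high EMG tone.  The true
slow-oscillation phase (0° at the rising zero-crossing, 90° at the positive
peak) is exported per sample so phase-targeting accuracy can be measured
against ground truth rather than against another estimator.

Stage alternation is a semi-Markov chain with exponential dwell times on the
transition graph W->N, N->{W, R}, R->W; W->R transitions are excluded as
physiologically rare in rats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import Hypnogram, Recording


@dataclass
class SynthConfig:
    """Parameters of the synthetic polysomnography generator.

    Amplitudes are in µV (rat EEG screw-electrode scale); dwell times in
    seconds.  Defaults put NREM delta relative power near 0.5 of the
    0.5–30 Hz total, in the physiological range for rat NREM sleep.
    """

    fs: float = 610.35
    epoch_len: float = 4.0
    # semi-Markov stage dynamics
    dwell_s: dict = field(default_factory=lambda: {"W": 200.0, "N": 250.0, "R": 80.0})
    p_n_to_r: float = 0.2
    # slow oscillation (NREM)
    so_freq: float = 1.35
    so_amp: float = 45.0
    so_mod_freq: float = 0.05
    so_mod_depth: float = 0.25
    delta_gain: float = 1.0         # multiplies all NREM delta-band amplitude
    # spindles (NREM)
    spindle_band: tuple = (11.0, 16.0)
    spindle_rate: float = 0.4       # bursts per second of NREM
    spindle_amp: float = 90.0
    spindle_dur: float = 0.7
    # REM theta
    theta_freq: float = 7.0
    theta_amp: float = 60.0
    # backgrounds
    background_amp: dict = field(
        default_factory=lambda: {"W": 70.0, "N": 60.0, "R": 60.0}
    )  # 1/f rms per stage
    white_amp: float = 50.0         # broadband instrument-noise floor, all stages
    # EMG rms per stage, with a slow multiplicative tone drift
    emg_level: dict = field(default_factory=lambda: {"W": 60.0, "N": 12.0, "R": 6.0})
    emg_mod_depth: float = 0.4
    emg_mod_freq: float = 0.015
    # artifacts
    artifact_epoch_rate: float = 0.002   # fraction of epochs flagged a*
    transient_rate: float = 0.001        # brief >8x-IQR spikes per second of NREM
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.so_freq < 4:
            raise ValueError("so_freq must lie in (0.5, 4) Hz")
        if any(v <= 0 for v in self.dwell_s.values()):
            raise ValueError("dwell times must be positive")
        for v in (self.so_amp, self.spindle_amp, self.theta_amp):
            if v < 0:
                raise ValueError("amplitudes must be non-negative")


_TRANSITIONS = {"W": ("N",), "N": ("W", "R"), "R": ("W",)}


def stationary_fractions(config: SynthConfig) -> dict[str, float]:
    """Analytic stationary time fractions of the semi-Markov stage chain.

    Visit rates follow the embedded chain (W->N always, N->R with
    probability ``p_n_to_r``, R->W always); time fractions weight visit
    rates by mean dwell.
    """
    p = config.p_n_to_r
    visits = {"W": 1.0, "N": 1.0, "R": p}  # per W->N cycle
    w = {s: visits[s] * config.dwell_s[s] for s in visits}
    tot = sum(w.values())
    return {s: w[s] / tot for s in w}


def generate_hypnogram(
    config: SynthConfig, duration_s: float, seed: int | None = None
) -> Hypnogram:
    """Draw a semi-Markov stage sequence and quantize it to scoring epochs.

    Each epoch is labeled by the stage occupying its midpoint; a small
    random fraction of epochs (``artifact_epoch_rate``) is artifact-flagged.
    """
    if duration_s < config.epoch_len:
        raise ValueError("duration must cover at least one epoch")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    # alternate stages until the requested duration is covered
    times, stages = [0.0], []
    state = "W"
    t = 0.0
    while t < duration_s:
        stages.append(state)
        t += rng.exponential(config.dwell_s[state])
        times.append(t)
        nxt = _TRANSITIONS[state]
        if state == "N":
            state = "R" if rng.random() < config.p_n_to_r else "W"
        else:
            state = nxt[0]
    bounds = np.asarray(times)
    n_epochs = int(duration_s // config.epoch_len)
    mids = (np.arange(n_epochs) + 0.5) * config.epoch_len
    idx = np.searchsorted(bounds, mids, side="right") - 1
    labels = [stages[i] for i in idx]
    flags = rng.random(n_epochs) < config.artifact_epoch_rate
    labels = [("a" + lab) if fl else lab for lab, fl in zip(labels, flags)]
    return Hypnogram(labels=labels, epoch_len=config.epoch_len)


def _pink_noise(n: int, rng: np.random.Generator, fs: float) -> np.ndarray:
    """Unit-rms 1/f-amplitude noise, flat below 0.5 Hz to keep variance finite."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0.5
    shape[nz] = np.sqrt(0.5 / freqs[nz])
    spec = shape * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _stage_sample_mask(hyp: Hypnogram, n: int, fs: float) -> np.ndarray:
    """Per-sample base-stage array ('W'/'N'/'R') from a hypnogram."""
    states = hyp.states()
    idx = np.minimum((np.arange(n) / fs // hyp.epoch_len).astype(int), len(states) - 1)
    return states[idx]


def synthesize_recording(
    hypnogram: Hypnogram, config: SynthConfig, seed: int | None = None
) -> tuple[Recording, np.ndarray]:
    """Render EEG/EMG traces for a hypnogram.

    Returns
    -------
    recording : Recording
        Channels EEG1 (left, the closed-loop input), EEG2 (right) and EMG.
    phase_deg : ndarray
        Ground-truth slow-oscillation phase per sample, degrees in
        [0, 360); NaN outside NREM.  The phase ramp restarts at 0° at the
        start of each NREM segment and advances 360·so_freq degrees per
        second within it.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.fs
    n = int(round(hypnogram.duration * fs))
    t = np.arange(n) / fs
    stage = _stage_sample_mask(hypnogram, n, fs)
    is_n, is_r, is_w = stage == "N", stage == "R", stage == "W"

    # ground-truth slow-oscillation phase: ramp within each NREM segment
    phase = np.full(n, np.nan)
    seg_starts = np.flatnonzero(np.diff(np.r_[0, is_n.astype(int)]) == 1)
    seg_ends = np.flatnonzero(np.diff(np.r_[is_n.astype(int), 0]) == -1) + 1
    so = np.zeros(n)
    for s, e in zip(seg_starts, seg_ends):
        local = np.arange(e - s) / fs
        ph = (360.0 * config.so_freq * local) % 360.0
        phase[s:e] = ph
        env = 1.0 - config.so_mod_depth * (
            0.5 - 0.5 * np.cos(2 * np.pi * config.so_mod_freq * local)
        )
        so[s:e] = config.delta_gain * config.so_amp * env * np.sin(np.deg2rad(ph))

    # spindle bursts within NREM
    spindles = np.zeros(n)
    n_seconds = is_n.sum() / fs
    n_bursts = rng.poisson(config.spindle_rate * n_seconds)
    n_idx = np.flatnonzero(is_n)
    if n_bursts and len(n_idx):
        centers = rng.choice(n_idx, size=n_bursts)
        half = int(config.spindle_dur * fs / 2)
        f_sp = rng.uniform(*config.spindle_band, size=n_bursts)
        for c, f in zip(centers, f_sp):
            s, e = max(0, c - half), min(n, c + half)
            k = np.arange(s, e)
            env = np.hanning(2 * half)[: e - s]
            spindles[s:e] += config.spindle_amp * env * np.sin(2 * np.pi * f * k / fs)

    theta = np.zeros(n)
    theta[is_r] = config.theta_amp * np.sin(
        2 * np.pi * config.theta_freq * t[is_r] + rng.uniform(0, 2 * np.pi)
    )

    bg_amp = np.where(is_w, config.background_amp["W"],
                      np.where(is_r, config.background_amp["R"], config.background_amp["N"]))

    def background() -> np.ndarray:
        bg = bg_amp * _pink_noise(n, rng, fs)
        if config.delta_gain != 1.0 and is_n.any():
            # scale the background's delta content inside NREM too, so
            # delta_gain multiplies the whole NREM delta-band amplitude
            sos = signal.butter(4, [0.5, 4.0], btype="bandpass", fs=fs, output="sos")
            bg_delta = signal.sosfiltfilt(sos, bg)
            bg = bg + (config.delta_gain - 1.0) * bg_delta * is_n
        return bg + config.white_amp * rng.standard_normal(n)

    eeg1 = so + spindles + theta + background()
    eeg2 = 0.8 * so + spindles * 0.9 + theta + background()

    # brief high-amplitude transients in NREM (exercise the 8x-IQR repair)
    n_spk = rng.poisson(config.transient_rate * n_seconds)
    if n_spk and len(n_idx):
        width = max(2, int(0.015 * fs))  # <10 samples once resampled to 300 Hz
        for c in rng.choice(n_idx, size=n_spk):
            e = min(n, c + width)
            eeg1[c:e] += rng.choice([-1, 1]) * 30 * config.so_amp

    emg_rms = np.where(is_w, config.emg_level["W"],
                       np.where(is_r, config.emg_level["R"], config.emg_level["N"]))
    drift = 1.0 + config.emg_mod_depth * np.sin(
        2 * np.pi * config.emg_mod_freq * t + rng.uniform(0, 2 * np.pi)
    )
    emg = emg_rms * drift * rng.standard_normal(n)
    # band-limit EMG to look muscular rather than white
    sos = signal.butter(2, [20, min(250.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    emg = signal.sosfilt(sos, emg)
    emg *= emg_rms.mean() / max(emg.std(), 1e-12)

    rec = Recording(channels={"EEG1": eeg1, "EEG2": eeg2, "EMG": emg}, fs=fs)
    return rec, phase
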