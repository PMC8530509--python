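"""Baseline calibration of the two online NREM-staging thresholds.

The online stager gates stimulation on two statistics computed on 1 s
windows: the NREMratio (rms of the delta band 0.5–4 Hz divided by rms of
the high-beta band 20–30 Hz of EEG) and the EMG rms.  From an offline-scored
baseline day, the NREMratio threshold is set at +1 SD over the mean of the
NREMratio of all NREM epochs (the 84.1th percentile under normality) and the
EMG threshold at −1 SD below the mean NREM EMG rms (the 15.9th percentile).
Both thresholds deliberately select *sustained* slow-wave sleep: they trade
sensitivity for specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, special

from .containers import Hypnogram, Recording


def staging_filter_bank(fs: float) -> dict[str, np.ndarray]:
    """Causal biquad band-pass filters of the online staging chain (SOS form).

    EEG delta 0.5–4 Hz and high-beta 20–30 Hz; EMG 5 Hz up to
    min(525, 0.45·fs) Hz plus a 50 Hz notch.  The EMG upper edge follows the
    acquisition chain's anti-aliasing limit of 45 % of the sampling rate.
    """
    emg_hi = min(525.0, 0.45 * fs)
    bank = {
        "delta": signal.butter(2, [0.5, 4.0], btype="bandpass", fs=fs, output="sos"),
        "beta": signal.butter(2, [20.0, 30.0], btype="bandpass", fs=fs, output="sos"),
        "emg": signal.butter(1, [5.0, emg_hi], btype="bandpass", fs=fs, output="sos"),
    }
    b, a = signal.iirnotch(50.0, Q=25.0, fs=fs)
    bank["emg_notch"] = signal.tf2sos(b, a)
    return bank


@dataclass
class StagingSeries:
    """Per-1 s staging statistics on a stepped grid.

    ``t`` holds window midpoints (0.5, 1.5, ...).  ``nrem_ratio`` is NaN
    where the beta rms vanishes.
    """

    t: np.ndarray
    rms_delta: np.ndarray
    rms_beta: np.ndarray
    emg_rms: np.ndarray

    @property
    def nrem_ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(self.rms_beta > 0, self.rms_delta / self.rms_beta, np.nan)
        return ratio


@dataclass
class CalibrationThresholds:
    """The two baseline-derived gates, with their provenance statistics."""

    nrem_ratio_thr: float
    emg_thr: float
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "nrem_ratio_thr": self.nrem_ratio_thr,
            "emg_thr": self.emg_thr,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationThresholds":
        return cls(d["nrem_ratio_thr"], d["emg_thr"], d.get("provenance", {}))


def _stepped_rms(x: np.ndarray, fs: float) -> np.ndarray:
    """rms over consecutive 1 s windows [j/fs, (j+1)/fs)."""
    n_win = int(len(x) / fs)
    edges = np.floor(np.arange(n_win + 1) * fs).astype(int)
    return np.array(
        [np.sqrt(np.mean(x[edges[j] : edges[j + 1]] ** 2)) for j in range(n_win)]
    )


def compute_staging_series(recording: Recording, eeg_channel: str = "EEG1") -> StagingSeries:
    """Band rms of EEG delta/high-beta and EMG on stepped 1 s windows.

    The same causal filters as the online chain are used so that the
    calibration statistics match what the running gate will see.
    """
    fs = recording.fs
    if recording.duration < 1.0:
        raise ValueError("recording shorter than the 1 s staging window")
    bank = staging_filter_bank(fs)
    eeg = recording.channel(eeg_channel)
    emg = recording.emg()
    delta = signal.sosfilt(bank["delta"], eeg)
    beta = signal.sosfilt(bank["beta"], eeg)
    emg_f = signal.sosfilt(bank["emg_notch"], signal.sosfilt(bank["emg"], emg))
    rms_d = _stepped_rms(delta, fs)
    rms_b = _stepped_rms(beta, fs)
    rms_e = _stepped_rms(emg_f, fs)
    t = np.arange(len(rms_d)) + 0.5
    return StagingSeries(t=t, rms_delta=rms_d, rms_beta=rms_b, emg_rms=rms_e)


def calibrate_thresholds(series: StagingSeries, hypnogram: Hypnogram) -> CalibrationThresholds:
    """Derive the NREMratio and EMG gates from scored-baseline NREM epochs.

    A 1 s value belongs to the scoring epoch containing its window
    midpoint.  Only plain (non-artifact) NREM epochs enter; the SD uses the
    n−1 denominator.
    """
    epoch_idx = (series.t // hypnogram.epoch_len).astype(int)
    valid = epoch_idx < len(hypnogram)
    labels = np.asarray(hypnogram.labels)
    in_n = np.zeros(len(series.t), dtype=bool)
    in_n[valid] = labels[epoch_idx[valid]] == "N"

    n_epochs_used = len(np.unique(epoch_idx[in_n]))
    if n_epochs_used < 2:
        raise ValueError(
            f"calibration needs >= 2 non-artifact NREM epochs, found {n_epochs_used}"
        )

    ratio = series.nrem_ratio[in_n]
    ratio = ratio[np.isfinite(ratio)]
    emg = series.emg_rms[in_n]

    r_mean, r_sd = float(np.mean(ratio)), float(np.std(ratio, ddof=1))
    e_mean, e_sd = float(np.mean(emg)), float(np.std(emg, ddof=1))
    return CalibrationThresholds(
        nrem_ratio_thr=r_mean + r_sd,
        emg_thr=max(0.0, e_mean - e_sd),
        provenance={
            "nrem_ratio": {"mean": r_mean, "sd": r_sd, "n": int(ratio.size)},
            "emg_rms": {"mean": e_mean, "sd": e_sd, "n": int(emg.size)},
            "n_nrem_epochs": n_epochs_used,
        },
    )


def zscore_percentile(z: float) -> float:
    """Percentile (in %) of a z-score under the standard normal: 100·Φ(z).

    Φ(+1) ≈ 84.1 % and Φ(−1) ≈ 15.9 %, the percentiles the ±1 SD
    calibration thresholds represent for normally distributed statistics.
    """
    return 100.0 * float(special.ndtr(z))
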