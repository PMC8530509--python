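"""Core data containers: recordings, hypnograms and trigger logs.

Times are seconds from recording start; sample indexing is 0-based;
scoring epochs are half-open intervals [k*epoch_len, (k+1)*epoch_len).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Vigilance-state alphabet: wake, NREM, REM, plus artifact-flagged variants.
STATE_ALPHABET = ("W", "N", "R", "aW", "aN", "aR")

#: Stimulation conditions. "mock" runs the full loop with the speaker muted.
CONDITIONS = ("up", "down", "mock")


class ChannelError(ValueError):
    """A required EEG or EMG channel is missing from a recording."""


@dataclass
class Recording:
    """Multichannel EEG/EMG recording.

    Parameters
    ----------
    channels : dict of str -> ndarray
        Signal traces in microvolts, all of equal length.
    fs : float
        Sampling rate in Hz.
    start_time : float
        Clock time of the first sample (seconds; informational only).
    """

    channels: dict[str, np.ndarray]
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channels:
            raise ValueError("recording must contain at least one channel")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"channels differ in length: {lengths}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, pattern: str) -> np.ndarray:
        """Return the first channel whose name contains ``pattern`` (case-insensitive)."""
        for name, trace in self.channels.items():
            if pattern.lower() in name.lower():
                return trace
        raise ChannelError(f"no channel matching {pattern!r} among {list(self.channels)}")

    def eeg(self, which: str = "EEG1") -> np.ndarray:
        return self.channel(which)

    def emg(self) -> np.ndarray:
        return self.channel("EMG")


@dataclass
class Hypnogram:
    """Per-epoch vigilance-state labels with artifact flags.

    Labels come from :data:`STATE_ALPHABET`; the ``a`` prefix marks
    artifact-contaminated epochs of the corresponding state.
    """

    labels: list[str]
    epoch_len: float = 4.0

    def __post_init__(self) -> None:
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")
        self.labels = list(self.labels)
        for i, lab in enumerate(self.labels):
            if lab not in STATE_ALPHABET:
                raise ValueError(
                    f"unknown vigilance label {lab!r} at epoch {i}; "
                    f"expected one of {STATE_ALPHABET}"
                )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration(self) -> float:
        return len(self.labels) * self.epoch_len

    def state(self, i: int) -> str:
        """Base state (W/N/R) of epoch ``i``, ignoring the artifact flag."""
        return self.labels[i].lstrip("a")

    def is_artifact(self, i: int) -> bool:
        return self.labels[i].startswith("a")

    def epoch_of(self, t: float) -> int:
        """Index of the epoch containing time ``t`` (seconds)."""
        return int(t // self.epoch_len)

    def states(self) -> np.ndarray:
        """Array of base states, artifact flags stripped."""
        return np.array([lab.lstrip("a") for lab in self.labels])

    def artifact_mask(self) -> np.ndarray:
        return np.array([lab.startswith("a") for lab in self.labels])


@dataclass
class TriggerLog:
    """Timestamped stimulation events.

    ``muted`` is true exactly for the mock condition: triggers are logged but
    no sound is delivered.  ``achieved_phase_deg`` is filled in by offline
    analysis (Hilbert phase at onset) and may be NaN until then.
    """

    onsets: np.ndarray
    target_phase_deg: float
    condition: str
    muted: bool | None = None
    achieved_phase_deg: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.muted is None:
            self.muted = self.condition == "mock"
        if self.muted != (self.condition == "mock"):
            raise ValueError("muted must be true iff condition is 'mock'")
        if not 0 <= self.target_phase_deg < 360:
            raise ValueError("target phase must lie in [0, 360)")
        if len(self.onsets) > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("trigger onsets must be strictly increasing")
        if self.achieved_phase_deg is not None:
            self.achieved_phase_deg = np.asarray(self.achieved_phase_deg, dtype=float)
            if len(self.achieved_phase_deg) != len(self.onsets):
                raise ValueError("achieved_phase_deg length must match onsets")

    def __len__(self) -> int:
        return len(self.onsets)
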