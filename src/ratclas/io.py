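"""Readers and writers for recordings (EDF), hypnograms and trigger logs.

EDF reading is delegated to MNE.  Writing uses a small self-contained EDF
encoder (16-bit samples with per-channel physical scaling), sufficient for
the plain continuous multichannel recordings this package produces.
Hypnograms and trigger logs are plain delimited text, one row per
epoch/trigger, so they stay diffable and software-agnostic.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ChannelError, Hypnogram, Recording, TriggerLog

#: Default channel-name patterns used to locate EEG/EMG traces in an EDF.
DEFAULT_CHANNEL_PATTERNS = {"eeg": ("EEG1", "EEG2"), "emg": ("EMG",)}

_DIGMIN, _DIGMAX = -32768, 32767


def _record_duration(fs: float) -> int:
    """Smallest record duration (s) giving an integer number of samples."""
    for d in (1, 2, 4, 5, 10, 20, 40, 60):
        if abs(fs * d - round(fs * d)) < 1e-6:
            return d
    raise ValueError(f"cannot find an EDF record duration for fs={fs}")


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` to an EDF file.

    The trace is zero-padded to fill the last data record; the pad is at
    most one record duration and carries the value 0 µV.
    """
    rec_dur = _record_duration(recording.fs)
    spr = int(round(recording.fs * rec_dur))
    n = recording.n_samples
    n_rec = max(1, int(np.ceil(n / spr)))
    labels = list(recording.channels)
    n_ch = len(labels)

    scaled, pmins, pmaxs = [], [], []
    for name in labels:
        sig = np.concatenate([recording.channels[name], np.zeros(n_rec * spr - n)])
        pmin, pmax = float(sig.min()), float(sig.max())
        if pmax <= pmin:  # constant channel: EDF needs pmax > pmin
            pmax = pmin + 1.0
        gain = (_DIGMAX - _DIGMIN) / (pmax - pmin)
        scaled.append(np.round((sig - pmin) * gain + _DIGMIN).astype("<i2"))
        pmins.append(pmin)
        pmaxs.append(pmax)

    hdr = _io.BytesIO()

    def put(value, width: int) -> None:
        hdr.write(str(value)[:width].ljust(width).encode("ascii"))

    put("0", 8)                      # version
    put("X X X X", 80)               # patient id (anonymous)
    put("Startdate X X X X", 80)     # recording id
    put("01.01.00", 8)               # start date
    put("00.00.00", 8)               # start time
    put(256 * (n_ch + 1), 8)         # header bytes
    put("", 44)                      # reserved
    put(n_rec, 8)
    put(rec_dur, 8)
    put(n_ch, 4)
    for lab in labels:
        put(lab, 16)
    for _ in labels:
        put("", 80)                  # transducer
    for _ in labels:
        put("uV", 8)
    for v in pmins:
        put(f"{v:.4f}"[:8], 8)
    for v in pmaxs:
        put(f"{v:.4f}"[:8], 8)
    for _ in labels:
        put(_DIGMIN, 8)
    for _ in labels:
        put(_DIGMAX, 8)
    for _ in labels:
        put("", 80)                  # prefilter
    for _ in labels:
        put(spr, 8)
    for _ in labels:
        put("", 32)                  # reserved

    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        for r in range(n_rec):
            for ch in scaled:
                fh.write(ch[r * spr : (r + 1) * spr].tobytes())


def read_recording(
    path: str | Path,
    channel_patterns: dict | None = None,
    n_samples: int | None = None,
) -> Recording:
    """Read an EDF file into a :class:`Recording` (signal values in µV).

    Parameters
    ----------
    channel_patterns : dict, optional
        ``{"eeg": (...), "emg": (...)}`` name substrings used to check that
        the file has at least one EEG and one EMG channel.
    n_samples : int, optional
        Trim to this many samples (drops the zero pad of the last record).
    """
    import mne  # deferred: mne import is slow

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE rescales µV -> V; undo
    channels = {name: data[i] for i, name in enumerate(raw.ch_names)}
    if n_samples is not None:
        channels = {k: v[:n_samples] for k, v in channels.items()}

    patterns = channel_patterns or DEFAULT_CHANNEL_PATTERNS
    names_lower = [n.lower() for n in channels]
    for role in ("eeg", "emg"):
        pats = patterns.get(role, ())
        if not any(p.lower() in n for p in pats for n in names_lower):
            raise ChannelError(f"no {role.upper()} channel found among {list(channels)}")
    return Recording(channels=channels, fs=float(raw.info["sfreq"]))


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    """Write a hypnogram as CSV with columns (epoch_index, label)."""
    df = pd.DataFrame({"epoch_index": np.arange(len(hyp)), "label": hyp.labels})
    df.to_csv(path, index=False)


def read_hypnogram(path: str | Path, epoch_len: float = 4.0) -> Hypnogram:
    """Read a hypnogram from delimited text.

    Accepts either the two-column (epoch_index, label) dialect written by
    :func:`write_hypnogram` or a single column/row of comma-separated labels.
    Unknown symbols raise with the offending symbol and row named.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"empty hypnogram file: {path}")
    if text.splitlines()[0].lower().startswith("epoch_index"):
        df = pd.read_csv(path)
        labels = [str(x).strip() for x in df["label"]]
    else:
        tokens: list[str] = []
        for line in text.splitlines():
            tokens.extend(t.strip() for t in line.split(",") if t.strip())
        labels = tokens
    try:
        return Hypnogram(labels=labels, epoch_len=epoch_len)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from None


def write_trigger_log(log: TriggerLog, path: str | Path) -> None:
    """Write a trigger log as CSV (onset_s, target_phase_deg, condition, muted, achieved_phase_deg)."""
    achieved = (
        log.achieved_phase_deg
        if log.achieved_phase_deg is not None
        else np.full(len(log), np.nan)
    )
    df = pd.DataFrame(
        {
            "onset_s": log.onsets,
            "target_phase_deg": np.full(len(log), log.target_phase_deg),
            "condition": [log.condition] * len(log),
            "muted": [log.muted] * len(log),
            "achieved_phase_deg": achieved,
        }
    )
    df.to_csv(path, index=False)


def read_trigger_log(path: str | Path) -> TriggerLog:
    df = pd.read_csv(path)
    if len(df) == 0:
        return TriggerLog(onsets=np.array([]), target_phase_deg=0.0, condition="mock")
    achieved = df["achieved_phase_deg"].to_numpy(float)
    return TriggerLog(
        onsets=df["onset_s"].to_numpy(float),
        target_phase_deg=float(df["target_phase_deg"].iloc[0]),
        condition=str(df["condition"].iloc[0]),
        muted=bool(df["muted"].iloc[0]),
        achieved_phase_deg=None if np.all(np.isnan(achieved)) else achieved,
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON configuration file into a plain dict."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
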