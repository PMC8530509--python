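"""Trigger-train and ISI statistics, ERP extraction, circular phase analysis.

Trigger trains are maximal runs of triggers at most one gap apart (1 s by
default; slow oscillations in rats peak near 1.35 Hz, so consecutive
within-sleep triggers sit about one cycle apart).  Achieved targeting is
quantified by the Hilbert phase of the 0.5-2 Hz EEG component at each
trigger onset, summarized with circular statistics and a six-bin 60°
histogram normalized per subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import Hypnogram, TriggerLog
from .spectral import ANALYSIS_FS, bandpass_zero_phase

#: Gap threshold variant used in parts of the reference analysis.
TRAIN_GAP_ALT_S = 0.8

#: Default log-spaced ISI bin edges, seconds.
DEFAULT_ISI_EDGES = (0.5, 1, 2, 4, 8, 16, 32, 64, 128, 256)


@dataclass
class TrainHistogram:
    """Counts of trigger trains by size; sizes >= ``pool_at`` are pooled."""

    counts: dict          # size (int) -> count; key pool_at holds the pool
    pool_at: int = 5
    gap_s: float = 1.0
    total_triggers: int = 0
    pooled_triggers: int = 0   # triggers inside pooled (>= pool_at) trains

    def conserved(self) -> bool:
        """Sum of size x count (pooled trains by actual membership) equals the total."""
        s = sum(size * cnt for size, cnt in self.counts.items() if size < self.pool_at)
        return s + self.pooled_triggers == self.total_triggers


def train_histogram(onsets: np.ndarray, gap_s: float = 1.0, pool_at: int = 5) -> TrainHistogram:
    """Partition sorted onsets into maximal runs with consecutive gaps <= gap_s."""
    onsets = np.asarray(onsets, float)
    counts = {k: 0 for k in range(1, pool_at + 1)}
    if len(onsets) == 0:
        return TrainHistogram(counts=counts, pool_at=pool_at, gap_s=gap_s)
    breaks = np.flatnonzero(np.diff(onsets) > gap_s)
    sizes = np.diff(np.r_[-1, breaks, len(onsets) - 1])
    pooled = 0
    for s in sizes:
        if s >= pool_at:
            counts[pool_at] += 1
            pooled += int(s)
        else:
            counts[int(s)] += 1
    return TrainHistogram(
        counts=counts, pool_at=pool_at, gap_s=gap_s,
        total_triggers=len(onsets), pooled_triggers=pooled,
    )


def isi_histogram(onsets: np.ndarray, bin_edges=DEFAULT_ISI_EDGES) -> tuple[np.ndarray, np.ndarray]:
    """Probability density of interstimulus intervals over the given bins.

    Returns (density, edges) with sum(density x bin width) = 1 when any
    ISI falls inside the binned range.
    """
    onsets = np.asarray(onsets, float)
    if len(onsets) < 2:
        raise ValueError("need at least two triggers to form an ISI")
    isis = np.diff(onsets)
    density, edges = np.histogram(isis, bins=np.asarray(bin_edges, float), density=True)
    return density, edges


def extract_erps(
    trace: np.ndarray,
    log: TriggerLog,
    hypnogram: Hypnogram,
    fs: float = ANALYSIS_FS,
    pre_s: float = 1.5,
    post_s: float = 2.0,
    band: tuple = (0.5, 2.0),
) -> dict:
    """Event-related potentials around NREM triggers.

    Snippets cover a 3.5 s window (−1.5 to +2 s around onset, a 2 s
    post-stimulus cutoff).  Triggers outside plain-N epochs or followed by
    another trigger within 1 s (post-ISI <= 1 s) are excluded; windows
    extending past the recording are dropped and logged.  The trace is
    band-passed (zero phase) before snipping.

    Returns dict with ``snippets`` (n x window), ``average``, ``t`` (s,
    relative to onset), ``included`` onsets and ``dropped``.
    """
    x = bandpass_zero_phase(np.asarray(trace, float), band[0], band[1], fs)
    n_pre, n_post = int(round(pre_s * fs)), int(round(post_s * fs))
    win = n_pre + n_post
    t = (np.arange(win) - n_pre) / fs

    onsets = np.asarray(log.onsets, float)
    post_isi = np.diff(np.r_[onsets, np.inf])
    keep, dropped = [], []
    for onset, gap in zip(onsets, post_isi):
        i = hypnogram.epoch_of(onset)
        if not (0 <= i < len(hypnogram)) or hypnogram.labels[i] != "N":
            dropped.append({"onset": float(onset), "reason": "not NREM"})
            continue
        if gap <= 1.0:
            dropped.append({"onset": float(onset), "reason": "post-ISI <= 1 s"})
            continue
        k = int(round(onset * fs))
        if k - n_pre < 0 or k + n_post > len(x):
            dropped.append({"onset": float(onset), "reason": "window out of range"})
            continue
        keep.append((onset, x[k - n_pre : k + n_post]))

    snippets = np.array([s for _, s in keep]) if keep else np.empty((0, win))
    average = snippets.mean(axis=0) if len(snippets) else np.full(win, np.nan)
    return {
        "snippets": snippets,
        "average": average,
        "t": t,
        "included": np.array([o for o, _ in keep]),
        "dropped": dropped,
    }


@dataclass
class CircularStats:
    """Summary of a sample of angles (degrees).

    ``circ_sd_deg`` is sqrt(−2 ln R) in degrees; ``circ_var`` is the
    dimensionless 1 − R; ``ang_dev_deg`` is the angular deviation
    sqrt(2(1 − R)) in degrees — both dispersion conventions are reported
    because toolbox outputs differ.
    """

    mean_deg: float
    R: float
    n: int

    @property
    def circ_sd_deg(self) -> float:
        if self.R <= 0:
            return float("inf")
        return float(np.degrees(np.sqrt(-2.0 * np.log(self.R))))

    @property
    def circ_var(self) -> float:
        return 1.0 - self.R

    @property
    def ang_dev_deg(self) -> float:
        return float(np.degrees(np.sqrt(2.0 * (1.0 - self.R))))


def circular_stats(angles_deg: np.ndarray) -> CircularStats:
    """Mean direction and resultant length by the vector-sum formula.

    With R = 0 (e.g. antipodal angles) the mean direction is undefined and
    reported as NaN.
    """
    a = np.deg2rad(np.asarray(angles_deg, float))
    if len(a) == 0:
        raise ValueError("no angles")
    z = np.exp(1j * a).mean()
    R = float(np.abs(z))
    mean = float(np.degrees(np.angle(z))) % 360.0 if R > 1e-12 else float("nan")
    return CircularStats(mean_deg=mean, R=R, n=len(a))


def hilbert_phase_deg(trace: np.ndarray) -> np.ndarray:
    """Instantaneous phase in the slow-wave convention (0° rising zero-crossing).

    The analytic-signal angle is 0 at a cosine peak; the convention places
    the peak at 90°, so 90° is added.
    """
    return (np.degrees(np.angle(signal.hilbert(np.asarray(trace, float)))) + 90.0) % 360.0


def phase_at_triggers(
    trace: np.ndarray,
    log: TriggerLog,
    fs: float = ANALYSIS_FS,
    band: tuple = (0.5, 2.0),
    n_bins: int = 6,
) -> dict:
    """Hilbert phase of the slow-wave band at each trigger onset.

    Returns dict with ``angles_deg``, ``stats`` (:class:`CircularStats`),
    ``hist`` (per-subject-normalized counts over ``n_bins`` equal bins) and
    ``bin_edges_deg``.
    """
    if len(log) == 0:
        raise ValueError("trigger log is empty")
    filt = bandpass_zero_phase(np.asarray(trace, float), band[0], band[1], fs)
    phase = hilbert_phase_deg(filt)
    idx = np.clip(np.round(np.asarray(log.onsets) * fs).astype(int), 0, len(phase) - 1)
    angles = phase[idx]
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    return {
        "angles_deg": angles,
        "stats": circular_stats(angles),
        "hist": counts / counts.sum(),
        "bin_edges_deg": edges,
    }
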