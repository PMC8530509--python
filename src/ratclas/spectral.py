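"""Offline EEG postprocessing: preprocessing, per-epoch PSD, band powers,
change-from-baseline time courses and sleep-architecture metrics.

The preprocessing chain resamples EEG to 300 Hz, tapers the first and last
2 s with a Fermi (logistic) edge window, and band-limits the signal with
zero-phase equiripple FIR filters (applied forward and backward).  Spectra
are estimated on 4 s Hamming-windowed segments advanced by 2 s (0.25 Hz
resolution), averaged within each 4 s scoring epoch, and each epoch's bins
are normalized by its total power over 0.5-30 Hz, so band powers are
relative (dimensionless) and robust to gain differences between animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

from .containers import Hypnogram

ANALYSIS_FS = 300.0

#: Half-amplitude band edges, Hz, half-open (low, high].
DEFAULT_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 11.0),
    "sigma": (11.0, 16.0),
    "beta": (16.0, 20.0),
}
#: Variant with the wider 16-30 Hz beta band.
WIDE_BANDS = {**DEFAULT_BANDS, "beta": (16.0, 30.0)}


@dataclass
class BandScheme:
    """Named frequency bands plus the total-power normalization range."""

    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    total_range: tuple = (0.5, 30.0)

    def __post_init__(self) -> None:
        edges = sorted(self.bands.values())
        for (l0, h0), (l1, _h1) in zip(edges, edges[1:]):
            if l1 < h0:
                raise ValueError(f"overlapping bands at {h0}-{l1} Hz")
        lo, hi = self.total_range
        for name, (l, h) in self.bands.items():
            if l < lo - 1e-9 or h > hi + 1e-9:
                raise ValueError(f"band {name} outside total range {self.total_range}")


def fermi_taper(n_samples: int, fs: float = ANALYSIS_FS, edge_s: float = 2.0) -> np.ndarray:
    """Edge window w(n) = 1/(1 + exp(5 - n/50)), n = 1..edge samples, mirrored.

    At 300 Hz the taper spans the first/last 600 samples and passes 0.5 at
    n = 250 from each edge; the interior is unity.
    """
    m = int(round(edge_s * fs))
    w = np.ones(n_samples)
    if n_samples < 2 * m:
        raise ValueError("trace shorter than twice the edge taper")
    n = np.arange(1, m + 1)
    edge = 1.0 / (1.0 + np.exp(5.0 - n / 50.0))
    w[:m] = edge
    w[-m:] = edge[::-1]
    return w


@lru_cache(maxsize=16)
def _fir_highpass(numtaps: int, f_stop: float, f_pass: float, fs: float) -> np.ndarray:
    return signal.remez(numtaps, [0, f_stop, f_pass, fs / 2], [0, 1], fs=fs, maxiter=100)


@lru_cache(maxsize=16)
def _fir_lowpass(numtaps: int, f_pass: float, f_stop: float, fs: float) -> np.ndarray:
    return signal.remez(numtaps, [0, f_pass, f_stop, fs / 2], [1, 0], fs=fs, maxiter=100)


def zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward FIR filtering via FFT convolution (zero phase).

    Equivalent to filtfilt with the given FIR kernel but O(N log N), which
    matters at the multi-thousand-tap orders used here.
    """
    y = signal.fftconvolve(x, taps, mode="full")
    y = signal.fftconvolve(y[::-1], taps, mode="full")[::-1]
    trim = len(taps) - 1
    return y[trim:-trim] if trim else y


def preprocess_eeg(trace: np.ndarray, fs_in: float, fs_out: float = ANALYSIS_FS) -> np.ndarray:
    """Resample to the analysis rate, taper edges, band-limit 0.5-48 Hz.

    The band limit uses zero-phase equiripple FIR filters of order
    1880 (high-pass) and 398 (low-pass); their half-amplitude cutoffs land
    near 0.28 and 49.12 Hz.
    """
    if len(trace) < 4 * fs_in:
        raise ValueError("recording shorter than 4 s")
    if abs(fs_in - fs_out) > 1e-9:
        frac = Fraction(fs_out / fs_in).limit_denominator(10000)
        x = signal.resample_poly(np.asarray(trace, float), frac.numerator, frac.denominator)
    else:
        x = np.asarray(trace, float).copy()
    x *= fermi_taper(len(x), fs_out)
    hp = _fir_highpass(1881, 0.06, 0.5, fs_out)
    lp = _fir_lowpass(399, 48.0, 50.3, fs_out)
    return zero_phase_fir(zero_phase_fir(x, hp), lp)


def design_band_filter(low: float, high: float, fs: float = ANALYSIS_FS) -> tuple[np.ndarray, np.ndarray]:
    """High-order equiripple band-pass pair (orders 3758/3861).

    Transition bands are placed so the half-amplitude cutoffs fall just
    inside the nominal band, mirroring the reference chain (0.5-2 Hz band
    -> -6 dB at 0.39 and 1.91 Hz).
    """
    hp = _fir_highpass(3759, round(0.56 * low, 6), low, fs)
    lp = _fir_lowpass(3862, round(0.91 * high, 6), high, fs)
    return hp, lp


def bandpass_zero_phase(x: np.ndarray, low: float, high: float, fs: float = ANALYSIS_FS) -> np.ndarray:
    """Zero-phase band-pass with the high-order equiripple pair."""
    hp, lp = design_band_filter(low, high, fs)
    return zero_phase_fir(zero_phase_fir(x, hp), lp)


def interpolate_artifacts(
    trace: np.ndarray,
    hypnogram: Hypnogram,
    fs: float = ANALYSIS_FS,
    iqr_factor: float = 8.0,
    max_run: int = 10,
    iqr_window_s: float = 7200.0,
) -> tuple[np.ndarray, list[dict]]:
    """Repair brief extreme excursions inside scored NREM sleep.

    Within plain-N epochs, runs of fewer than ``max_run`` consecutive
    samples whose magnitude exceeds ``iqr_factor`` x IQR are replaced by
    cubic-spline interpolation from flanking samples.  The IQR is local:
    computed over NREM samples within a ±1 h window around coarse grid
    centers (10 min step).  Longer excursions are left untouched but logged.
    """
    x = np.asarray(trace, float).copy()
    n = len(x)
    states = hypnogram.states()
    epoch_idx = np.minimum(
        (np.arange(n) / fs // hypnogram.epoch_len).astype(int), len(states) - 1
    )
    in_n = (states[epoch_idx] == "N") & ~hypnogram.artifact_mask()[epoch_idx]
    log: list[dict] = []
    if not in_n.any():
        return x, log

    # local IQR on a coarse grid
    half_w = int(iqr_window_s * fs / 2)
    step = int(600 * fs)
    centers = np.arange(step // 2, n, step)
    if len(centers) == 0:
        centers = np.array([n // 2])
    iqrs = []
    for c in centers:
        seg = x[max(0, c - half_w) : c + half_w]
        msk = in_n[max(0, c - half_w) : c + half_w]
        vals = seg[msk] if msk.any() else x[in_n]
        q75, q25 = np.percentile(vals, [75, 25])
        iqrs.append(q75 - q25)
    iqrs = np.asarray(iqrs)
    nearest = np.clip(
        np.round((np.arange(n) - centers[0]) / step).astype(int), 0, len(centers) - 1
    )
    thr = iqr_factor * iqrs[nearest]

    bad = in_n & (np.abs(x) > thr)
    if not bad.any():
        return x, log
    edges = np.flatnonzero(np.diff(np.r_[0, bad.astype(int), 0]))
    for s, e in zip(edges[::2], edges[1::2]):
        length = e - s
        if length >= max_run:
            log.append({"start": int(s), "length": int(length), "repaired": False})
            continue
        left = [i for i in range(s - 8, s) if 0 <= i < n and not bad[i]]
        right = [i for i in range(e, e + 8) if i < n and not bad[i]]
        if len(left) < 2 or len(right) < 2:
            log.append({"start": int(s), "length": int(length), "repaired": False})
            continue
        knots = np.array(left + right)
        x[s:e] = CubicSpline(knots, x[knots])(np.arange(s, e))
        log.append({"start": int(s), "length": int(length), "repaired": True})
    return x, log


@dataclass
class SpectralTable:
    """Per-epoch relative power spectra on a 0.25 Hz bin grid."""

    freqs: np.ndarray           # bin centers, Hz
    rel_power: np.ndarray       # (n_epochs, n_bins); rows sum to 1 over total_range
    stages: np.ndarray          # base state per epoch
    artifact: np.ndarray        # artifact flag per epoch
    epoch_len: float = 4.0
    total_range: tuple = (0.5, 30.0)

    def __len__(self) -> int:
        return len(self.stages)

    def band_mask(self, low: float, high: float) -> np.ndarray:
        """Bins whose center lies in the half-open interval (low, high]."""
        return (self.freqs > low + 1e-9) & (self.freqs <= high + 1e-9)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rel_power, columns=[f"{f:.2f}" for f in self.freqs])
        df.insert(0, "stage", self.stages)
        df.insert(1, "artifact", self.artifact)
        return df


def psd_epochs(
    trace: np.ndarray,
    hypnogram: Hypnogram,
    fs: float = ANALYSIS_FS,
    total_range: tuple = (0.5, 30.0),
) -> SpectralTable:
    """Per-epoch normalized power spectra.

    4 s Hamming segments at 2 s hop; each segment belongs to the scoring
    epoch containing its midpoint, so interior epochs average two
    segments.  Each epoch's bin powers are normalized by its summed power
    over ``total_range`` (half-open (lo, hi]).
    """
    nper = int(round(4 * fs))
    hop = int(round(2 * fs))
    if len(trace) < nper:
        raise ValueError("trace shorter than one 4 s epoch")
    f, tt, S = signal.spectrogram(
        np.asarray(trace, float), fs=fs, window="hamming", nperseg=nper,
        noverlap=nper - hop, mode="psd", detrend=False,
    )
    n_epochs = min(len(hypnogram), int(len(trace) / fs // hypnogram.epoch_len))
    seg_epoch = (tt // hypnogram.epoch_len).astype(int)
    rel = np.full((n_epochs, len(f)), np.nan)
    lo, hi = total_range
    norm_mask = (f > lo + 1e-9) & (f <= hi + 1e-9)
    for k in range(n_epochs):
        cols = np.flatnonzero(seg_epoch == k)
        if len(cols) == 0:
            continue
        p = S[:, cols].mean(axis=1)
        tot = p[norm_mask].sum()
        rel[k] = p / tot if tot > 0 else np.nan
    return SpectralTable(
        freqs=f,
        rel_power=rel,
        stages=hypnogram.states()[:n_epochs],
        artifact=hypnogram.artifact_mask()[:n_epochs],
        epoch_len=hypnogram.epoch_len,
        total_range=total_range,
    )


def band_power(
    table: SpectralTable,
    scheme: BandScheme | None = None,
    stage: str = "N",
    include_artifact: bool = False,
    group: str | None = "day",
) -> pd.DataFrame:
    """Mean relative band power over selected epochs, grouped by day or hour.

    ``group`` is "day" (86400 s), "hour" (zeitgeber hour, 3600 s) or None
    for a single overall group.  Groups without qualifying epochs carry NaN.
    """
    scheme = scheme or BandScheme()
    sel = table.stages == stage
    if not include_artifact:
        sel &= ~table.artifact
    sel &= np.isfinite(table.rel_power).all(axis=1)

    epoch_t = np.arange(len(table)) * table.epoch_len
    if group == "day":
        keys = (epoch_t // 86400).astype(int)
    elif group == "hour":
        keys = (epoch_t // 3600).astype(int) + 1  # ZT hour, 1-based
    elif group is None:
        keys = np.zeros(len(table), dtype=int)
    else:
        raise ValueError(f"unknown grouping {group!r}")

    cols = {}
    for name, (l, h) in scheme.bands.items():
        cols[name] = table.rel_power[:, table.band_mask(l, h)].sum(axis=1)
    df = pd.DataFrame(cols)
    df["_key"] = keys
    df["_sel"] = sel
    out = df[df["_sel"]].groupby("_key").mean().drop(columns="_sel")
    full_index = pd.Index(sorted(np.unique(keys)), name="group")
    out.index.name = "group"
    return out.reindex(full_index)


def change_from_baseline(series, baseline) -> pd.Series:
    """Percent change from baseline per matched key: 100·(x − x_BL)/x_BL.

    Accepts aligned pandas Series (joined on index) or equal-length arrays.
    Keys with a zero baseline are NaN.
    """
    if isinstance(series, pd.Series) and isinstance(baseline, pd.Series):
        x, b = series.align(baseline, join="inner")
    else:
        x = pd.Series(np.asarray(series, float))
        b = pd.Series(np.asarray(baseline, float))
        if len(x) != len(b):
            raise ValueError("series and baseline must have equal length")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (x - b) / b
    return out.where(b != 0)


def contrast_pp(change_a: pd.Series, change_b: pd.Series) -> pd.Series:
    """Difference of two percent-change series, in percentage points."""
    a, b = pd.Series(change_a).align(pd.Series(change_b), join="inner")
    return a - b


@dataclass
class SleepArchitecture:
    """NREM amount and fragmentation of one hypnogram."""

    nrem_minutes: float
    n_bouts: int
    n_nrem_epochs: int

    @property
    def fragmentation_index(self) -> float:
        """NREM bouts per NREM epoch; higher means more fragmented sleep."""
        return self.n_bouts / self.n_nrem_epochs if self.n_nrem_epochs else float("nan")


def sleep_architecture(hypnogram: Hypnogram) -> SleepArchitecture:
    """NREM minutes (artifact-flagged NREM included) and bout fragmentation.

    A bout is a maximal run of consecutive NREM epochs.
    """
    is_n = hypnogram.states() == "N"
    n_epochs = int(is_n.sum())
    bouts = int(np.sum(np.diff(np.r_[0, is_n.astype(int)]) == 1))
    minutes = n_epochs * hypnogram.epoch_len / 60.0
    return SleepArchitecture(nrem_minutes=minutes, n_bouts=bouts, n_nrem_epochs=n_epochs)
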