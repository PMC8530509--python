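"""Validation of online staging against an offline-scored hypnogram.

Online gate decisions arrive on a 1 s grid; the offline reference is scored
in 4 s epochs, so decisions are grouped in blocks of four and a block counts
as online-NREM whenever two or more of its 1 s values were true.  The
positive class is plain NREM; artifact-flagged epochs count as negatives
(they are not sustained NREM) but are reported separately in the trigger
breakdown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Hypnogram, TriggerLog


def aggregate_online_epochs(decisions_1s: np.ndarray, block: int = 4, min_true: int = 2) -> np.ndarray:
    """Collapse 1 s gate decisions to per-epoch online NREM labels.

    Non-overlapping blocks of ``block`` decisions; a block is NREM iff at
    least ``min_true`` values are true.  A trailing partial block is dropped.
    """
    d = np.asarray(decisions_1s, dtype=bool)
    if len(d) < block:
        raise ValueError(f"need at least {block} decisions, got {len(d)}")
    n_blocks = len(d) // block
    return d[: n_blocks * block].reshape(n_blocks, block).sum(axis=1) >= min_true


@dataclass
class ConfusionSummary:
    """2x2 tally of online vs offline NREM with the three reported ratios.

    Ratios are NaN when their denominator is zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def _ratio(self, num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    @property
    def sensitivity(self) -> float:
        """Online NREM confirmed offline, out of all offline NREM."""
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        """Online non-NREM confirmed offline, out of all offline non-NREM."""
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> float:
        """Offline-confirmed NREM among all online NREM labels."""
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def n_epochs(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(online_nrem: np.ndarray, hypnogram: Hypnogram) -> ConfusionSummary:
    """Compare per-epoch online NREM labels with the offline reference.

    The offline positive class is plain ``N``; ``aN`` and every other label
    count as negative.  Arrays must already be aligned (both starting at
    recording time 0) and of equal length.
    """
    online = np.asarray(online_nrem, dtype=bool)
    if len(online) != len(hypnogram):
        raise ValueError(
            f"length mismatch: {len(online)} online epochs vs {len(hypnogram)} offline"
        )
    offline = np.asarray(hypnogram.labels) == "N"
    tp = int(np.sum(online & offline))
    fp = int(np.sum(online & ~offline))
    fn = int(np.sum(~online & offline))
    tn = int(np.sum(~online & ~offline))
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def trigger_stage_breakdown(log: TriggerLog, hypnogram: Hypnogram) -> dict:
    """Count triggers per vigilance state of the epoch containing each onset.

    Artifact-flagged epochs are pooled into an ``artifact`` bucket (split
    by state in ``artifact_detail``); onsets beyond the labeled span land in
    ``unlabeled``.  Proportions are over all triggers and sum to 1; with an
    empty log they are NaN.
    """
    counts = {"W": 0, "N": 0, "R": 0, "artifact": 0, "unlabeled": 0}
    detail = {"aW": 0, "aN": 0, "aR": 0}
    for onset in log.onsets:
        i = hypnogram.epoch_of(onset)
        if not 0 <= i < len(hypnogram):
            counts["unlabeled"] += 1
            continue
        lab = hypnogram.labels[i]
        if lab.startswith("a"):
            counts["artifact"] += 1
            detail[lab] += 1
        else:
            counts[lab] += 1
    total = len(log)
    proportions = {
        k: (v / total if total else float("nan")) for k, v in counts.items()
    }
    return {
        "counts": counts,
        "proportions": proportions,
        "artifact_detail": detail,
        "total": total,
    }
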