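"""Single-pellet reaching task (SPRT) metrics and the design-stage power
computation.

Each motor-training session yields counts of attempts, successes, fails and
drop-ins over five bins of 20 pellets or 12 min.  Success rate defaults to
successes per attempt (with an "out of 100 possible attempts" mode, the two
definitions coexisting in the source protocol); intra-session learning is
the log2 fold change of last-bin over first-bin successes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class SessionCounts:
    """Counts of one session (or one bin of a session)."""

    attempts: int
    successes: int
    fails: int
    drop_ins: int
    bin_index: int | None = None

    def __post_init__(self) -> None:
        for name in ("attempts", "successes", "fails", "drop_ins"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.successes + self.fails + self.drop_ins > self.attempts:
            raise ValueError("classified reaches exceed attempts")


def success_fail_rates(counts: SessionCounts, mode: str = "per_attempt") -> tuple[float, float]:
    """Success and fail rates; drop-ins are excluded from both numerators.

    ``mode`` "per_attempt" divides by attempts (drop-ins stay in the
    denominator); "per_100" divides by the 100 possible attempts of a full
    session.
    """
    if mode == "per_attempt":
        if counts.attempts == 0:
            raise ValueError("attempts must be positive in per-attempt mode")
        den = counts.attempts
    elif mode == "per_100":
        den = 100
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return counts.successes / den, counts.fails / den


def intra_session_change(successes_first_bin: int, successes_last_bin: int) -> float:
    """log2 fold change of last-bin over first-bin successes.

    +1 means twice the successes of the first bin, −1 a 50 % drop.  A zero
    first bin is undefined (NaN); a zero last bin with a positive first bin
    is −inf.
    """
    if successes_first_bin < 0 or successes_last_bin < 0:
        raise ValueError("success counts must be non-negative")
    if successes_first_bin == 0:
        return float("nan")
    if successes_last_bin == 0:
        return float("-inf")
    return float(np.log2(successes_last_bin / successes_first_bin))


def apply_exclusion_rule(sr_by_day: dict, min_sr: float = 0.10, from_day: int = 2) -> bool:
    """True (exclude) iff SR stays below ``min_sr`` on every day from M-T_2 on.

    ``sr_by_day`` maps motor-training day number (1-based) to SR.  Reaching
    exactly the minimum on any day keeps the animal.
    """
    days = [d for d in sr_by_day if d >= from_day]
    if from_day not in sr_by_day:
        raise ValueError(f"SR series is missing M-T day {from_day}")
    return all(sr_by_day[d] < min_sr for d in days)


def anova_power(n: int, group_means, within_sd: float, alpha: float = 0.05) -> float:
    """Power of a balanced one-way ANOVA with n subjects per group.

    Noncentral-F with df1 = k−1, df2 = k(n−1) and noncentrality
    λ = n·Σ(μi − μ̄)²/σ² (equivalently (k−1)·n·Var_{k−1}(means)/σ²), the
    convention of R's ``power.anova.test``.
    """
    means = np.asarray(group_means, float)
    k = len(means)
    if k < 2:
        raise ValueError("need at least two groups")
    if within_sd <= 0:
        raise ValueError("within-group SD must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    lam = n * np.sum((means - means.mean()) ** 2) / within_sd**2
    df1, df2 = k - 1, k * (n - 1)
    fcrit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def anova_sample_size(
    group_means,
    within_sd: float,
    alpha: float = 0.05,
    power: float = 0.80,
    n_max: int = 10000,
) -> int:
    """Smallest per-group n with ANOVA power at least the target.

    For the design of the stimulation study — expected delta changes of
    +15 % (up-phase), 0 % (mock) and −10 % (down-phase) with a 15 % SD —
    this gives n = 8 per group at α = 0.05 and power 0.80.
    """
    means = np.asarray(group_means, float)
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    if np.allclose(means, means.mean()):
        raise ValueError("zero effect: identical group means admit no finite n")
    for n in range(2, n_max + 1):
        if anova_power(n, means, within_sd, alpha) >= power:
            return n
    raise ValueError(f"power {power} not reached by n = {n_max}")
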