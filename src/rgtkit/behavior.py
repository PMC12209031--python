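"""Behavioral metrics for the rodent gambling task (rGT).

An rGT probe session is a sequence of 90 trials in a two-lever arena.
One lever carries a low-risk contingency (one pellet with probability
0.9, a small certain reward) and the other a high-risk contingency
(three pellets with probability 0.3, a large uncertain reward); the two
have equal expected value. Each completed trial is classified by arm and
outcome — low-risk rewarded (LR) or non-rewarded (LNo), high-risk
rewarded (HR) or non-rewarded (HNo) — and a trial with no lever press
within the 15-s limit is an omission.

The central behavioral statistic is the choice preference index (CPI),

    CPI = (n_low - n_high) / n_completed,

computed per block of 10 consecutive trials. CPI lies in [-1, 1]: values
near +1 indicate a strong preference for the low-risk lever, values near
-1 a strong preference for the high-risk lever. Omissions count toward
block membership but not toward the CPI denominator (completed trials
only), which is what bounds the index to [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TRIAL_LIMIT_S",
    "OUTCOME_CLASSES",
    "OMISSION",
    "RESPONSE_MAP_CODES",
    "Trial",
    "Session",
    "PreferenceCurve",
    "LatencySummary",
    "choice_preference_index",
    "preference_curve",
    "smooth_curve",
    "omission_rate",
    "response_map",
    "latency_summary",
]

#: Trial duration limit (seconds); reaching it without a press is an omission.
TRIAL_LIMIT_S = 15.0

#: Completed-trial outcome classes: low/high risk, rewarded or not.
OUTCOME_CLASSES = ("LR", "LNo", "HR", "HNo")
OMISSION = "omission"

_LOW_OUTCOMES = frozenset({"LR", "LNo"})
_HIGH_OUTCOMES = frozenset({"HR", "HNo"})

#: Trial-by-trial response-map categorical codes (one per outcome class).
RESPONSE_MAP_CODES = {
    "LR": "low_rewarded",
    "LNo": "low_unrewarded",
    "HR": "high_rewarded",
    "HNo": "high_unrewarded",
    OMISSION: "omission",
}

_ARM_FOR_OUTCOME = {
    "LR": "low_risk",
    "LNo": "low_risk",
    "HR": "high_risk",
    "HNo": "high_risk",
    OMISSION: "none",
}


@dataclass(frozen=True)
class Trial:
    """A single rGT trial.

    ``outcome == "omission"`` if and only if ``arm == "none"`` if and
    only if ``latency is None``; completed-trial latencies lie in
    (0, 15] seconds.
    """

    index: int
    side: str  # "left" | "right" | "none"
    arm: str  # "low_risk" | "high_risk" | "none"
    outcome: str  # "LR" | "LNo" | "HR" | "HNo" | "omission"
    latency: float | None = None

    def __post_init__(self) -> None:
        if self.outcome not in _ARM_FOR_OUTCOME:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.arm != _ARM_FOR_OUTCOME[self.outcome]:
            raise ValueError(
                f"trial {self.index}: arm {self.arm!r} inconsistent with "
                f"outcome {self.outcome!r}"
            )
        if self.outcome == OMISSION:
            if self.latency is not None:
                raise ValueError(f"trial {self.index}: omission with a latency")
        else:
            if self.latency is None:
                raise ValueError(f"trial {self.index}: completed trial without latency")
            if not 0.0 < self.latency <= TRIAL_LIMIT_S:
                raise ValueError(
                    f"trial {self.index}: latency {self.latency} outside "
                    f"(0, {TRIAL_LIMIT_S}]"
                )

    @property
    def is_omission(self) -> bool:
        return self.outcome == OMISSION


@dataclass(frozen=True)
class Session:
    """An ordered rGT probe session (trial indices contiguous from 1)."""

    trials: tuple[Trial, ...]
    session_label: str = "control"  # "control" | "pain" | synthetic label
    treatment: str = "VH"  # "VH" | "QP" | "RC" | synthetic label

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        for i, trial in enumerate(self.trials, start=1):
            if trial.index != i:
                raise ValueError(
                    f"trial indices must be contiguous from 1; got {trial.index} "
                    f"at position {i}"
                )

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def completed(self) -> tuple[Trial, ...]:
        return tuple(t for t in self.trials if not t.is_omission)

    @property
    def n_omissions(self) -> int:
        return sum(t.is_omission for t in self.trials)


@dataclass(frozen=True)
class PreferenceCurve:
    """Per-block CPI values and their smoothed form.

    ``cpi_values`` contains NaN for blocks with zero completed trials
    (rendered as gaps). ``partial_final`` flags a last block shorter
    than ``block_size``.
    """

    block_indices: tuple[int, ...]
    cpi_values: tuple[float, ...]
    smoothed: tuple[float, ...]
    block_size: int
    partial_final: bool = False


@dataclass(frozen=True)
class LatencySummary:
    mean: float
    sd: float
    n: int


def choice_preference_index(trials: Iterable[Trial]) -> float:
    """CPI = (low-risk choices - high-risk choices) / completed trials.

    Returns NaN (the undefined marker) when no trial in ``trials`` was
    completed; omissions never enter the numerator or the denominator.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("choice_preference_index requires at least one trial")
    n_low = sum(t.outcome in _LOW_OUTCOMES for t in trials)
    n_high = sum(t.outcome in _HIGH_OUTCOMES for t in trials)
    n_completed = n_low + n_high
    if n_completed == 0:
        return math.nan
    return (n_low - n_high) / n_completed


def preference_curve(session: Session, block_size: int = 10) -> PreferenceCurve:
    """CPI per block of ``block_size`` consecutive trials, plus 3-point smoothing.

    Blocks tile the trial sequence in order, omissions included in block
    membership; a final partial block is kept and flagged.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if len(session) == 0:
        raise ValueError("cannot compute a preference curve for an empty session")
    trials = session.trials
    cpi = []
    for start in range(0, len(trials), block_size):
        cpi.append(choice_preference_index(trials[start : start + block_size]))
    partial = len(trials) % block_size != 0
    smoothed = smooth_curve(cpi, window=3)
    return PreferenceCurve(
        block_indices=tuple(range(1, len(cpi) + 1)),
        cpi_values=tuple(cpi),
        smoothed=tuple(smoothed),
        block_size=block_size,
        partial_final=partial,
    )


def smooth_curve(values: Sequence[float], window: int = 3) -> list[float]:
    """Centered moving mean with a shrinking window at the edges.

    NaN entries stay NaN in the output and are excluded from the means
    of their neighbours. ``window`` must be odd so the mean is centered.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    x = np.asarray(values, dtype=float)
    half = window // 2
    out = np.full(x.shape, math.nan)
    for i in range(x.size):
        if math.isnan(x[i]):
            continue
        seg = x[max(0, i - half) : i + half + 1]
        out[i] = np.nanmean(seg)
    return out.tolist()


def omission_rate(session: Session) -> float:
    """Percentage of omitted (incomplete) trials in the session."""
    if len(session) == 0:
        raise ValueError("empty session")
    return 100.0 * session.n_omissions / len(session)


def response_map(session: Session) -> list[str]:
    """Trial-by-trial categorical codes for response-map displays.

    One code per trial, in order, drawn from ``RESPONSE_MAP_CODES``
    (low/high x rewarded/unrewarded, plus omission).
    """
    if len(session) == 0:
        raise ValueError("empty session")
    return [RESPONSE_MAP_CODES[t.outcome] for t in session.trials]


def detect_preference_switch(curve: PreferenceCurve) -> float | None:
    """Zero crossing of the smoothed CPI curve, in block units.

    A session that starts risk-averse (positive CPI) and shifts toward
    the high-risk lever crosses zero; the crossing position is linearly
    interpolated between the last positive and first nonpositive
    smoothed block. None if the smoothed curve never starts positive or
    never reaches zero.
    """
    prev_block: float | None = None
    prev_value: float | None = None
    for block, v in zip(curve.block_indices, curve.smoothed):
        if math.isnan(v):
            continue
        if prev_value is not None and prev_value > 0 and v <= 0:
            if v == 0:
                return float(block)
            return prev_block + prev_value / (prev_value - v) * (block - prev_block)
        prev_block, prev_value = float(block), v
    return None


def latency_summary(session: Session) -> LatencySummary:
    """Mean and SD of lever-press latency over completed trials.

    Omissions are excluded. With zero completed trials both moments are
    NaN (undefined marker); with one, the sample SD is NaN.
    """
    lats = np.array([t.latency for t in session.completed], dtype=float)
    if lats.size == 0:
        return LatencySummary(mean=math.nan, sd=math.nan, n=0)
    sd = float(np.std(lats, ddof=1)) if lats.size > 1 else math.nan
    return LatencySummary(mean=float(np.mean(lats)), sd=sd, n=int(lats.size))
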