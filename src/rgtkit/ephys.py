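"""Event-locked spike-train analysis: PETHs, Gaussian smoothing, Z-scoring.

A peri-event time histogram (PETH) bins each unit's spikes relative to
the lever press (press = 0 s) from 5 s before to 10 s after, in 50-ms
bins, averaged over all events of one response class. The raw PETH is
optionally smoothed with a narrow truncated Gaussian kernel (3 bins,
sigma = 1 bin) and standardized against the pre-press baseline:

    Z = (x - m) / SD

where m and SD are the mean and standard deviation of the baseline
(5-s pre-press) bins of the same PETH. Units with a flat baseline
(SD = 0) are flagged ``degenerate_baseline`` rather than assigned
fabricated Z values.

Binning convention (applied everywhere): bins are half-open
[t, t + bin_width) in press-relative time, so a spike exactly at the
press falls in the first post-press bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

__all__ = [
    "SpikeTrain",
    "EventSeries",
    "PETHConfig",
    "PETH",
    "ZScoredPETH",
    "compute_peth",
    "gaussian_smooth",
    "zscore_peth",
    "background_rate",
    "mean_rate_in_window",
]

_VALID_CLASSES = frozenset({"LR", "LNo", "HR", "HNo"})


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted, nonnegative spike timestamps (seconds) for one unit."""

    unit_id: str
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        if ts.ndim != 1:
            raise ValueError("timestamps must be one-dimensional")
        if ts.size and ts[0] < 0:
            raise ValueError("spike timestamps must be nonnegative")
        if np.any(np.diff(ts) < 0):
            raise ValueError("spike timestamps must be nondecreasing")
        object.__setattr__(self, "timestamps", ts)

    def __len__(self) -> int:
        return int(self.timestamps.size)


@dataclass(frozen=True)
class EventSeries:
    """Lever-press event times labeled by trial response class."""

    times: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.classes, dtype=object)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and classes must be 1-D and equal length")
        if np.any(np.diff(t) < 0):
            raise ValueError("event times must be sorted")
        bad = set(c) - _VALID_CLASSES
        if bad:
            raise ValueError(f"invalid response classes: {sorted(bad)}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "classes", c)

    def __len__(self) -> int:
        return int(self.times.size)

    def of_class(self, response_class: str) -> np.ndarray:
        """Event times of one response class."""
        return self.times[self.classes == response_class]


@dataclass(frozen=True)
class PETHConfig:
    """PETH window and bin geometry (defaults: -5 s..+10 s, 50-ms bins)."""

    window_pre: float = 5.0
    window_post: float = 10.0
    bin_width: float = 0.05
    smooth_points: int = 3

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for name, w in (("window_pre", self.window_pre), ("window_post", self.window_post)):
            n = w / self.bin_width
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"{name} must be an integer multiple of bin_width")
        if self.smooth_points < 1 or self.smooth_points % 2 == 0:
            raise ValueError("smooth_points must be odd and >= 1")

    @property
    def n_bins(self) -> int:
        return int(round((self.window_pre + self.window_post) / self.bin_width))

    @property
    def bin_edges(self) -> np.ndarray:
        return -self.window_pre + self.bin_width * np.arange(self.n_bins + 1)


@dataclass(frozen=True)
class PETH:
    """Binned event-locked mean firing rate (Hz per bin).

    ``counts`` holds the raw per-bin spike totals across events (None
    after smoothing, when counts are no longer integers of anything).
    A PETH with ``n_events == 0`` is the explicit empty marker: rates
    are NaN, never silent zeros.
    """

    bin_edges: np.ndarray
    mean_rate: np.ndarray
    n_events: int
    unit_id: str
    response_class: str | None
    counts: np.ndarray | None = None

    @property
    def is_empty(self) -> bool:
        return self.n_events == 0

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class ZScoredPETH:
    """Baseline-normalized PETH; ``degenerate`` marks SD = 0 baselines."""

    bin_edges: np.ndarray
    z: np.ndarray
    baseline_mean: float
    baseline_sd: float
    unit_id: str
    response_class: str | None
    degenerate: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean_z_in_window(self, start: float = 0.0, stop: float = 5.0) -> float:
        """Mean Z over bins whose left edge lies in [start, stop)."""
        if self.degenerate:
            return math.nan
        left = self.bin_edges[:-1]
        mask = (left >= start - 1e-12) & (left < stop - 1e-12)
        return float(np.mean(self.z[mask]))


def compute_peth(
    spikes: SpikeTrain,
    events: EventSeries,
    class_filter: str | None = None,
    config: PETHConfig = PETHConfig(),
) -> PETH:
    """Peri-event time histogram of one unit around lever presses.

    ``mean_rate[b] = total count in bin b across events / (n_events * bin_width)``.
    Overlapping event windows are allowed; each event contributes
    independently. With zero events of the requested class the returned
    PETH is the explicit empty marker (``is_empty``).
    """
    times = events.times if class_filter is None else events.of_class(class_filter)
    n_bins = config.n_bins
    edges = config.bin_edges
    if times.size == 0:
        return PETH(
            bin_edges=edges,
            mean_rate=np.full(n_bins, math.nan),
            n_events=0,
            unit_id=spikes.unit_id,
            response_class=class_filter,
            counts=np.zeros(n_bins, dtype=int),
        )
    counts = np.zeros(n_bins, dtype=int)
    ts = spikes.timestamps
    for t in times:
        lo = np.searchsorted(ts, t - config.window_pre, side="left")
        hi = np.searchsorted(ts, t + config.window_post, side="left")
        if hi > lo:
            idx = np.floor((ts[lo:hi] - t + config.window_pre) / config.bin_width)
            idx = idx.astype(int)
            idx = idx[(idx >= 0) & (idx < n_bins)]
            counts += np.bincount(idx, minlength=n_bins)
    rate = counts / (times.size * config.bin_width)
    return PETH(
        bin_edges=edges,
        mean_rate=rate,
        n_events=int(times.size),
        unit_id=spikes.unit_id,
        response_class=class_filter,
        counts=counts,
    )


def gaussian_smooth(peth: PETH, smooth_points: int = 3, sigma_bins: float = 1.0) -> PETH:
    """Convolve the PETH with a normalized truncated Gaussian kernel.

    The kernel spans ``smooth_points`` bins (odd) with standard
    deviation ``sigma_bins``; weights sum to 1 and are renormalized over
    the available bins at the edges, so a constant PETH is unchanged.
    """
    if smooth_points < 1 or smooth_points % 2 == 0:
        raise ValueError("smooth_points must be odd and >= 1")
    if peth.is_empty:
        return peth
    half = smooth_points // 2
    offsets = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (offsets / sigma_bins) ** 2)
    kernel /= kernel.sum()
    x = peth.mean_rate
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return PETH(
        bin_edges=peth.bin_edges,
        mean_rate=num / den,
        n_events=peth.n_events,
        unit_id=peth.unit_id,
        response_class=peth.response_class,
        counts=None,
    )


def zscore_peth(peth: PETH, baseline: tuple[float, float] | None = None) -> ZScoredPETH:
    """Standardize a PETH against its pre-press baseline.

    ``baseline`` is a half-open press-relative interval, defaulting to
    the full pre-press window [-window_pre, 0). A zero-SD baseline
    yields a ``degenerate`` result (NaN Z) so silent or flat units are
    excluded from Z-based summaries instead of contributing fake nulls.
    """
    if peth.is_empty:
        raise ValueError("cannot Z-score an empty PETH")
    if baseline is None:
        baseline = (float(peth.bin_edges[0]), 0.0)
    lo, hi = baseline
    left = peth.bin_edges[:-1]
    mask = (left >= lo - 1e-12) & (left < hi - 1e-12)
    if not np.any(mask):
        raise ValueError("baseline interval contains no PETH bins")
    base = peth.mean_rate[mask]
    m = float(np.mean(base))
    sd = float(np.std(base, ddof=0))
    if sd == 0.0:
        return ZScoredPETH(
            bin_edges=peth.bin_edges,
            z=np.full(peth.mean_rate.shape, math.nan),
            baseline_mean=m,
            baseline_sd=0.0,
            unit_id=peth.unit_id,
            response_class=peth.response_class,
            degenerate=True,
        )
    return ZScoredPETH(
        bin_edges=peth.bin_edges,
        z=(peth.mean_rate - m) / sd,
        baseline_mean=m,
        baseline_sd=sd,
        unit_id=peth.unit_id,
        response_class=peth.response_class,
    )


def background_rate(
    spikes: SpikeTrain,
    interval: float = 600.0,
    start: float = 0.0,
    duration: float | None = None,
) -> float:
    """Mean firing rate (Hz) over [start, start + interval).

    ``duration``, when given, is the recording length; an interval
    extending past it (or a negative start) is an error.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    if start < 0:
        raise ValueError("interval start must be nonnegative")
    if duration is not None and start + interval > duration + 1e-9:
        raise ValueError("interval extends past the end of the recording")
    ts = spikes.timestamps
    n = np.searchsorted(ts, start + interval, side="left") - np.searchsorted(
        ts, start, side="left"
    )
    return float(n / interval)


def mean_rate_in_window(peth: PETH, start: float, stop: float) -> float:
    """Mean of PETH bin rates whose left edge lies in [start, stop)."""
    if peth.is_empty:
        return math.nan
    left = peth.bin_edges[:-1]
    mask = (left >= start - 1e-12) & (left < stop - 1e-12)
    if not np.any(mask):
        raise ValueError("window contains no PETH bins")
    return float(np.mean(peth.mean_rate[mask]))
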