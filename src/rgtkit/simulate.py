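"""Synthetic rGT sessions, spike populations and Ct tables.

Every pipeline stage is testable without recorded data: this module
generates (a) 90-trial gambling sessions under the task contingencies
(low-risk lever: 1 pellet at p = 0.9; high-risk lever: 3 pellets at
p = 0.3; 15-s trial limit; 10-s inter-trial interval), driven by a
simple stochastic agent with a low-risk choice probability, an omission
probability and optional drift or a mid-session preference switch;
(b) unit populations as inhomogeneous Poisson processes whose rate is
``baseline_rate`` everywhere and ``baseline_rate * gain`` during the
5 s after each lever press, with gains per response class — planting
cluster structure by giving groups of units shared gain profiles; and
(c) Gaussian replicate Ct tables with a housekeeping gene.

All randomness flows through one explicitly seeded generator; identical
configurations produce bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .behavior import OMISSION, TRIAL_LIMIT_S, Session, Trial
from .ephys import EventSeries, SpikeTrain

__all__ = [
    "TaskContingency",
    "AgentParams",
    "UnitSpec",
    "SimConfig",
    "SimulatedRecording",
    "simulate_session",
    "simulate_spikes",
    "simulate_recording",
    "simulate_ct_table",
    "make_planted_units",
]

#: Post-press modulation window (seconds), mirroring the analysis window.
DEFAULT_MODULATION_WINDOW_S = 5.0


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class TaskContingency:
    """Reward contingencies of the two levers and session geometry."""

    low_risk_prob: float = 0.9
    low_risk_pellets: int = 1
    high_risk_prob: float = 0.3
    high_risk_pellets: int = 3
    n_trials: int = 90
    trial_limit: float = TRIAL_LIMIT_S
    inter_trial: float = 10.0

    def __post_init__(self) -> None:
        _check_prob("low_risk_prob", self.low_risk_prob)
        _check_prob("high_risk_prob", self.high_risk_prob)
        if self.low_risk_pellets < 1 or self.high_risk_pellets < 1:
            raise ValueError("pellet counts must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.trial_limit <= 0 or self.inter_trial < 0:
            raise ValueError("trial_limit must be positive, inter_trial nonnegative")


@dataclass(frozen=True)
class AgentParams:
    """Stochastic agent standing in for rat behavior.

    Each trial is first omitted with probability ``p_omit``; otherwise
    the low-risk lever is chosen with probability ``p_low_choice``
    (clipped to [0, 1] under ``drift``, a per-trial increment). Setting
    ``switch_trial``/``p_low_after`` plants a step change in preference
    at that (1-based) trial, emulating the control-to-pain shift toward
    the large uncertain reward. Latencies are truncated-normal on
    (0, trial_limit].
    """

    p_low_choice: float
    p_omit: float = 0.0
    latency_mean: float = 2.0
    latency_sd: float = 1.0
    drift: float = 0.0
    switch_trial: int | None = None
    p_low_after: float | None = None

    def __post_init__(self) -> None:
        _check_prob("p_low_choice", self.p_low_choice)
        _check_prob("p_omit", self.p_omit)
        if self.latency_sd < 0:
            raise ValueError("latency_sd must be >= 0")
        if (self.switch_trial is None) != (self.p_low_after is None):
            raise ValueError("switch_trial and p_low_after must be set together")
        if self.p_low_after is not None:
            _check_prob("p_low_after", self.p_low_after)
        if self.switch_trial is not None and self.switch_trial < 1:
            raise ValueError("switch_trial is 1-based")


@dataclass(frozen=True)
class UnitSpec:
    """One simulated unit: baseline rate and per-class post-press gains.

    ``gain_by_response`` maps response classes to multiplicative rate
    gains over the post-press window; a gain of 1 means no modulation.
    ``cluster_id`` records the planted cluster membership.
    """

    unit_id: str
    baseline_rate: float
    gain_by_response: Mapping[str, float] = field(default_factory=dict)
    cluster_id: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        for cls, g in self.gain_by_response.items():
            if cls not in {"LR", "LNo", "HR", "HNo"}:
                raise ValueError(f"unknown response class {cls!r}")
            if g < 0:
                raise ValueError("gains must be >= 0")
        object.__setattr__(self, "gain_by_response", dict(self.gain_by_response))


@dataclass(frozen=True)
class SimConfig:
    """Full simulation configuration; the seed is mandatory."""

    contingency: TaskContingency
    agent: AgentParams
    units: tuple[UnitSpec, ...] = ()
    seed: int = 0
    session_padding: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", tuple(self.units))
        if self.session_padding < 10.0:
            raise ValueError(
                "session_padding must be >= 10 s so every PETH window fits"
            )


@dataclass(frozen=True)
class SimulatedRecording:
    """One simulated session with its events and spike population."""

    session: Session
    events: EventSeries
    spike_trains: tuple[SpikeTrain, ...]
    duration: float


def _draw_latency(rng: np.random.Generator, agent: AgentParams, limit: float) -> float:
    if agent.latency_sd == 0.0:
        return float(np.clip(agent.latency_mean, 1e-6, limit))
    a = (0.0 - agent.latency_mean) / agent.latency_sd
    b = (limit - agent.latency_mean) / agent.latency_sd
    return float(
        stats.truncnorm.rvs(
            a, b, loc=agent.latency_mean, scale=agent.latency_sd, random_state=rng
        )
    )


def simulate_session(config: SimConfig) -> tuple[Session, EventSeries]:
    """Simulate one gambling session.

    Returns exactly ``n_trials`` trials; each completed trial carries a
    press event, a risk arm and an outcome drawn from the arm's reward
    probability. Omitted trials consume the trial limit and contribute
    no event. Event times are strictly increasing with spacing of at
    least the inter-trial interval. By convention the low-risk lever is
    on the left.
    """
    cont = config.contingency
    agent = config.agent
    rng = np.random.default_rng(config.seed)
    p_low = agent.p_low_choice
    t = config.session_padding
    trials: list[Trial] = []
    ev_times: list[float] = []
    ev_classes: list[str] = []
    for i in range(1, cont.n_trials + 1):
        if agent.switch_trial is not None and i == agent.switch_trial:
            p_low = agent.p_low_after  # type: ignore[assignment]
        if rng.random() < agent.p_omit:
            trials.append(Trial(index=i, side="none", arm="none", outcome=OMISSION))
            t += cont.trial_limit + cont.inter_trial
        else:
            low = rng.random() < p_low
            latency = _draw_latency(rng, agent, cont.trial_limit)
            press = t + latency
            p_reward = cont.low_risk_prob if low else cont.high_risk_prob
            rewarded = rng.random() < p_reward
            outcome = ("LR" if rewarded else "LNo") if low else ("HR" if rewarded else "HNo")
            trials.append(
                Trial(
                    index=i,
                    side="left" if low else "right",
                    arm="low_risk" if low else "high_risk",
                    outcome=outcome,
                    latency=latency,
                )
            )
            ev_times.append(press)
            ev_classes.append(outcome)
            t = press + cont.inter_trial
        p_low = float(np.clip(p_low + agent.drift, 0.0, 1.0))
    session = Session(trials=tuple(trials), session_label="synthetic", treatment="synthetic")
    events = EventSeries(
        times=np.asarray(ev_times, dtype=float),
        classes=np.asarray(ev_classes, dtype=object),
    )
    return session, events


def _rate_segments(
    events: EventSeries, duration: float, window: float
) -> list[tuple[float, float, str | None]]:
    """Piecewise-constant rate segments (start, end, active class or None).

    When post-press windows overlap, the later event's class takes over
    from its onset (the later event wins).
    """
    segs: list[tuple[float, float, str | None]] = []
    times = events.times
    classes = events.classes
    cur = 0.0
    for j in range(len(times)):
        t_e = float(times[j])
        if t_e > cur:
            segs.append((cur, t_e, None))
        end = min(t_e + window, duration)
        if j + 1 < len(times) and float(times[j + 1]) < end:
            end = float(times[j + 1])
        if end > t_e:
            segs.append((t_e, end, str(classes[j])))
        cur = max(cur, end)
    if cur < duration:
        segs.append((cur, duration, None))
    return segs


def simulate_spikes(
    units: Sequence[UnitSpec],
    events: EventSeries,
    duration: float,
    seed: int,
    window: float = DEFAULT_MODULATION_WINDOW_S,
) -> list[SpikeTrain]:
    """Inhomogeneous-Poisson spike trains locked to the event series.

    The rate of each unit is ``baseline_rate`` everywhere and
    ``baseline_rate * gain_by_response[class]`` during [event,
    event + window] for events of that class. Overlapping windows with
    conflicting gains are resolved in favour of the later event (a
    warning is emitted). Timestamps are sorted and lie in [0, duration];
    a fixed seed reproduces the population bit-identically.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if len(events):
        if float(events.times[0]) < 0:
            raise ValueError("event times must be nonnegative")
        if float(events.times[-1]) + window > duration + 1e-9:
            raise ValueError("duration does not cover the last event window")
        if np.any(np.diff(events.times) < window):
            warnings.warn(
                "overlapping post-event windows: later events override earlier gains",
                stacklevel=2,
            )
    segs = _rate_segments(events, duration, window)
    children = np.random.SeedSequence(seed).spawn(len(units))
    trains: list[SpikeTrain] = []
    for spec, child in zip(units, children):
        rng = np.random.default_rng(child)
        parts: list[np.ndarray] = []
        for start, end, cls in segs:
            gain = 1.0 if cls is None else spec.gain_by_response.get(cls, 1.0)
            rate = spec.baseline_rate * gain
            n = rng.poisson(rate * (end - start))
            if n:
                parts.append(rng.uniform(start, end, size=n))
        ts = np.sort(np.concatenate(parts)) if parts else np.empty(0)
        trains.append(SpikeTrain(unit_id=spec.unit_id, timestamps=ts))
    return trains


def simulate_recording(config: SimConfig) -> SimulatedRecording:
    """Simulate a session and its spike population in one call.

    The recording duration pads the last event (or the session start)
    by ``session_padding`` seconds so every PETH window fits.
    """
    session, events = simulate_session(config)
    last = float(events.times[-1]) if len(events) else config.session_padding
    duration = last + config.session_padding
    trains = simulate_spikes(config.units, events, duration, seed=config.seed + 1)
    return SimulatedRecording(
        session=session,
        events=events,
        spike_trains=tuple(trains),
        duration=duration,
    )


def simulate_ct_table(
    groups: Mapping[str, Mapping[str, tuple[float, float]]],
    n_samples: int,
    n_replicates: int = 3,
    seed: int = 0,
    housekeeping: str = "GAPDH",
):
    """Gaussian replicate Ct table with ``n_samples`` samples per group.

    ``groups`` maps group name -> {gene: (mean Ct, SD)}; every group
    must include the housekeeping gene. Returns a DataFrame with
    columns (sample, group, gene, replicate, ct).
    """
    import pandas as pd

    if n_samples < 1 or n_replicates < 1:
        raise ValueError("n_samples and n_replicates must be >= 1")
    for group, genes in groups.items():
        if housekeeping not in genes:
            raise ValueError(f"group {group!r} lacks the housekeeping gene {housekeeping!r}")
        for gene, (mean, sd) in genes.items():
            if mean <= 0:
                raise ValueError(f"Ct mean for {group}/{gene} must be positive")
            if sd < 0:
                raise ValueError(f"Ct SD for {group}/{gene} must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for group in sorted(groups):
        genes = groups[group]
        for s in range(1, n_samples + 1):
            sample = f"{group}_{s:02d}"
            for gene in sorted(genes):
                mean, sd = genes[gene]
                cts = mean + sd * rng.standard_normal(n_replicates)
                for rep, ct in enumerate(cts, start=1):
                    records.append(
                        {
                            "sample": sample,
                            "group": group,
                            "gene": gene,
                            "replicate": rep,
                            "ct": float(ct),
                        }
                    )
    return pd.DataFrame.from_records(records)


def make_planted_units(
    n_per_cluster: int,
    cluster_gains: Sequence[Mapping[str, float]],
    baseline_rate: float = 8.0,
) -> list[UnitSpec]:
    """Unit population with planted cluster structure.

    ``cluster_gains[c]`` is the shared gain profile of cluster ``c``;
    each cluster gets ``n_per_cluster`` units with that profile.
    """
    units = []
    for c, gains in enumerate(cluster_gains):
        for k in range(n_per_cluster):
            units.append(
                UnitSpec(
                    unit_id=f"c{c}_u{k:02d}",
                    baseline_rate=baseline_rate,
                    gain_by_response=dict(gains),
                    cluster_id=c,
                )
            )
    return units
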