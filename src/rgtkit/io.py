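"""CSV interchange schemas (UTF-8, comma-separated, header row).

Schemas:
- trials:  trial, side, arm, outcome, omission, latency_s
- events:  press_time_s, outcome
- spikes:  unit_id, time_s
- ct:      sample, group, gene, replicate, ct
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import OMISSION, Session, Trial
from .ephys import EventSeries, SpikeTrain

__all__ = [
    "session_to_frame",
    "session_from_frame",
    "write_trials",
    "read_trials",
    "write_events",
    "read_events",
    "write_spikes",
    "read_spikes",
    "write_ct",
    "read_ct",
]


def session_to_frame(session: Session) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial": [t.index for t in session.trials],
            "side": [t.side for t in session.trials],
            "arm": [t.arm for t in session.trials],
            "outcome": [t.outcome for t in session.trials],
            "omission": [int(t.is_omission) for t in session.trials],
            "latency_s": [t.latency if t.latency is not None else math.nan for t in session.trials],
        }
    )


def session_from_frame(
    frame: pd.DataFrame, session_label: str = "control", treatment: str = "VH"
) -> Session:
    trials = []
    for row in frame.itertuples(index=False):
        lat = None if row.outcome == OMISSION else float(row.latency_s)
        trials.append(
            Trial(
                index=int(row.trial),
                side=str(row.side),
                arm=str(row.arm),
                outcome=str(row.outcome),
                latency=lat,
            )
        )
    return Session(trials=tuple(trials), session_label=session_label, treatment=treatment)


def write_trials(session: Session, path: str | Path) -> None:
    session_to_frame(session).to_csv(path, index=False, float_format="%.17g")


def read_trials(path: str | Path, **kwargs) -> Session:
    return session_from_frame(pd.read_csv(path, float_precision="round_trip"), **kwargs)


def write_events(events: EventSeries, path: str | Path) -> None:
    pd.DataFrame({"press_time_s": events.times, "outcome": events.classes}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_events(path: str | Path) -> EventSeries:
    frame = pd.read_csv(path, float_precision="round_trip")
    return EventSeries(
        times=frame["press_time_s"].to_numpy(dtype=float),
        classes=frame["outcome"].to_numpy(dtype=object),
    )


def write_spikes(trains: list[SpikeTrain] | tuple[SpikeTrain, ...], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"unit_id": tr.unit_id, "time_s": tr.timestamps}) for tr in trains
    ]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["unit_id", "time_s"]
    )
    out.to_csv(path, index=False, float_format="%.17g")


def read_spikes(path: str | Path) -> list[SpikeTrain]:
    frame = pd.read_csv(path, float_precision="round_trip")
    trains = []
    for unit_id, grp in frame.groupby("unit_id", sort=True):
        trains.append(
            SpikeTrain(unit_id=str(unit_id), timestamps=np.sort(grp["time_s"].to_numpy(dtype=float)))
        )
    return trains


def write_ct(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.17g")


def read_ct(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
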