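"""Cohort bookkeeping for the recorded-unit census.

The experiments this pipeline models recorded orbitofrontal single
units from 18 rats split evenly over three systemic treatments:
vehicle (VH), the D2/3-receptor agonist quinpirole (QP) and the
D2-receptor antagonist raclopride (RC). The per-group unit counts are
inputs; the totals and per-animal averages are derived from them.
"""

from __future__ import annotations

from typing import Mapping

__all__ = [
    "RECORDED_UNITS_BY_GROUP",
    "N_RATS",
    "total_recorded_units",
    "mean_units_per_rat",
]

#: Single units recorded per treatment group.
RECORDED_UNITS_BY_GROUP: dict[str, int] = {"VH": 81, "QP": 80, "RC": 78}

#: Animals in the recording cohort (6 per treatment group).
N_RATS: int = 18


def total_recorded_units(counts: Mapping[str, int] | None = None) -> int:
    """Total units across treatment groups."""
    counts = RECORDED_UNITS_BY_GROUP if counts is None else counts
    return int(sum(counts.values()))


def mean_units_per_rat(
    counts: Mapping[str, int] | None = None, n_rats: int = N_RATS
) -> float:
    """Average number of recorded units per animal."""
    if n_rats < 1:
        raise ValueError("n_rats must be >= 1")
    return total_recorded_units(counts) / n_rats
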