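from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rgtkit.behavior import OMISSION, Session, Trial

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

_SIDE = {"LR": "left", "LNo": "left", "HR": "right", "HNo": "right", OMISSION: "none"}
_ARM = {
    "LR": "low_risk",
    "LNo": "low_risk",
    "HR": "high_risk",
    "HNo": "high_risk",
    OMISSION: "none",
}


def make_session(outcomes, latency: float = 2.0, **kwargs) -> Session:
    """Session from a list of outcome codes, constant latency."""
    trials = tuple(
        Trial(
            index=i,
            side=_SIDE[o],
            arm=_ARM[o],
            outcome=o,
            latency=None if o == OMISSION else latency,
        )
        for i, o in enumerate(outcomes, start=1)
    )
    return Session(trials=trials, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
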