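"""Static figure export: preference curves and trial-by-trial response maps."""

from __future__ import annotations

from .behavior import PreferenceCurve, RESPONSE_MAP_CODES, Session, response_map

#: Display colors per response-map code (low risk green/cyan, high risk
#: red/orange, omissions black).
CODE_COLORS = {
    "low_rewarded": "#1b9e77",
    "low_unrewarded": "#66c2a5",
    "high_rewarded": "#d62728",
    "high_unrewarded": "#ff7f0e",
    "omission": "#000000",
}


def plot_preference_curve(curve: PreferenceCurve, ax=None):
    """Per-block CPI with its 3-point smoothed overlay."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.block_indices, curve.cpi_values, "o-", label="CPI", alpha=0.6)
    ax.plot(curve.block_indices, curve.smoothed, "-", label="smoothed", lw=2)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylim(-1.05, 1.05)
    ax.set_xlabel(f"block ({curve.block_size} trials)")
    ax.set_ylabel("choice preference index")
    ax.legend()
    return ax


def plot_response_map(sessions: list[Session], ax=None):
    """One column per session, one colored cell per trial."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if ax is None:
        _, ax = plt.subplots()
    codes = list(CODE_COLORS)
    cmap = ListedColormap([CODE_COLORS[c] for c in codes])
    import numpy as np

    n_trials = max(len(s) for s in sessions)
    grid = np.full((n_trials, len(sessions)), np.nan)
    for j, s in enumerate(sessions):
        for i, code in enumerate(response_map(s)):
            grid[i, j] = codes.index(code)
    ax.imshow(grid, aspect="auto", cmap=cmap, vmin=0, vmax=len(codes) - 1)
    ax.set_xlabel("session")
    ax.set_ylabel("trial")
    return ax
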