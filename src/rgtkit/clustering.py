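"""Hierarchical clustering of unit response profiles.

Each unit is summarized by an activity ratio per response class:

    ratio = mean rate 5 s post-press / mean rate 5 s pre-press,

yielding a units x {LR, HR, LNo, HNo} feature matrix. Units with a
session-wide firing rate below 0.5 Hz are excluded (low-firing units
contribute unstable ratios), as are units with a silent pre-press
baseline (the ratio is undefined) or a missing response class (no
trials of that type; imputing a profile would fabricate a response).

Included units are agglomerated with average linkage on Euclidean
distances. The dendrogram is cut by a gap rule: only merges whose
linkage distance is below a threshold (default 3) may be applied, and
among the candidate cuts the one exploiting the largest increase
between consecutive merge distances wins (including the jump from the
last sub-threshold merge to the first merge above threshold). If no
merge lies below the threshold every unit is a singleton; if no
strictly positive gap exists (an equal-distance regime) all
sub-threshold merges are applied; tied gaps resolve to the earliest
cut.

Cluster response magnitude is the mean post-press Z over member units,
per class; the flexibility score counts how many of the four classes a
cluster encodes at |mean Z| >= 1.96 (the two-sided 5% normal bound),
quantifying a cluster's capacity to represent multiple task outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import pdist

from .ephys import PETH, ZScoredPETH, mean_rate_in_window

__all__ = [
    "RESPONSE_CLASSES",
    "ClusterConfig",
    "FeatureMatrix",
    "ClusterTree",
    "ClusterResult",
    "build_features",
    "exclude_low_firing",
    "hierarchical_cluster",
    "cut_tree",
    "cluster_mean_z",
    "flexibility_score",
]

#: Column order of the feature matrix.
RESPONSE_CLASSES = ("LR", "HR", "LNo", "HNo")


@dataclass(frozen=True)
class ClusterConfig:
    """Clustering parameters; defaults follow the analysis they reproduce."""

    metric: str = "euclidean"
    linkage: str = "average"
    cut_threshold: float = 3.0
    min_rate_hz: float = 0.5
    row_standardize: bool = False

    def __post_init__(self) -> None:
        if self.cut_threshold <= 0:
            raise ValueError("cut_threshold must be positive")
        if self.min_rate_hz < 0:
            raise ValueError("min_rate_hz must be nonnegative")


@dataclass(frozen=True)
class FeatureMatrix:
    """Units x response-class activity ratios.

    ``values`` rows are unit ids, columns ``RESPONSE_CLASSES``; a
    missing class is NaN (recorded, never imputed). ``excluded`` maps
    unit id -> reason for units dropped during feature construction.
    """

    values: pd.DataFrame
    excluded: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ClusterTree:
    """Average-linkage merge tree over the included units.

    ``merges`` is in SciPy linkage format (left, right, distance, size);
    leaf i corresponds to ``units[i]``. ``excluded`` maps unit ids
    dropped before clustering to their reason.
    """

    merges: np.ndarray
    units: tuple[str, ...]
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def distances(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass(frozen=True)
class ClusterResult:
    """Labels, per-cluster mean Z and flexibility for one session."""

    tree: ClusterTree
    labels: dict[str, int]
    cluster_mean_z: pd.DataFrame
    flexibility: pd.Series
    excluded: dict[str, str]


def build_features(
    peths: Mapping[str, Mapping[str, PETH]],
    window: float = 5.0,
) -> FeatureMatrix:
    """Activity-ratio feature matrix from per-unit, per-class raw PETHs.

    The ratio uses the mean PETH rate over [0, window) versus
    [-window, 0). A silent pre-press baseline with any post-press
    activity makes the ratio infinite: the unit is excluded with reason
    ``zero_baseline``. A class with no events is recorded as NaN.
    """
    if not peths:
        raise ValueError("no units provided")
    rows: dict[str, dict[str, float]] = {}
    excluded: dict[str, str] = {}
    for unit_id, by_class in peths.items():
        row: dict[str, float] = {}
        bad_baseline = False
        for cls in RESPONSE_CLASSES:
            peth = by_class.get(cls)
            if peth is None or peth.is_empty:
                row[cls] = math.nan
                continue
            pre = mean_rate_in_window(peth, -window, 0.0)
            post = mean_rate_in_window(peth, 0.0, window)
            if pre == 0.0:
                bad_baseline = True
                break
            row[cls] = post / pre
        if bad_baseline:
            excluded[unit_id] = "zero_baseline"
        else:
            rows[unit_id] = row
    values = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    values = values.reindex(columns=list(RESPONSE_CLASSES))
    return FeatureMatrix(values=values, excluded=excluded)


def exclude_low_firing(
    rates: Mapping[str, float], min_rate_hz: float = 0.5
) -> tuple[list[str], list[tuple[str, float]]]:
    """Split units by session-wide firing rate at a strict threshold.

    Kept iff rate >= ``min_rate_hz`` (units strictly below are
    excluded). Returns (kept unit ids, [(excluded unit id, rate), ...]).
    """
    kept = [u for u, r in rates.items() if r >= min_rate_hz]
    excluded = [(u, float(r)) for u, r in rates.items() if r < min_rate_hz]
    return kept, excluded


def hierarchical_cluster(
    features: FeatureMatrix, config: ClusterConfig = ClusterConfig()
) -> ClusterTree:
    """Agglomerative merge tree over units with complete feature rows.

    Units with any missing class are excluded with reason
    ``missing_class``. Requires at least two clusterable units.
    """
    values = features.values
    excluded = dict(features.excluded)
    complete = values.dropna(axis=0)
    for unit_id in values.index.difference(complete.index):
        excluded[str(unit_id)] = "missing_class"
    if complete.shape[0] < 2:
        raise ValueError(
            f"clustering needs >= 2 units with complete profiles; "
            f"got {complete.shape[0]}"
        )
    X = complete.to_numpy(dtype=float)
    if config.row_standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    merges = _scipy_linkage(pdist(X, metric=config.metric), method=config.linkage)
    return ClusterTree(
        merges=merges,
        units=tuple(str(u) for u in complete.index),
        excluded=excluded,
    )


def _labels_after_merges(merges: np.ndarray, n_leaves: int, n_apply: int) -> np.ndarray:
    """Flat labels after applying the first ``n_apply`` merge rows.

    Labels are 0-based, ordered by each cluster's smallest leaf index,
    so permuting input rows only renames clusters.
    """
    members: dict[int, list[int]] = {i: [i] for i in range(n_leaves)}
    for i in range(n_apply):
        a, b = int(merges[i, 0]), int(merges[i, 1])
        members[n_leaves + i] = members.pop(a) + members.pop(b)
    labels = np.empty(n_leaves, dtype=int)
    order = sorted(members.values(), key=min)
    for lab, leaves in enumerate(order):
        labels[leaves] = lab
    return labels


def cut_tree(tree: ClusterTree, cut_threshold: float = 3.0) -> dict[str, int]:
    """Cut the dendrogram by the largest-gap rule below a linkage threshold.

    See the module docstring for the rule. Returns unit id -> 0-based
    cluster label.
    """
    merges = tree.merges
    n_leaves = len(tree.units)
    d = merges[:, 2]
    k = int(np.sum(d < cut_threshold))
    if k == 0:
        n_apply = 0
    else:
        # candidate cuts apply the first m merges (m <= k); the gap a cut
        # exploits is the distance increase opened by the next merge, so the
        # jump from the last sub-threshold merge to the first supra-threshold
        # one also counts. Rounding-level differences are no gap; ties
        # resolve to the earliest cut; a gapless regime applies all k merges.
        tol = 1e-9 * max(1.0, float(d.max()))
        n_apply, best_gap = k, tol
        for m in range(1, k + 1):
            if m < d.size:
                gap = float(d[m] - d[m - 1])
                if gap > best_gap:
                    best_gap, n_apply = gap, m
    labels = _labels_after_merges(merges, n_leaves, n_apply)
    return {u: int(lab) for u, lab in zip(tree.units, labels)}


def cluster_mean_z(
    labels: Mapping[str, int],
    zpeths: Mapping[str, Mapping[str, ZScoredPETH]],
    window: tuple[float, float] = (0.0, 5.0),
) -> pd.DataFrame:
    """Per-cluster, per-class mean post-press Z.

    Each unit contributes its mean Z over the post-press window; the
    cluster value is the mean over member units. Degenerate-baseline or
    missing entries are skipped; a cluster with no valid unit for a
    class is NaN (undefined marker).
    """
    clusters = sorted(set(labels.values()))
    table = pd.DataFrame(index=clusters, columns=list(RESPONSE_CLASSES), dtype=float)
    for cl in clusters:
        units = [u for u, lab in labels.items() if lab == cl]
        for cls in RESPONSE_CLASSES:
            vals = []
            for u in units:
                zp = zpeths.get(u, {}).get(cls)
                if zp is None or zp.degenerate:
                    continue
                vals.append(zp.mean_z_in_window(*window))
            table.loc[cl, cls] = float(np.mean(vals)) if vals else math.nan
    table.index.name = "cluster"
    return table


def flexibility_score(
    mean_z_row: Mapping[str, float] | pd.Series, z_threshold: float = 1.96
) -> int:
    """Number of response classes a cluster encodes at |mean Z| >= threshold.

    Missing (NaN) classes never count. At threshold 0 this equals the
    number of non-missing classes.
    """
    count = 0
    for cls in RESPONSE_CLASSES:
        v = mean_z_row.get(cls, math.nan) if hasattr(mean_z_row, "get") else mean_z_row[cls]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if abs(float(v)) >= z_threshold:
            count += 1
    return count
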