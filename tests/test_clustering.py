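import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracle_linkage import brute_force_average_linkage, trees_equal
from rgtkit.clustering import (
    ClusterConfig,
    ClusterTree,
    FeatureMatrix,
    RESPONSE_CLASSES,
    build_features,
    cluster_mean_z,
    cut_tree,
    exclude_low_firing,
    flexibility_score,
    hierarchical_cluster,
)
from rgtkit.ephys import PETH, ZScoredPETH


def _fm(array, units=None):
    array = np.asarray(array, dtype=float)
    units = units or [f"u{i}" for i in range(array.shape[0])]
    return FeatureMatrix(
        values=pd.DataFrame(array, index=units, columns=list(RESPONSE_CLASSES)[: array.shape[1]])
    )


def _fm4(array, units=None):
    """Pad 1-D feature rows to the 4 response-class columns with zeros."""
    array = np.asarray(array, dtype=float)
    if array.ndim == 1:
        array = array[:, None]
    padded = np.zeros((array.shape[0], 4))
    padded[:, : array.shape[1]] = array
    return _fm(padded, units=units)


def _peth(pre_rate, post_rate, unit="u", cls="HR"):
    rates = np.concatenate([np.full(100, float(pre_rate)), np.full(200, float(post_rate))])
    edges = -5.0 + 0.05 * np.arange(301)
    return PETH(bin_edges=edges, mean_rate=rates, n_events=10, unit_id=unit, response_class=cls)


def _zp(mean_post_z, unit="u", cls="HR", degenerate=False):
    z = np.concatenate([np.zeros(100), np.full(200, float(mean_post_z))])
    edges = -5.0 + 0.05 * np.arange(301)
    return ZScoredPETH(
        bin_edges=edges, z=z, baseline_mean=5.0, baseline_sd=1.0,
        unit_id=unit, response_class=cls, degenerate=degenerate,
    )


class TestBuildFeatures:
    def test_identical_pre_post_gives_unit_ratio(self):
        peths = {"u0": {cls: _peth(6.0, 6.0, cls=cls) for cls in RESPONSE_CLASSES}}
        fm = build_features(peths)
        assert np.allclose(fm.values.loc["u0"], 1.0)

    def test_ratio_reflects_modulation(self):
        peths = {"u0": {"HR": _peth(5.0, 15.0), "LR": _peth(5.0, 2.5, cls="LR")}}
        fm = build_features(peths)
        assert fm.values.loc["u0", "HR"] == pytest.approx(3.0)
        assert fm.values.loc["u0", "LR"] == pytest.approx(0.5)
        assert math.isnan(fm.values.loc["u0", "LNo"])

    def test_silent_baseline_excluded_with_reason(self):
        peths = {
            "good": {cls: _peth(5.0, 5.0, cls=cls) for cls in RESPONSE_CLASSES},
            "silent": {"HR": _peth(0.0, 3.0, unit="silent")},
        }
        fm = build_features(peths)
        assert fm.excluded == {"silent": "zero_baseline"}
        assert list(fm.values.index) == ["good"]

    def test_no_units_rejected(self):
        with pytest.raises(ValueError):
            build_features({})


class TestExcludeLowFiring:
    def test_boundary_is_kept_if_equal(self):
        kept, excluded = exclude_low_firing({"a": 0.4, "b": 0.5, "c": 2.0})
        assert sorted(kept) == ["b", "c"]
        assert excluded == [("a", 0.4)]

    def test_zero_threshold_keeps_all(self):
        kept, excluded = exclude_low_firing({"a": 0.0, "b": 0.1}, min_rate_hz=0.0)
        assert sorted(kept) == ["a", "b"] and not excluded

    def test_all_below_threshold_then_clustering_refuses(self):
        kept, _ = exclude_low_firing({"a": 0.1, "b": 0.2})
        assert kept == []
        with pytest.raises(ValueError, match=">= 2 units"):
            hierarchical_cluster(_fm4(np.empty((0, 1))))

    @given(st.lists(st.floats(min_value=0, max_value=10), min_size=1, max_size=30))
    @settings(max_examples=30)
    def test_exclusion_monotone_in_threshold(self, rates):
        units = {f"u{i}": r for i, r in enumerate(rates)}
        kept_low, _ = exclude_low_firing(units, min_rate_hz=0.5)
        kept_high, _ = exclude_low_firing(units, min_rate_hz=1.0)
        assert set(kept_high) <= set(kept_low)


class TestHierarchicalCluster:
    def test_identical_rows_merge_at_zero(self):
        tree = hierarchical_cluster(_fm4(np.array([[1.0, 2.0], [1.0, 2.0]])))
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_four_points_on_a_line(self):
        """{0,1,10,11}: pairs merge at 1, final average-linkage merge at 10."""
        tree = hierarchical_cluster(_fm4(np.array([0.0, 1.0, 10.0, 11.0])))
        d = np.sort(tree.distances)
        assert d[0] == pytest.approx(1.0) and d[1] == pytest.approx(1.0)
        assert d[2] == pytest.approx(10.0)  # mean of |0-10|,|0-11|,|1-10|,|1-11|

    @pytest.mark.parametrize("n", [2, 3, 5, 7])
    def test_matches_exhaustive_oracle(self, n, rng):
        for _ in range(10):
            X = rng.normal(size=(n, 4))
            tree = hierarchical_cluster(_fm(X))
            oracle = brute_force_average_linkage(X)
            assert trees_equal(tree.merges, oracle, n)

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(_fm4(np.array([1.0])))

    def test_missing_class_excluded_with_reason(self):
        values = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0], [2.0, 2.0, np.nan, 2.0], [3.0, 3.0, 3.0, 3.0]],
            index=["a", "b", "c"],
            columns=list(RESPONSE_CLASSES),
        )
        tree = hierarchical_cluster(FeatureMatrix(values=values))
        assert tree.excluded == {"b": "missing_class"}
        assert tree.units == ("a", "c")

    def test_permutation_invariance(self, rng):
        X = rng.normal(size=(8, 4))
        units = [f"u{i}" for i in range(8)]
        labels1 = cut_tree(hierarchical_cluster(_fm(X, units)), cut_threshold=1.5)
        perm = rng.permutation(8)
        labels2 = cut_tree(
            hierarchical_cluster(_fm(X[perm], [units[i] for i in perm])), cut_threshold=1.5
        )
        # identical partitions up to label renaming
        part1 = {}
        for u, l in labels1.items():
            part1.setdefault(l, set()).add(u)
        part2 = {}
        for u, l in labels2.items():
            part2.setdefault(l, set()).add(u)
        assert set(map(frozenset, part1.values())) == set(map(frozenset, part2.values()))


class TestCutTree:
    def _tree(self, merges, n_units):
        return ClusterTree(
            merges=np.asarray(merges, dtype=float),
            units=tuple(f"u{i}" for i in range(n_units)),
        )

    def test_largest_gap_before_last_merge(self):
        """Merge distances {0.1, 0.12, 2.9}: cut below the 2.9 merge."""
        tree = self._tree([[0, 1, 0.1, 2], [2, 3, 0.12, 2], [4, 5, 2.9, 4]], 4)
        labels = cut_tree(tree, cut_threshold=3.0)
        assert labels == {"u0": 0, "u1": 0, "u2": 1, "u3": 1}

    def test_equidistant_regime_collapses_to_one_cluster(self):
        """All pairwise distances equal: gapless, one cluster."""
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, math.sqrt(3) / 2]])
        tree = hierarchical_cluster(_fm4(X))
        labels = cut_tree(tree, cut_threshold=3.0)
        assert set(labels.values()) == {0}

    def test_no_merge_below_threshold_gives_singletons(self):
        tree = self._tree([[0, 1, 5.0, 2], [2, 3, 7.0, 2], [4, 5, 9.0, 4]], 4)
        labels = cut_tree(tree, cut_threshold=3.0)
        assert sorted(labels.values()) == [0, 1, 2, 3]

    def test_tied_gaps_cut_at_earliest(self):
        # gaps of 1.0 after the first and after the second merge
        tree = self._tree([[0, 1, 0.5, 2], [2, 3, 1.5, 2], [4, 5, 2.5, 4]], 4)
        labels = cut_tree(tree, cut_threshold=3.0)
        assert sorted(labels.values()) == [0, 0, 1, 2]

    def test_above_threshold_merges_never_applied(self):
        tree = self._tree([[0, 1, 0.5, 2], [2, 3, 0.6, 2], [4, 5, 10.0, 4]], 4)
        labels = cut_tree(tree, cut_threshold=3.0)
        assert labels == {"u0": 0, "u1": 0, "u2": 1, "u3": 1}


class TestClusterSummaries:
    def test_single_unit_cluster_identity(self):
        labels = {"u0": 0}
        zp = {"u0": {"HR": _zp(2.5, unit="u0")}}
        table = cluster_mean_z(labels, zp)
        assert table.loc[0, "HR"] == pytest.approx(2.5)
        assert math.isnan(table.loc[0, "LR"])

    def test_symmetric_pair_averages_to_zero(self):
        labels = {"a": 0, "b": 0}
        zp = {"a": {"HR": _zp(2.0, unit="a")}, "b": {"HR": _zp(-2.0, unit="b")}}
        assert cluster_mean_z(labels, zp).loc[0, "HR"] == pytest.approx(0.0)

    def test_degenerate_units_skipped(self):
        labels = {"a": 0, "b": 0}
        zp = {
            "a": {"HR": _zp(3.0, unit="a")},
            "b": {"HR": _zp(99.0, unit="b", degenerate=True)},
        }
        assert cluster_mean_z(labels, zp).loc[0, "HR"] == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "row, expected",
        [
            ({"LR": 0.0, "HR": 0.0, "LNo": 0.0, "HNo": 0.0}, 0),
            ({"LR": 2.5, "HR": 2.1, "LNo": -3.0, "HNo": 0.1}, 3),
            ({"LR": 1.96, "HR": -1.96, "LNo": 1.95, "HNo": math.nan}, 2),
        ],
    )
    def test_flexibility_counting(self, row, expected):
        assert flexibility_score(row) == expected

    def test_flexibility_zero_threshold_counts_non_missing(self):
        row = {"LR": 0.0, "HR": 1.0, "LNo": math.nan, "HNo": -0.5}
        assert flexibility_score(row, z_threshold=0.0) == 3
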