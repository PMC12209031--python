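"""Independent exhaustive average-linkage oracle used only by tests.

Recomputes the full merge tree by brute force: at every step the
inter-cluster distance is the mean of all pairwise point distances, the
minimum is found by exhaustive search, and ties break to the lowest
pair of cluster ids. Deliberately naive (O(n^4)) and independent of the
library's clustering path.
"""

from __future__ import annotations

import numpy as np


def brute_force_average_linkage(X: np.ndarray) -> np.ndarray:
    """Merge tree in (left, right, distance, size) rows over leaves of X."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(members) > 1:
        ids = sorted(members)
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                d = float(
                    np.mean(
                        [
                            np.linalg.norm(X[i] - X[j])
                            for i in members[a]
                            for j in members[b]
                        ]
                    )
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merges.append([a, b, d, len(members[a]) + len(members[b])])
        members[next_id] = members.pop(a) + members.pop(b)
        next_id += 1
    return np.asarray(merges, dtype=float)


def canonical_merges(Z: np.ndarray, n_leaves: int) -> list[tuple[float, frozenset]]:
    """Order-insensitive canonical form: (distance, merged leaf set) rows.

    Two merge trees are equivalent iff their canonical forms match row
    by row (distances to tolerance, leaf sets exactly).
    """
    members = {i: frozenset([i]) for i in range(n_leaves)}
    rows = []
    for k in range(Z.shape[0]):
        a, b = int(Z[k, 0]), int(Z[k, 1])
        merged = members[a] | members[b]
        members[n_leaves + k] = merged
        rows.append((float(Z[k, 2]), merged))
    return sorted(rows, key=lambda t: (t[0], sorted(t[1])))


def trees_equal(Z1: np.ndarray, Z2: np.ndarray, n_leaves: int, atol: float = 1e-12) -> bool:
    c1 = canonical_merges(Z1, n_leaves)
    c2 = canonical_merges(Z2, n_leaves)
    if len(c1) != len(c2):
        return False
    for (d1, m1), (d2, m2) in zip(c1, c2):
        if m1 != m2 or abs(d1 - d2) > atol:
            return False
    return True
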