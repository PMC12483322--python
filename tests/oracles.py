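"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths (and libraries) they validate:
UPGMA by direct O(n^3) agglomeration on the raw distance matrix, alignment by
exhaustive search over all circular shifts.
"""

from __future__ import annotations

import numpy as np


def brute_force_upgma(dist: np.ndarray) -> list[tuple[frozenset, float]]:
    """Average-linkage agglomeration from first principles.

    Returns the merge list as ``(leaf-index set, merge height)`` pairs.
    Cluster-to-cluster distance is the unweighted mean of all cross pairs,
    computed fresh from the original matrix at every step.
    """
    n = dist.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((merged, d))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def linkage_merges(z: np.ndarray) -> list[tuple[frozenset, float]]:
    """Convert a scipy linkage matrix to the same merge-list representation."""
    n = z.shape[0] + 1
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for i, (a, b, h, _c) in enumerate(z):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        merges.append((merged, float(h)))
    return merges


def brute_force_align_shift(polarity: np.ndarray, center: int) -> int:
    """Circular shift maximizing the (3-smoothed) polarity value at ``center``.

    Exhaustive over all N shifts; ties resolved toward the shift that an
    argmax at the lowest peak index would give.
    """
    pol = np.asarray(polarity, dtype=float)
    n = pol.size
    sm = (np.roll(pol, 1) + pol + np.roll(pol, -1)) / 3.0
    best_shift, best_val = None, -np.inf
    for k in range(n):  # k = candidate peak index
        if sm[k] > best_val:
            best_val = sm[k]
            best_shift = (center - k) % n
    return best_shift
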