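"""Diagram metrics: exact bottleneck distance.

Binary search over the candidate distance set with a bipartite matching
feasibility test (Hopcroft-Karp via scipy).  Points may be matched to each
other or to the diagonal; the distance is the L-infinity cost of the best
matching.  Intended for the small diagrams that arise in tests.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching


def _pairwise_linf(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.abs(a[:, None, :] - b[None, :, :]).max(axis=2)


def bottleneck_distance(pts_a: np.ndarray, pts_b: np.ndarray) -> float:
    """Bottleneck distance between two diagrams given as (n, 2) arrays of
    (birth, death) points."""
    a = np.asarray(pts_a, float).reshape(-1, 2)
    b = np.asarray(pts_b, float).reshape(-1, 2)
    if len(a) == 0 and len(b) == 0:
        return 0.0
    diag_a = (a[:, 1] - a[:, 0]) / 2.0 if len(a) else np.empty(0)
    diag_b = (b[:, 1] - b[:, 0]) / 2.0 if len(b) else np.empty(0)
    if len(a) == 0:
        return float(diag_b.max())
    if len(b) == 0:
        return float(diag_a.max())

    cross = _pairwise_linf(a, b)
    candidates = np.unique(np.concatenate(
        [cross.ravel(), diag_a, diag_b, [0.0]]))

    def feasible(eps: float) -> bool:
        # bipartite graph: A points + B-diagonal slots vs B points + A-diagonal
        # slots; a point may match a point within eps or its own diagonal
        # projection within eps; diagonal slots match each other freely.
        na, nb = len(a), len(b)
        rows, cols = [], []
        ok = cross <= eps
        r, c = np.nonzero(ok)
        rows.extend(r)
        cols.extend(c)
        for i in range(na):  # a_i to its diagonal (column nb + i)
            if diag_a[i] <= eps:
                rows.append(i)
                cols.append(nb + i)
        for j in range(nb):  # diagonal row na + j to b_j
            if diag_b[j] <= eps:
                rows.append(na + j)
                cols.append(j)
        # diagonal rows absorb diagonal columns freely
        jj, ii = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
        rows.extend((na + jj.ravel()).tolist())
        cols.extend((nb + ii.ravel()).tolist())
        m = csr_matrix((np.ones(len(rows), dtype=np.int8),
                        (np.array(rows), np.array(cols))),
                       shape=(na + nb, na + nb))
        match = maximum_bipartite_matching(m, perm_type="column")
        return int((match >= 0).sum()) == na + nb

    lo, hi = 0, len(candidates) - 1
    if feasible(candidates[lo]):
        return float(candidates[lo])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if feasible(candidates[mid]):
            hi = mid
        else:
            lo = mid
    return float(candidates[hi])
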