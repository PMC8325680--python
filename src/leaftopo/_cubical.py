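"""Union-find kernels for 2-D cubical sublevel-set persistence.

The complex is the V-construction on the pixel grid: pixels are vertices,
edges join 4-neighbours, squares fill 2x2 blocks, and every cell carries the
maximum value of its vertices.  Degree-0 classes are therefore 4-connected
sublevel components; degree-1 classes are computed by the planar duality
between holes of the sublevel set and 8-connected components of the
superlevel complement (including the unbounded outside region).

Both kernels emit raw (birth, death) pairs; zero-persistence filtering and
essential-class clamping happen in the caller.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every caller
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:
        nxt = parent[i]
        parent[i] = root
        i = nxt
    return root


@njit(cache=True)
def pairs_h0(values, order, h, w):
    """Degree-0 pairs of the sublevel filtration, 4-connectivity.

    ``values`` is the flattened grid (+inf on background), ``order`` the
    indices of finite pixels sorted by (value, index) ascending.  Returns
    (births, deaths, essential) where essential deaths are +inf (clamped by
    the caller).  Zero-persistence pairs are not emitted.
    """
    n = h * w
    parent = np.full(n, -1, dtype=np.int64)
    comp_birth = np.empty(n, dtype=np.float64)
    # rank of the pixel in the processing order, used to break birth ties so
    # the elder rule is deterministic
    rank = np.full(n, -1, dtype=np.int64)

    births = np.empty(order.shape[0], dtype=np.float64)
    deaths = np.empty(order.shape[0], dtype=np.float64)
    m = 0
    for k in range(order.shape[0]):
        idx = order[k]
        parent[idx] = idx
        comp_birth[idx] = values[idx]
        rank[idx] = k
        v = values[idx]
        r = idx
        col = idx % w
        for t in range(4):
            if t == 0:
                nb = idx - w
                ok = nb >= 0
            elif t == 1:
                nb = idx + w
                ok = nb < n
            elif t == 2:
                nb = idx - 1
                ok = col > 0
            else:
                nb = idx + 1
                ok = col < w - 1
            if not ok or parent[nb] < 0:
                continue
            r1 = _find(parent, r)
            r2 = _find(parent, nb)
            if r1 == r2:
                continue
            # elder rule: the component with the smaller birth survives;
            # ties broken by earlier creation
            if (comp_birth[r2] < comp_birth[r1]) or (
                comp_birth[r2] == comp_birth[r1] and rank[r2] < rank[r1]
            ):
                elder, young = r2, r1
            else:
                elder, young = r1, r2
            if v > comp_birth[young]:
                births[m] = comp_birth[young]
                deaths[m] = v
                m += 1
            parent[young] = elder
            r = elder

    # surviving roots are essential degree-0 classes
    n_markers = 0
    for k in range(order.shape[0]):
        idx = order[k]
        if _find(parent, idx) == idx:
            births[m] = comp_birth[idx]
            deaths[m] = np.inf
            m += 1
            n_markers += 1
    return births[:m], deaths[:m]


@njit(cache=True)
def pairs_h1(values, order_desc, h, w):
    """Degree-1 pairs of the sublevel filtration via complement duality.

    Pixels (background +inf included) are activated in decreasing value
    order with 8-connectivity; a virtual outside node (index h*w) represents
    the unbounded region and is attached to every border pixel.  A merge at
    value v killing a component born (max value) b corresponds to a hole of
    the sublevel set born at v and dying at b.  Merges between two
    components of infinite birth yield essential holes (death +inf here,
    clamped by the caller).
    """
    n = h * w
    outside = n
    parent = np.full(n + 1, -1, dtype=np.int64)
    comp_birth = np.empty(n + 1, dtype=np.float64)
    has_outside = np.zeros(n + 1, dtype=np.uint8)
    rank = np.full(n + 1, -1, dtype=np.int64)

    parent[outside] = outside
    comp_birth[outside] = np.inf
    has_outside[outside] = 1
    rank[outside] = -1

    births = np.empty(order_desc.shape[0] + 1, dtype=np.float64)
    deaths = np.empty(order_desc.shape[0] + 1, dtype=np.float64)
    m = 0
    for k in range(order_desc.shape[0]):
        idx = order_desc[k]
        parent[idx] = idx
        comp_birth[idx] = values[idx]
        rank[idx] = k
        v = values[idx]
        row = idx // w
        col = idx % w
        r = idx
        # border pixels touch the unbounded outside region
        if row == 0 or row == h - 1 or col == 0 or col == w - 1:
            r = _union_h1(parent, comp_birth, has_outside, rank, r, outside, v,
                          births, deaths, m)
            if r < 0:
                r = -r - 1
                m += 1
        for dr in range(-1, 2):
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                r2c = row + dr
                c2 = col + dc
                if r2c < 0 or r2c >= h or c2 < 0 or c2 >= w:
                    continue
                nb = r2c * w + c2
                if parent[nb] < 0:
                    continue
                r = _union_h1(parent, comp_birth, has_outside, rank, r, nb, v,
                              births, deaths, m)
                if r < 0:
                    r = -r - 1
                    m += 1
    return births[:m], deaths[:m]


@njit(cache=True)
def _union_h1(parent, comp_birth, has_outside, rank, a, b, v, births, deaths, m):
    """Union helper; returns the surviving root, negated-minus-one if a pair
    was recorded at slot m."""
    r1 = _find(parent, a)
    r2 = _find(parent, b)
    if r1 == r2:
        return r1
    b1 = comp_birth[r1]
    b2 = comp_birth[r2]
    # elder = larger superlevel birth; ties broken in favour of the outside
    # component, then earlier activation
    if b2 > b1:
        elder, young = r2, r1
    elif b1 > b2:
        elder, young = r1, r2
    elif has_outside[r2] and not has_outside[r1]:
        elder, young = r2, r1
    elif has_outside[r1] and not has_outside[r2]:
        elder, young = r1, r2
    elif rank[r2] < rank[r1]:
        elder, young = r2, r1
    else:
        elder, young = r1, r2
    recorded = False
    yb = comp_birth[young]
    if yb > v:
        if np.isinf(yb):
            # two infinite-birth complement regions separate at v: a hole
            # enclosing background is born and never dies
            births[m] = v
            deaths[m] = np.inf
        else:
            births[m] = v
            deaths[m] = yb
        recorded = True
    parent[young] = elder
    if has_outside[young]:
        has_outside[elder] = 1
    if recorded:
        return -elder - 1
    return elder
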