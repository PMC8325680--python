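"""Independent brute-force persistence oracle.

Computes the persistence diagram of a small filtration grid by explicit
boundary-matrix reduction over Z/2 on the full V-construction cubical
complex (vertices = pixels, edges = 4-adjacent pairs, squares = 2x2
blocks; every cell takes the maximum value of its vertices).  It shares no
code with the union-find implementation in :mod:`leaftopo.persistence` and
is cubic in the cell count, hence the hard size cap.
"""

from __future__ import annotations

import numpy as np

from .persistence import FiltrationGrid, PersistenceDiagram

MAX_SIDE = 12


def persistence_oracle(grid: FiltrationGrid) -> PersistenceDiagram:
    """Diagram by naive boundary-matrix reduction; grids at most 12x12."""
    vals = grid.values
    h, w = vals.shape
    if h > MAX_SIDE or w > MAX_SIDE:
        raise ValueError(f"oracle refuses grids larger than {MAX_SIDE}x{MAX_SIDE}")

    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("all-background grid")

    # cells: (value, dim, vertex-tuple); vertices are flat pixel indices
    cells: list[tuple[float, int, tuple[int, ...]]] = []
    vid = {}
    for r in range(h):
        for c in range(w):
            if finite[r, c]:
                vid[(r, c)] = len(cells)
                cells.append((float(vals[r, c]), 0, (r * w + c,)))
    edges = {}
    for r in range(h):
        for c in range(w):
            if not finite[r, c]:
                continue
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 < h and c2 < w and finite[r2, c2]:
                    val = max(float(vals[r, c]), float(vals[r2, c2]))
                    edges[((r, c), (r2, c2))] = len(cells)
                    cells.append((val, 1, (r * w + c, r2 * w + c2)))
    squares = []
    for r in range(h - 1):
        for c in range(w - 1):
            corners = [(r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1)]
            if all(finite[p] for p in corners):
                val = max(float(vals[p]) for p in corners)
                squares.append((val, corners))

    # boundaries in terms of cell list positions
    boundaries: list[list[int]] = [[] for _ in cells]
    for (a, b), ei in edges.items():
        boundaries[ei] = [vid[a], vid[b]]
    for val, corners in squares:
        (r, c) = corners[0]
        e = [
            edges[((r, c), (r, c + 1))],
            edges[((r, c), (r + 1, c))],
            edges[((r, c + 1), (r + 1, c + 1))],
            edges[((r + 1, c), (r + 1, c + 1))],
        ]
        boundaries.append(e)
        cells.append((val, 2, ()))

    n = len(cells)
    # filtration order: by (value, dim, position) so faces precede cofaces
    order = sorted(range(n), key=lambda i: (cells[i][0], cells[i][1], i))
    pos = {ci: k for k, ci in enumerate(order)}

    # columns as sorted sets of row positions, Z/2 reduction
    cols: list[set[int]] = [set(pos[f] for f in boundaries[ci]) for ci in order]
    low_of: dict[int, int] = {}
    pairs: list[tuple[int, int]] = []
    for j in range(n):
        col = cols[j]
        while col:
            low = max(col)
            if low not in low_of:
                break
            col ^= cols[low_of[low]]
        if col:
            low = max(col)
            low_of[low] = j
            pairs.append((low, j))
        cols[j] = col

    paired = set()
    births, deaths, degrees, essential = [], [], [], []
    for i, j in pairs:
        paired.add(i)
        paired.add(j)
        ci, cj = order[i], order[j]
        b, dim, _ = cells[ci]
        d = cells[cj][0]
        if d > b and dim <= 1:
            births.append(b)
            deaths.append(d)
            degrees.append(dim)
            essential.append(False)
    clamp = float(vals[finite].max())
    for k in range(n):
        if k in paired:
            continue
        ci = order[k]
        b, dim, _ = cells[ci]
        if dim <= 1:
            births.append(b)
            deaths.append(max(b, clamp))
            degrees.append(dim)
            essential.append(True)

    return PersistenceDiagram(
        np.array(births), np.array(deaths), np.array(degrees, np.int8),
        np.array(essential, bool), grid.kind, grid.direction_index,
        essential_clamped=True,
    )
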