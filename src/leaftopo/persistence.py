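"""Persistence diagrams of 2-D image filtrations.

Three filtrations drive the leaf descriptors:

* *shape* — directional height functions on the binary leaf mask, scanned
  from ``n_dirs`` equally spaced directions (degree 0 tracks how contour
  lobes and marginal teeth merge as the half-plane sweeps the leaf);
* *texture* — sublevel sets of the contrast-enhanced grayscale lamina
  (degree 0: dark blotches; degree 1: bright rings);
* *venation* — sublevel sets of the Euclidean distance transform of the
  binary vein network (degree 1 classes are areoles: closed vein loops,
  born at distance 0 and dying at the loop inradius).

Persistence is computed on the V-construction cubical complex (pixels are
vertices, higher cells take the max of their vertices): degree 0 by
union-find over 4-connected pixels in increasing value order, degree 1 by
the planar duality with 8-connected superlevel components of the
complement.  Essential classes are clamped to the maximum finite
filtration value and flagged.  Zero-lifetime non-essential pairs are
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._cubical import pairs_h0, pairs_h1
from .images import BinaryMask, GrayImage

KINDS = ("shape", "texture", "venation")


@dataclass
class FiltrationGrid:
    """Real-valued filtration on a pixel grid; +inf marks background."""

    values: np.ndarray
    kind: str
    direction_index: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("filtration grid must be 2-D")
        if self.kind not in KINDS:
            raise ValueError(f"unknown filtration kind {self.kind!r}")
        if self.kind == "shape" and self.direction_index is None:
            raise ValueError("shape filtrations carry a direction index")
        finite = np.isfinite(self.values)
        if not finite.any():
            raise ValueError("filtration grid has no finite cell")
        if np.isnan(self.values).any():
            raise ValueError("filtration values must not be NaN")

    @property
    def max_finite(self) -> float:
        return float(self.values[np.isfinite(self.values)].max())


@dataclass
class PersistenceDiagram:
    """Multiset of (birth, death, degree) points from one filtration."""

    births: np.ndarray
    deaths: np.ndarray
    degrees: np.ndarray
    essential: np.ndarray
    kind: str
    direction_index: int | None = None
    essential_clamped: bool = True

    def __post_init__(self) -> None:
        self.births = np.asarray(self.births, dtype=np.float64)
        self.deaths = np.asarray(self.deaths, dtype=np.float64)
        self.degrees = np.asarray(self.degrees, dtype=np.int8)
        self.essential = np.asarray(self.essential, dtype=bool)
        if not (self.deaths >= self.births).all():
            raise ValueError("death < birth in persistence diagram")

    def __len__(self) -> int:
        return self.births.shape[0]

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (birth, death) pairs."""
        return np.column_stack([self.births, self.deaths])

    @property
    def lifetimes(self) -> np.ndarray:
        return self.deaths - self.births

    def restrict(self, degree: int) -> "PersistenceDiagram":
        sel = self.degrees == degree
        return PersistenceDiagram(
            self.births[sel], self.deaths[sel], self.degrees[sel],
            self.essential[sel], self.kind, self.direction_index,
            self.essential_clamped,
        )

    def as_multiset(self, decimals: int = 9) -> list[tuple]:
        """Canonical sorted tuple list, for exact diagram comparison."""
        pts = sorted(
            (int(d), round(float(b), decimals), round(float(dd), decimals), bool(e))
            for b, dd, d, e in zip(self.births, self.deaths, self.degrees,
                                   self.essential)
        )
        return pts


def sublevel_persistence(grid: FiltrationGrid) -> PersistenceDiagram:
    """Degree-0 and degree-1 persistence of the sublevel filtration."""
    vals = grid.values
    h, w = vals.shape
    flat = vals.ravel()
    finite_idx = np.flatnonzero(np.isfinite(flat))
    # ascending by (value, index); stable sort keeps index order on ties
    order0 = finite_idx[np.argsort(flat[finite_idx], kind="stable")]
    b0, d0 = pairs_h0(flat, order0.astype(np.int64), h, w)

    order1 = np.argsort(-flat, kind="stable").astype(np.int64)
    b1, d1 = pairs_h1(flat, order1, h, w)

    clamp = grid.max_finite
    births = np.concatenate([b0, b1])
    deaths = np.concatenate([d0, d1])
    degrees = np.concatenate([np.zeros(len(b0), np.int8), np.ones(len(b1), np.int8)])
    essential = ~np.isfinite(deaths)
    deaths = np.where(essential, clamp, deaths)
    # essential classes may clamp below their birth only if birth == clamp
    deaths = np.maximum(deaths, births)
    return PersistenceDiagram(births, deaths, degrees, essential, grid.kind,
                              grid.direction_index, essential_clamped=True)


def height_filtration(mask: BinaryMask, theta: float) -> FiltrationGrid:
    """Height function <p - centroid, (cos t, sin t)> on the leaf mask.

    Coordinates are centroid-centred with x pointing right (columns) and y
    pointing up (decreasing rows); values are normalised by the mask's
    maximal radius so they lie in [-1, 1].  Background is +inf.
    """
    if mask.role != "leaf":
        raise ValueError("height filtration expects a leaf mask")
    fg = mask.values.astype(bool)
    if not fg.any():
        raise ValueError("empty leaf mask")
    rows, cols = np.nonzero(fg)
    cr, cc = rows.mean(), cols.mean()
    x = cols - cc
    y = cr - rows  # y axis points up
    rmax = np.sqrt(x * x + y * y).max()
    if rmax == 0:
        rmax = 1.0
    vals = np.full(mask.values.shape, np.inf)
    vals[rows, cols] = (x * np.cos(theta) + y * np.sin(theta)) / rmax
    # direction index is attached by shape_pds; a bare call gets 0
    return FiltrationGrid(vals, "shape", direction_index=0)


def shape_pds(mask: BinaryMask, n_dirs: int = 30) -> list[PersistenceDiagram]:
    """Degree-0 diagrams of the height filtration from n_dirs directions.

    Directions are 2*pi*i/n_dirs counter-clockwise from the x axis.
    """
    if n_dirs < 3:
        raise ValueError("need at least 3 directions")
    out = []
    for i in range(n_dirs):
        grid = height_filtration(mask, 2.0 * np.pi * i / n_dirs)
        grid.direction_index = i
        pd = sublevel_persistence(grid).restrict(0)
        pd.direction_index = i
        out.append(pd)
    return out


def distance_map(venation: BinaryMask, leaf: BinaryMask) -> FiltrationGrid:
    """Euclidean distance to the nearest vein pixel, inside the leaf.

    Vein pixels are at 0; pixels outside the leaf are background (+inf).
    """
    from scipy.ndimage import distance_transform_edt

    if venation.role != "venation":
        raise ValueError("expected a venation mask")
    vein = venation.values.astype(bool)
    if not vein.any():
        raise ValueError("empty venation mask")
    dist = distance_transform_edt(~vein)
    vals = np.where(leaf.values.astype(bool), dist, np.inf)
    return FiltrationGrid(vals, "venation")


def texture_venation_pds(
    enhanced: GrayImage, leaf: BinaryMask, venation: BinaryMask
) -> tuple[PersistenceDiagram, PersistenceDiagram,
           PersistenceDiagram, PersistenceDiagram]:
    """(texture PD0, texture PD1, venation PD0, venation PD1).

    Texture diagrams come from the sublevel filtration of the enhanced
    grayscale restricted to the leaf; venation diagrams from the sublevel
    filtration of the vein distance map.
    """
    if enhanced.values.shape != leaf.values.shape:
        raise ValueError("image/mask shape mismatch")
    tex_vals = np.where(leaf.values.astype(bool), enhanced.values, np.inf)
    tex = sublevel_persistence(FiltrationGrid(tex_vals, "texture"))
    ven = sublevel_persistence(distance_map(venation, leaf))
    return tex.restrict(0), tex.restrict(1), ven.restrict(0), ven.restrict(1)


# -- serialization ----------------------------------------------------------

def write_diagram(pd: PersistenceDiagram, path) -> None:
    """Columnar text: header comments then birth<TAB>death<TAB>degree."""
    with open(path, "w") as fh:
        fh.write(f"#kind\t{pd.kind}\n")
        di = "" if pd.direction_index is None else str(pd.direction_index)
        fh.write(f"#direction_index\t{di}\n")
        fh.write(f"#essential_clamped\t{int(pd.essential_clamped)}\n")
        for b, d, deg, ess in zip(pd.births, pd.deaths, pd.degrees, pd.essential):
            fh.write(f"{b:.9g}\t{d:.9g}\t{int(deg)}\t{int(ess)}\n")


def read_diagram(path) -> PersistenceDiagram:
    kind = "texture"
    direction_index: int | None = None
    clamped = True
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("\t")
                if key == "kind":
                    kind = val
                elif key == "direction_index":
                    direction_index = int(val) if val else None
                elif key == "essential_clamped":
                    clamped = bool(int(val))
                continue
            parts = line.split("\t")
            rows.append((float(parts[0]), float(parts[1]), int(parts[2]),
                         int(parts[3])))
    if rows:
        b, d, deg, ess = (np.array(c) for c in zip(*rows))
    else:
        b = d = np.empty(0)
        deg = np.empty(0, np.int8)
        ess = np.empty(0, bool)
    return PersistenceDiagram(b, d, deg, ess.astype(bool), kind,
                              direction_index, clamped)
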