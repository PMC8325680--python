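"""Network-ready persistence-diagram features.

Diagrams become fixed-size inputs by lifetime-ranked point selection
(700 points for shape, 1000 for texture/venation), diagonal padding, and
3-consecutive-direction stacking for the shape streams.  The trainable
vectorization maps a point multiset to a fixed vector through anisotropic
exponential structure elements over (birth, lifetime) coordinates:

    out[j] = sum_p exp(-(s_j0^2 (b_p - mu_j0)^2 + s_j1^2 (l_p - mu_j1)^2))

Padding points sit at lifetime 0 and are masked out of the sum, so they
contribute nothing regardless of the learned element positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .persistence import PersistenceDiagram

SHAPE_CAPACITY = 700
TEXTURE_CAPACITY = 1000


@dataclass
class PDPointSet:
    """Fixed-capacity, lifetime-ranked, diagonal-padded point list."""

    points: np.ndarray  # (k, 2) of (birth, lifetime)
    n_real: int
    channel: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("point set must be (k, 2)")
        if (self.points[:, 1] < 0).any():
            raise ValueError("negative lifetime")

    @property
    def capacity(self) -> int:
        return self.points.shape[0]

    @property
    def real_points(self) -> np.ndarray:
        return self.points[: self.n_real]


@dataclass
class DirectionStack:
    """Point sets from three consecutive height-function directions."""

    channels: tuple[PDPointSet, PDPointSet, PDPointSet]
    stack_index: int

    def __post_init__(self) -> None:
        caps = {c.capacity for c in self.channels}
        if len(caps) != 1:
            raise ValueError("stack channels must share capacity")

    def as_array(self) -> np.ndarray:
        """(3, k, 2) array of (birth, lifetime) with diagonal padding."""
        return np.stack([c.points for c in self.channels])


@dataclass
class VectorizationParams:
    """Trainable structure elements of the vectorization input layer."""

    centers: np.ndarray  # (n_elements, 2)
    sharpness: np.ndarray  # (n_elements, 2), strictly positive
    trainable: bool = True

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        self.sharpness = np.asarray(self.sharpness, dtype=np.float64)
        if self.centers.shape != self.sharpness.shape or self.centers.ndim != 2:
            raise ValueError("centers and sharpness must be (n_elements, 2)")
        if (self.sharpness <= 0).any():
            raise ValueError("sharpness must be strictly positive")

    @property
    def n_elements(self) -> int:
        return self.centers.shape[0]


def default_vectorization_params(n_elements: int, birth_range: tuple[float, float],
                                 life_range: tuple[float, float]
                                 ) -> VectorizationParams:
    """Structure elements on a regular sqrt(n) x sqrt(n) grid over the
    expected (birth, lifetime) window, sharpness one cell width."""
    side = int(round(np.sqrt(n_elements)))
    if side * side != n_elements:
        raise ValueError("n_elements must be a perfect square for grid init")
    b = np.linspace(*birth_range, side)
    l = np.linspace(*life_range, side)
    bb, ll = np.meshgrid(b, l, indexing="ij")
    centers = np.column_stack([bb.ravel(), ll.ravel()])
    db = (birth_range[1] - birth_range[0]) / max(side - 1, 1)
    dl = (life_range[1] - life_range[0]) / max(side - 1, 1)
    sharp = np.tile([1.0 / max(db, 1e-3), 1.0 / max(dl, 1e-3)], (n_elements, 1))
    return VectorizationParams(centers, sharp)


def select_top_points(pd: PersistenceDiagram, k: int,
                      channel: str = "") -> PDPointSet:
    """Longest-lifetime k points as (birth, lifetime), diagonal-padded.

    Ties in lifetime are broken by ascending birth, then ascending death,
    for determinism.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    births = pd.births
    lifetimes = pd.lifetimes
    order = np.lexsort((pd.deaths, births, -lifetimes))
    order = order[:k]
    n_real = len(order)
    pts = np.zeros((k, 2))
    pts[:n_real, 0] = births[order]
    pts[:n_real, 1] = lifetimes[order]
    return PDPointSet(pts, n_real=n_real, channel=channel)


def stack_directions(shape_pds: list[PersistenceDiagram],
                     k: int = SHAPE_CAPACITY) -> list[DirectionStack]:
    """Stack point sets of directions (i, i+1, i+2) mod n for each i."""
    n = len(shape_pds)
    if n < 3:
        raise ValueError("need at least 3 shape diagrams")
    if any(pd.kind != "shape" for pd in shape_pds):
        raise ValueError("all diagrams must have kind 'shape'")
    stacks = []
    for i in range(n):
        chans = tuple(
            select_top_points(shape_pds[(i + d) % n], k,
                              channel=f"shape_{(i + d) % n}")
            for d in range(3)
        )
        stacks.append(DirectionStack(chans, stack_index=i))
    return stacks


def structure_element_response(points: np.ndarray, n_real: int,
                               params: VectorizationParams) -> np.ndarray:
    """Sum of anisotropic exponential elements over the real points."""
    p = np.asarray(points, float)[:n_real]
    if p.shape[0] == 0:
        return np.zeros(params.n_elements)
    d0 = p[:, 0:1] - params.centers[None, :, 0]
    d1 = p[:, 1:2] - params.centers[None, :, 1]
    expo = (params.sharpness[None, :, 0] * d0) ** 2 + \
        (params.sharpness[None, :, 1] * d1) ** 2
    return np.exp(-expo).sum(axis=0)


def vectorize(ps: PDPointSet, params: VectorizationParams) -> np.ndarray:
    """Vectorize one point set; output length n_elements."""
    return structure_element_response(ps.points, ps.n_real, params)


def pd_histogram(pd: PersistenceDiagram, bins: int = 32) -> np.ndarray:
    """2-D histogram of (birth, death) points on a bins x bins mesh.

    The square window spans [min birth, max death] on both axes; bins are
    half-open except the last, so counts sum to the point count.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if len(pd) == 0:
        return np.zeros((bins, bins), dtype=np.int64)
    lo = float(pd.births.min())
    hi = float(pd.deaths.max())
    if hi <= lo:
        hi = lo + 1.0
    hist, _, _ = np.histogram2d(pd.births, pd.deaths, bins=bins,
                                range=[[lo, hi], [lo, hi]])
    return hist.astype(np.int64)


# -- per-image feature records and on-disk cache ---------------------------

@dataclass
class FeatureRecord:
    """All network inputs for one leaf image."""

    shape_stacks: list[DirectionStack]  # 30 stacks of (3, 700, 2)
    texture: tuple[PDPointSet, PDPointSet]  # PD0, PD1 at capacity 1000
    venation: tuple[PDPointSet, PDPointSet]
    label: int = -1
    image_vector: np.ndarray | None = None

    def stream_arrays(self) -> list[tuple[np.ndarray, int | np.ndarray]]:
        """34 streams as ((C, k, 2) array, per-channel n_real)."""
        out = []
        for st in self.shape_stacks:
            arr = st.as_array()
            nr = np.array([c.n_real for c in st.channels])
            out.append((arr, nr))
        for ps in (*self.texture, *self.venation):
            out.append((ps.points[None, :, :], np.array([ps.n_real])))
        return out


def save_record(path, rec: FeatureRecord) -> None:
    """One compressed container per image; keys documented below.

    shape/stack_00..29 -> (3, 700, 2) float32, shape/stack_XX_nreal -> (3,)
    texture/pd0, texture/pd1, venation/pd0, venation/pd1 -> (1000, 2),
    with matching *_nreal scalars; label; optional image_vector.
    """
    data = {}
    for i, st in enumerate(rec.shape_stacks):
        data[f"shape/stack_{i:02d}"] = st.as_array().astype(np.float32)
        data[f"shape/stack_{i:02d}_nreal"] = np.array(
            [c.n_real for c in st.channels], np.int32)
    for name, pair in (("texture", rec.texture), ("venation", rec.venation)):
        for d, ps in enumerate(pair):
            data[f"{name}/pd{d}"] = ps.points.astype(np.float32)
            data[f"{name}/pd{d}_nreal"] = np.int32(ps.n_real)
    data["label"] = np.int32(rec.label)
    if rec.image_vector is not None:
        data["image_vector"] = rec.image_vector.astype(np.float32)
    np.savez_compressed(path, **data)


def load_record(path) -> FeatureRecord:
    with np.load(path) as z:
        stacks = []
        for i in range(30):
            arr = z[f"shape/stack_{i:02d}"].astype(np.float64)
            nr = z[f"shape/stack_{i:02d}_nreal"]
            chans = tuple(PDPointSet(arr[c], int(nr[c]), f"shape_{i}")
                          for c in range(3))
            stacks.append(DirectionStack(chans, stack_index=i))
        pairs = {}
        for name in ("texture", "venation"):
            pairs[name] = tuple(
                PDPointSet(z[f"{name}/pd{d}"].astype(np.float64),
                           int(z[f"{name}/pd{d}_nreal"]), f"{name}_pd{d}")
                for d in range(2))
        label = int(z["label"])
        iv = z["image_vector"].astype(np.float64) if "image_vector" in z else None
    return FeatureRecord(stacks, pairs["texture"], pairs["venation"],
                         label=label, image_vector=iv)
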