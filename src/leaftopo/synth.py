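"""Procedural transmitted-light leaf images with ground truth.

Each cultivar is a point in a continuous morphology space: a low-order
Fourier contour (ovate-to-elliptic outlines), margin serration (tooth
amplitude and count), a branching venation plan (secondary vein count,
branch angle, areole-loop probability), and lamina texture statistics
(base transmittance, vein brightness contrast, correlated noise).  Growth
periods R1..R6 rescale, elongate, and degrade the same cultivar identity,
emulating leaves sampled at successive reproductive stages, with spots
and wormholes most frequent at R6.

The generator renders one dark leaf per frame on a bright background with
veins brighter than the lamina, and returns the ground-truth leaf and
vein masks alongside the image, so segmentation and vein recovery can be
scored directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .images import BinaryMask, GrayImage

FOURIER_ORDER = 6


@dataclass
class CultivarSpec:
    cultivar_id: int
    base_radius: float  # fraction of half-canvas
    fourier_cos: np.ndarray  # order 6 radius(theta) harmonics
    fourier_sin: np.ndarray
    serration_amp: float
    serration_freq: int
    n_secondary: int  # secondary veins per side
    branch_angle: float  # radians from the midrib
    areole_prob: float
    lamina_base: float
    vein_contrast: float
    noise_amp: float
    noise_corr: float  # correlation length, px

    def __post_init__(self) -> None:
        self.fourier_cos = np.asarray(self.fourier_cos, float)
        self.fourier_sin = np.asarray(self.fourier_sin, float)
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        if (self.radius(th) <= 0).any():
            raise ValueError("contour radius must stay positive")
        if not (0 < self.lamina_base + self.vein_contrast < 1):
            raise ValueError("intensities leave [0, 1]")

    def radius(self, theta: np.ndarray) -> np.ndarray:
        k = np.arange(1, FOURIER_ORDER + 1)
        mod = (self.fourier_cos * np.cos(np.outer(theta, k)) +
               self.fourier_sin * np.sin(np.outer(theta, k))).sum(axis=1)
        return self.base_radius * (1.0 + mod)


# parameter ranges used both for sampling and for distance normalisation
_RANGES = {
    "base_radius": (0.55, 0.72),
    "serration_amp": (0.0, 0.055),
    "serration_freq": (8, 28),
    "n_secondary": (4, 9),
    "branch_angle": (np.deg2rad(30), np.deg2rad(70)),
    "areole_prob": (0.0, 0.6),
    "lamina_base": (0.28, 0.44),
    "vein_contrast": (0.16, 0.34),
    "noise_amp": (0.02, 0.10),
    "noise_corr": (1.5, 4.0),
}
_FOURIER_SCALE = 0.10


def sample_cultivar_spec(rng_seed: int, cultivar_id: int = 0) -> CultivarSpec:
    """Deterministic spec draw from the morphology prior."""
    rng = np.random.default_rng(rng_seed)
    draw = {k: rng.uniform(lo, hi) for k, (lo, hi) in _RANGES.items()}
    decay = 1.0 / np.arange(1, FOURIER_ORDER + 1)
    return CultivarSpec(
        cultivar_id=cultivar_id,
        base_radius=draw["base_radius"],
        fourier_cos=rng.uniform(-1, 1, FOURIER_ORDER) * _FOURIER_SCALE * decay,
        fourier_sin=rng.uniform(-1, 1, FOURIER_ORDER) * _FOURIER_SCALE * decay,
        serration_amp=draw["serration_amp"],
        serration_freq=int(round(draw["serration_freq"])),
        n_secondary=int(round(draw["n_secondary"])),
        branch_angle=draw["branch_angle"],
        areole_prob=draw["areole_prob"],
        lamina_base=draw["lamina_base"],
        vein_contrast=draw["vein_contrast"],
        noise_amp=draw["noise_amp"],
        noise_corr=draw["noise_corr"],
    )


def _normalized_vector(spec: CultivarSpec) -> np.ndarray:
    vals = []
    for k, (lo, hi) in _RANGES.items():
        vals.append((getattr(spec, k) - lo) / (hi - lo))
    decay = 1.0 / np.arange(1, FOURIER_ORDER + 1)
    vals.extend(spec.fourier_cos / (2 * _FOURIER_SCALE * decay) + 0.5)
    vals.extend(spec.fourier_sin / (2 * _FOURIER_SCALE * decay) + 0.5)
    return np.array(vals)


def spec_distance(a: CultivarSpec, b: CultivarSpec) -> float:
    """Max absolute difference of range-normalised parameters."""
    return float(np.abs(_normalized_vector(a) - _normalized_vector(b)).max())


def sample_cultivar_specs(n: int, seed: int, min_dist: float = 0.15,
                          max_tries: int = 10_000) -> list[CultivarSpec]:
    """Rejection-sample n specs with pairwise distance >= min_dist."""
    specs: list[CultivarSpec] = []
    rng = np.random.default_rng(seed)
    tries = 0
    while len(specs) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("cannot place cultivars at this spacing")
        cand = sample_cultivar_spec(int(rng.integers(0, 2**31)),
                                    cultivar_id=len(specs))
        if all(spec_distance(cand, s) >= min_dist for s in specs):
            specs.append(cand)
    return specs


@dataclass
class GrowthPeriod:
    label: str
    scale: float
    elongation: float
    degradation: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")


DEFAULT_PERIODS = {
    "R1": GrowthPeriod("R1", 0.60, 1.00, 0.00),
    "R3": GrowthPeriod("R3", 0.72, 1.06, 0.02),
    "R4": GrowthPeriod("R4", 0.84, 1.12, 0.05),
    "R5": GrowthPeriod("R5", 0.95, 1.18, 0.10),
    "R6": GrowthPeriod("R6", 1.00, 1.22, 0.25),
}


def _draw_segment(mask: np.ndarray, p0, p1) -> None:
    from skimage.draw import line

    rr, cc = line(int(round(p0[0])), int(round(p0[1])),
                  int(round(p1[0])), int(round(p1[1])))
    ok = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
    mask[rr[ok], cc[ok]] = True


def render_leaf(spec: CultivarSpec, period: GrowthPeriod, rng_seed: int,
                size: int = 256) -> tuple[GrayImage, BinaryMask, BinaryMask]:
    """Render one leaf; returns (image, leaf mask, venation mask)."""
    from scipy.ndimage import binary_dilation, gaussian_filter
    from skimage.draw import polygon

    if size < 128:
        raise ValueError("canvas must be at least 128x128")
    rng = np.random.default_rng(rng_seed)
    half = size / 2.0
    rot = np.deg2rad(rng.uniform(-10, 10))

    theta = np.linspace(0, 2 * np.pi, 1440, endpoint=False)
    r = spec.radius(theta) * half * 0.85 * period.scale
    saw = 2.0 * np.abs(((spec.serration_freq * theta) / (2 * np.pi)) % 1.0 - 0.5)
    r = r * (1.0 + spec.serration_amp * (saw - 0.5) * 2.0)
    e = np.sqrt(period.elongation)
    x = r * np.cos(theta) / e
    y = r * np.sin(theta) * e
    xr = x * np.cos(rot) - y * np.sin(rot)
    yr = x * np.sin(rot) + y * np.cos(rot)
    rows = half - yr
    cols = half + xr
    leaf = np.zeros((size, size), bool)
    rr, cc = polygon(rows, cols, shape=leaf.shape)
    leaf[rr, cc] = True

    # venation: midrib along the (rotated) major axis plus secondary veins
    vein = np.zeros_like(leaf)

    def to_canvas(px, py):
        cx = px * np.cos(rot) - py * np.sin(rot)
        cy = px * np.sin(rot) + py * np.cos(rot)
        return (half - cy, half + cx)

    tip_r = spec.radius(np.array([np.pi / 2]))[0] * half * 0.85 * period.scale * e
    base_r = spec.radius(np.array([-np.pi / 2]))[0] * half * 0.85 * period.scale * e
    top = (0.0, tip_r * 0.97)
    bottom = (0.0, -base_r * 0.97)
    _draw_segment(vein, to_canvas(*bottom), to_canvas(*top))

    side_pts: dict[int, list[tuple[float, float]]] = {-1: [], 1: []}
    length = tip_r + base_r
    for i in range(spec.n_secondary):
        t = (i + 1) / (spec.n_secondary + 1)
        oy = -base_r * 0.97 + t * length * 0.94
        jit = rng.normal(0, 1.5)
        for sgn in (-1, 1):
            ang = np.pi / 2 - sgn * spec.branch_angle
            ln = length * 0.33 * (1.0 - 0.55 * abs(t - 0.45))
            ex = np.cos(ang) * ln * sgn
            ey = np.sin(ang) * ln * 0.4
            end = (ex + rng.normal(0, 1.0), oy + ey + jit)
            _draw_segment(vein, to_canvas(0.0, oy + jit), to_canvas(*end))
            side_pts[sgn].append(end)

    # areole loops: bridge consecutive secondary tips on the same side
    for sgn in (-1, 1):
        pts = side_pts[sgn]
        for a, b in zip(pts, pts[1:]):
            if rng.random() < spec.areole_prob:
                _draw_segment(vein, to_canvas(*a), to_canvas(*b))

    vein = binary_dilation(vein, iterations=1) & leaf

    # intensity: bright background, dark lamina, brighter veins, noise
    img = np.ones((size, size))
    noise = gaussian_filter(rng.standard_normal((size, size)), spec.noise_corr)
    noise *= spec.noise_amp / max(noise.std(), 1e-9)
    img[leaf] = spec.lamina_base + noise[leaf]
    img[vein] = spec.lamina_base + spec.vein_contrast + 0.3 * noise[vein]

    # degradation: disease spots (dark) and wormholes (bright), mostly R6
    n_spots = rng.poisson(8.0 * period.degradation)
    lr, lc = np.nonzero(leaf)
    for _ in range(n_spots):
        if len(lr) == 0:
            break
        j = rng.integers(len(lr))
        rad = rng.uniform(2, 5)
        yy, xx = np.ogrid[:size, :size]
        disk = (yy - lr[j]) ** 2 + (xx - lc[j]) ** 2 <= rad ** 2
        if rng.random() < 0.3:  # wormhole: light shines through
            img[disk & leaf] = 0.95
        else:
            img[disk & leaf] *= 0.5

    img = np.clip(img, 0.0, 1.0)
    return (GrayImage(img), BinaryMask(leaf, "leaf"),
            BinaryMask(vein, "venation"))


def image_seed(base_seed: int, cultivar: int, period_idx: int, j: int) -> int:
    return int((base_seed * 1_000_003 + cultivar * 10_007 +
                period_idx * 101 + j) % (2**31 - 1))


def generate_dataset(n_cultivars: int, n_per_cultivar_per_period: int,
                     periods: list[str], seed: int, out_dir,
                     size: int = 256, min_dist: float = 0.15):
    """Render a labelled dataset to <cultivar>/<period>/<image>.png.

    Ground-truth masks are written alongside each image; returns the
    manifest DataFrame (also saved as manifest.csv).
    """
    import imageio.v3 as iio
    import pandas as pd

    if n_cultivars < 2:
        raise ValueError("need at least 2 cultivars")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs = sample_cultivar_specs(n_cultivars, seed, min_dist)
    rows = []
    for ci, spec in enumerate(specs):
        for pi, plabel in enumerate(periods):
            period = DEFAULT_PERIODS[plabel]
            pdir = out / f"cultivar_{ci:03d}" / plabel
            pdir.mkdir(parents=True, exist_ok=True)
            for j in range(n_per_cultivar_per_period):
                iseed = image_seed(seed, ci, pi, j)
                img, leaf, veinmask = render_leaf(spec, period, iseed, size)
                name = f"leaf_{j:03d}"
                ipath = pdir / f"{name}.png"
                iio.imwrite(ipath, (img.values * 255).astype(np.uint8))
                iio.imwrite(pdir / f"{name}_leafmask.png",
                            leaf.values * np.uint8(255))
                iio.imwrite(pdir / f"{name}_veinmask.png",
                            veinmask.values * np.uint8(255))
                rows.append({"path": str(ipath.relative_to(out)),
                             "cultivar": ci, "period": plabel, "seed": iseed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    with open(out / "specs.json", "w") as fh:
        json.dump([{k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in asdict(s).items()} for s in specs], fh)
    return manifest
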