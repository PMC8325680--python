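"""Image -> feature-record extraction pipeline.

Glues preprocessing, the three filtrations, and point selection into the
per-image record the classifier consumes: 30 three-channel shape stacks
(700 points each), texture PD0/PD1 and venation PD0/PD1 (1000 points
each), plus an optional image-branch vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .features import (FeatureRecord, SHAPE_CAPACITY, TEXTURE_CAPACITY,
                       select_top_points, stack_directions)
from .images import (BinaryMask, GrayImage, enhance_contrast, extract_venation,
                     segment_leaf)
from .persistence import shape_pds, texture_venation_pds

log = logging.getLogger(__name__)


@dataclass
class ExtractConfig:
    n_dirs: int = 30
    shape_capacity: int = SHAPE_CAPACITY
    texture_capacity: int = TEXTURE_CAPACITY
    dark_leaf: bool = True
    vein_scales: tuple = (1, 2, 4)
    vein_low_quantile: float = 0.85
    vein_high_quantile: float = 0.97
    vein_min_size: int = 20


def extract_record(img: GrayImage, label: int = -1,
                   cfg: ExtractConfig | None = None,
                   image_branch=None,
                   leaf_mask: BinaryMask | None = None,
                   vein_mask: BinaryMask | None = None) -> FeatureRecord:
    """Extract all 34 streams from one leaf image.

    Ground-truth masks may be injected (synthetic data); otherwise the
    image is segmented and the veins extracted from the enhanced lamina.
    """
    cfg = cfg or ExtractConfig()
    if leaf_mask is None:
        leaf_mask = segment_leaf(img, dark_leaf=cfg.dark_leaf)
    enhanced = enhance_contrast(img, leaf_mask)
    if vein_mask is None:
        vein_mask = extract_venation(
            enhanced, leaf_mask, scales=cfg.vein_scales,
            low_quantile=cfg.vein_low_quantile,
            high_quantile=cfg.vein_high_quantile,
            min_size=cfg.vein_min_size)

    spds = shape_pds(leaf_mask, n_dirs=cfg.n_dirs)
    stacks = stack_directions(spds, k=cfg.shape_capacity)
    tex0, tex1, ven0, ven1 = texture_venation_pds(enhanced, leaf_mask, vein_mask)
    k = cfg.texture_capacity
    rec = FeatureRecord(
        shape_stacks=stacks,
        texture=(select_top_points(tex0, k, "texture_pd0"),
                 select_top_points(tex1, k, "texture_pd1")),
        venation=(select_top_points(ven0, k, "venation_pd0"),
                  select_top_points(ven1, k, "venation_pd1")),
        label=label,
    )
    if image_branch is not None:
        rec.image_vector = image_branch(img.values)
    return rec


def extract_dataset(images, labels, cfg: ExtractConfig | None = None,
                    image_branch=None, masks=None) -> list[FeatureRecord]:
    """Extract records for a list of images; masks may carry ground truth
    as (leaf_mask, vein_mask) tuples."""
    records = []
    for i, (img, lab) in enumerate(zip(images, labels)):
        lm = vm = None
        if masks is not None:
            lm, vm = masks[i]
        records.append(extract_record(img, lab, cfg, image_branch, lm, vm))
    return records
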