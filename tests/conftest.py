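import numpy as np
import pytest

from leaftopo.synth import DEFAULT_PERIODS, image_seed, render_leaf, \
    sample_cultivar_specs


@pytest.fixture(scope="session")
def leaf_scene():
    """One rendered mid-season leaf with ground truth, 128px canvas."""
    spec = sample_cultivar_specs(1, 7, min_dist=0.0)[0]
    img, leaf, vein = render_leaf(spec, DEFAULT_PERIODS["R3"], 42, size=128)
    return spec, img, leaf, vein


@pytest.fixture(scope="session")
def recovery_dataset():
    """The 5-cultivar parameter-recovery bed: 40 leaves per cultivar at one
    period, full preprocessing pipeline (no ground-truth mask injection)."""
    from leaftopo.pipeline import extract_record

    specs = sample_cultivar_specs(5, 7)
    records = []
    for ci, spec in enumerate(specs):
        for j in range(40):
            img, _, _ = render_leaf(spec, DEFAULT_PERIODS["R3"],
                                    image_seed(7, ci, 1, j), size=128)
            records.append(extract_record(img, label=ci))
    return records


@pytest.fixture(scope="session")
def recovery_model(recovery_dataset):
    """PD-branches-only model trained on the recovery bed (seed 7)."""
    from leaftopo.model import FusionConfig, TrainConfig, build_fusion_model, \
        train

    fcfg = FusionConfig(use_image_branch=False)
    tcfg = TrainConfig(epochs=40, seed=7)
    model = build_fusion_model(fcfg, 5, seed=7)
    model, hist = train(model, recovery_dataset, tcfg)
    return model, hist
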