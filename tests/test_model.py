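import numpy as np
import pytest

from leaftopo.features import DirectionStack, FeatureRecord, PDPointSet
from leaftopo.model import (BranchConfig, ConfigError, FusionConfig,
                            TrainConfig, build_fusion_model,
                            build_image_branch, build_pd_branch, predict,
                            train)


def toy_record(rng, label, n_classes=2, signal=0.5):
    """Small feature record whose shape-stream point clouds carry a
    label-dependent offset, so the task is learnable fast."""
    def ps(center, n=6, cap=12):
        pts = np.zeros((cap, 2))
        pts[:n, 0] = rng.normal(center, 0.05, n)
        pts[:n, 1] = np.abs(rng.normal(0.5, 0.1, n))
        return PDPointSet(pts, n_real=n)

    center = -0.5 + signal * label / max(n_classes - 1, 1)
    stacks = [DirectionStack((ps(center), ps(center), ps(center)), i)
              for i in range(30)]
    tex = (ps(0.3 + 0.2 * label, cap=12), ps(0.5, cap=12))
    ven = (ps(0.2, cap=12), ps(0.4, cap=12))
    return FeatureRecord(stacks, tex, ven, label=label)


def toy_dataset(n_per_class=12, n_classes=2, seed=0):
    rng = np.random.default_rng(seed)
    return [toy_record(rng, c, n_classes)
            for c in range(n_classes) for _ in range(n_per_class)]


class TestBranch:
    def test_output_is_256_dimensional(self):
        rng = np.random.default_rng(0)
        branch = build_pd_branch(
            BranchConfig(3, (-1, 1), (0, 2)), rng)
        pts = rng.random((4, 3, 10, 2)).astype(np.float32)
        mask = np.ones((4, 3, 10), np.float32)
        out = branch.forward((pts, mask), train=False)
        assert out.shape == (4, 256)

    def test_ten_layers(self):
        rng = np.random.default_rng(0)
        branch = build_pd_branch(BranchConfig(1, (0, 1), (0, 1)), rng)
        assert len(branch.layers) == 10

    def test_identical_weights_identical_outputs(self):
        rng = np.random.default_rng(5)
        pts = rng.random((2, 1, 8, 2)).astype(np.float32)
        mask = np.ones((2, 1, 8), np.float32)
        b1 = build_pd_branch(BranchConfig(1, (0, 1), (0, 1)), np.random.default_rng(7))
        b2 = build_pd_branch(BranchConfig(1, (0, 1), (0, 1)), np.random.default_rng(7))
        np.testing.assert_array_equal(b1.forward((pts, mask), False),
                                      b2.forward((pts, mask), False))

    def test_shape_branch_rejects_single_channel_input(self):
        rng = np.random.default_rng(0)
        branch = build_pd_branch(BranchConfig(3, (-1, 1), (0, 2)), rng)
        pts = rng.random((2, 1, 5, 2)).astype(np.float32)
        mask = np.ones((2, 1, 5), np.float32)
        with pytest.raises(ValueError):
            branch.forward((pts, mask), False)

    def test_invalid_channel_count_rejected(self):
        with pytest.raises(ConfigError):
            build_pd_branch(BranchConfig(2, (0, 1), (0, 1)),
                            np.random.default_rng(0))


class TestImageBranch:
    def test_stub_emits_2048(self):
        stub = build_image_branch("stub")
        out = stub(np.random.default_rng(0).random((256, 256, 3)))
        assert out.shape == (2048,)

    def test_stub_deterministic(self):
        stub = build_image_branch("stub", seed=3)
        img = np.full((256, 256), 0.5)
        np.testing.assert_array_equal(stub(img), stub(img))

    def test_xception_backbones_unavailable_offline(self):
        with pytest.raises(ConfigError, match="framework"):
            build_image_branch("xception_imagenet")
        with pytest.raises(ConfigError):
            build_image_branch("nonsense")


class TestFusionModel:
    def test_dimension_identity(self):
        fcfg = FusionConfig()
        assert fcfg.n_streams == 34
        assert fcfg.topo_dim == 34 * 256 == 8704
        assert fcfg.concat_dim == 2048 + 8704 == 10752

    def test_probabilities_sum_to_one(self):
        model = build_fusion_model(FusionConfig(use_image_branch=False), 3,
                                   seed=0)
        ds = toy_dataset(2, 3)
        probs = predict(model, ds)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_predict_is_deterministic(self):
        model = build_fusion_model(FusionConfig(use_image_branch=False), 2)
        rec = toy_dataset(1, 2)[0]
        np.testing.assert_array_equal(predict(model, rec),
                                      predict(model, rec))

    def test_needs_two_classes(self):
        with pytest.raises(ConfigError):
            build_fusion_model(FusionConfig(), 1)


class TestTraining:
    def test_split_fractions_validated(self):
        with pytest.raises(ValueError):
            TrainConfig(test_fraction=0.7, val_fraction=0.4)
        with pytest.raises(ValueError):
            TrainConfig(test_fraction=0.0)

    def test_selected_model_attains_min_val_loss(self):
        from leaftopo.model import _epoch_loss

        ds = toy_dataset(10, 2, seed=1)
        model = build_fusion_model(FusionConfig(use_image_branch=False), 2,
                                   seed=1)
        tcfg = TrainConfig(epochs=6, seed=1, batch_size=8)
        model, hist = train(model, ds, tcfg)
        assert hist["best_val_loss"] == pytest.approx(min(hist["val_loss"]))
        reloaded = _epoch_loss(model, ds, hist["split"]["val"], 8)
        assert reloaded == pytest.approx(hist["best_val_loss"], rel=1e-5)

    def test_plateau_halves_learning_rate(self):
        """With a vanishing step size the validation loss never improves
        after epoch 1, so the plateau rule must halve the learning rate
        after each patience window (5 epochs)."""
        ds = toy_dataset(8, 2, seed=2)
        model = build_fusion_model(FusionConfig(use_image_branch=False), 2,
                                   seed=2)
        tcfg = TrainConfig(epochs=8, seed=2, initial_lr=1e-30, batch_size=8)
        model, hist = train(model, ds, tcfg)
        assert hist["lr"][5] == pytest.approx(1e-30)
        assert hist["lr"][6] == pytest.approx(0.5e-30)

    def test_learns_separable_toy_classes(self):
        from leaftopo.model import accuracy

        ds = toy_dataset(12, 2, seed=3)
        model = build_fusion_model(FusionConfig(use_image_branch=False), 2,
                                   seed=3)
        model, hist = train(model, ds, TrainConfig(epochs=10, seed=3))
        assert accuracy(model, ds, hist["split"]["test"]) >= 0.75

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        ds = [toy_record(rng, 0) for _ in range(8)]
        model = build_fusion_model(FusionConfig(use_image_branch=False), 2)
        with pytest.raises(ValueError):
            train(model, ds, TrainConfig(epochs=1))


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        from leaftopo.model import load_model, save_model

        model = build_fusion_model(FusionConfig(use_image_branch=False), 2,
                                   seed=9)
        rec = toy_dataset(1, 2)[0]
        before = predict(model, rec)
        save_model(tmp_path / "m.npz", model, class_names=["a", "b"])
        back, names = load_model(tmp_path / "m.npz")
        assert names == ["a", "b"]
        np.testing.assert_allclose(predict(back, rec), before, atol=1e-6)
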