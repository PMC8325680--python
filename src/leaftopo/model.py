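"""The fused cultivar classifier.

34 topological streams -- 30 three-channel shape stacks plus texture PD0/
PD1 and venation PD0/PD1 -- each pass through a ten-layer branch
(vectorization input, conv with 16 filters, max-pool along the filter
dimension, dropout, batch norm, ReLU, second conv + pool + dropout, dense
to 256).  The 34 x 256 = 8704-dim topological feature is concatenated
with a 2048-dim image-branch vector (early fusion, 10752 total) and fed
to the head: dropout 0.5, dense 2048, batch norm, softmax over cultivars.

Training follows the published recipe: RMSProp at 1e-3, learning rate
halved after five epochs without validation-loss improvement, the
checkpoint with the smallest validation loss kept, 0.3/0.1 test and
validation fractions.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .features import FeatureRecord, default_vectorization_params

STREAM_DIM = 256
IMAGE_DIM = 2048
N_SHAPE_STREAMS = 30


class ConfigError(ValueError):
    pass


@dataclass
class BranchConfig:
    """One PD-processing branch: ten layers, 256-dim output."""

    n_channels: int
    birth_range: tuple[float, float]
    life_range: tuple[float, float]
    n_elements: int = 64
    n_filters: int = 16
    kernel: int = 3
    dropout: float = 0.25
    out_dim: int = STREAM_DIM


@dataclass
class FusionConfig:
    n_shape: int = N_SHAPE_STREAMS
    n_texture: int = 2
    n_venation: int = 2
    stream_dim: int = STREAM_DIM
    image_branch_dim: int = IMAGE_DIM
    n_elements: int = 64
    branch_dropout: float = 0.25
    head_dropout: float = 0.5
    head_dense: int = 2048
    venation_scale: float = 24.0  # expected max vein distance, px
    # optional stream ablation: subset of {"shape", "texture", "venation"}
    stream_kinds: tuple[str, ...] = ("shape", "texture", "venation")
    use_image_branch: bool = True

    @property
    def n_streams(self) -> int:
        n = 0
        if "shape" in self.stream_kinds:
            n += self.n_shape
        if "texture" in self.stream_kinds:
            n += self.n_texture
        if "venation" in self.stream_kinds:
            n += self.n_venation
        return n

    @property
    def topo_dim(self) -> int:
        return self.n_streams * self.stream_dim

    @property
    def concat_dim(self) -> int:
        return self.image_branch_dim + self.topo_dim


@dataclass
class TrainConfig:
    epochs: int = 200
    optimizer: str = "rmsprop"
    initial_lr: float = 1e-3
    lr_patience: int = 5
    batch_size: int = 32
    test_fraction: float = 0.3
    val_fraction: float = 0.1
    image_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1 and 0 < self.val_fraction < 1):
            raise ValueError("fractions must lie in (0, 1)")
        if self.test_fraction + self.val_fraction >= 1:
            raise ValueError("test + validation fraction must be < 1")


def build_pd_branch(cfg: BranchConfig, rng: np.random.Generator) -> nn.Sequential:
    """Ten-layer branch mapping one stream's point sets to 256 dims."""
    if cfg.n_channels not in (1, 3):
        raise ConfigError("branches take 1 (texture/venation) or 3 (shape) channels")
    vp = default_vectorization_params(cfg.n_elements, cfg.birth_range,
                                      cfg.life_range)
    return nn.Sequential([
        nn.Vectorization(cfg.n_channels, vp.centers, vp.sharpness),
        nn.Conv1D(cfg.n_channels, cfg.n_filters, cfg.kernel, rng),
        nn.FilterMaxPool(),
        nn.Dropout(cfg.dropout, rng),
        nn.BatchNorm(cfg.n_elements),
        nn.ReLU(),
        nn.Conv1D(1, cfg.n_filters, cfg.kernel, rng),
        nn.FilterMaxPool(),
        nn.Dropout(cfg.dropout, rng),
        nn.Dense(cfg.n_elements, cfg.out_dim, rng),
    ])


class ImageBranchStub:
    """Small fixed feature extractor ending in global average pooling.

    A frozen, seeded random convolutional projection: resize to 32x32,
    3x3 conv with 16 filters (stride 2) + ReLU, 1x1 conv to 2048
    channels, then global average pooling.  Deterministic and offline;
    used wherever a pretrained backbone is unavailable or unwanted.
    """

    out_dim = IMAGE_DIM

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.w1 = rng.standard_normal((16, 3, 3, 3)).astype(np.float32) * 0.1
        self.w2 = rng.standard_normal((16, self.out_dim)).astype(np.float32) * 0.1

    def __call__(self, image: np.ndarray) -> np.ndarray:
        from skimage.transform import resize

        img = np.asarray(image, np.float32)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        img = resize(img, (32, 32, 3), anti_aliasing=True).astype(np.float32)
        # valid 3x3 conv, stride 2
        patches = np.lib.stride_tricks.sliding_window_view(
            img, (3, 3, 3))[::2, ::2, 0]
        feat = np.einsum("hwijc,fijc->hwf", patches, self.w1)
        feat = np.maximum(feat, 0.0)
        pooled = feat.mean(axis=(0, 1))  # global average pooling over space
        return (pooled @ self.w2).astype(np.float64)


def build_image_branch(backbone: str, seed: int = 0):
    """Image feature extractor producing a 2048-dim vector."""
    if backbone == "stub":
        return ImageBranchStub(seed)
    if backbone in ("xception_imagenet", "xception_random"):
        raise ConfigError(
            f"backbone {backbone!r} requires an optional deep-learning "
            "framework with Xception weights, which is not installed; "
            "use backbone='stub'")
    raise ConfigError(f"unknown backbone {backbone!r}")


class FusionModel:
    """34 PD branches + image vector -> fusion head -> class probabilities."""

    def __init__(self, fcfg: FusionConfig, n_classes: int, seed: int = 0):
        if n_classes < 2:
            raise ConfigError("need at least two classes")
        self.fcfg = fcfg
        self.n_classes = n_classes
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(
            rng.integers(0, 2**31))

        self.stream_specs: list[tuple[str, int]] = []
        if "shape" in fcfg.stream_kinds:
            self.stream_specs += [("shape", i) for i in range(fcfg.n_shape)]
        if "texture" in fcfg.stream_kinds:
            self.stream_specs += [("texture", d) for d in range(fcfg.n_texture)]
        if "venation" in fcfg.stream_kinds:
            self.stream_specs += [("venation", d) for d in range(fcfg.n_venation)]

        self.branches = []
        for kind, _ in self.stream_specs:
            if kind == "shape":
                bcfg = BranchConfig(3, (-1.0, 1.0), (0.0, 2.0),
                                    n_elements=fcfg.n_elements,
                                    dropout=fcfg.branch_dropout)
            elif kind == "texture":
                bcfg = BranchConfig(1, (0.0, 1.0), (0.0, 1.0),
                                    n_elements=fcfg.n_elements,
                                    dropout=fcfg.branch_dropout)
            else:
                s = fcfg.venation_scale
                bcfg = BranchConfig(1, (0.0, s), (0.0, s),
                                    n_elements=fcfg.n_elements,
                                    dropout=fcfg.branch_dropout)
            self.branches.append(build_pd_branch(bcfg, rng))

        # dimension identity checked at build time
        default = FusionConfig()
        if fcfg.stream_kinds == default.stream_kinds and \
                fcfg.n_shape == 30 and fcfg.stream_dim == 256:
            assert fcfg.topo_dim == 8704
            assert fcfg.concat_dim == 10752

        self.head = nn.Sequential([
            nn.Dropout(fcfg.head_dropout, rng),
            nn.Dense(fcfg.concat_dim, fcfg.head_dense, rng),
            nn.BatchNorm(fcfg.head_dense),
            nn.Dense(fcfg.head_dense, n_classes, rng),
        ])
        # share one dropout rng across all dropout layers for reseeding
        for layer in self.layers():
            if isinstance(layer, nn.Dropout):
                layer.rng = self._dropout_rng

    def layers(self) -> list[nn.Layer]:
        out = []
        for br in self.branches:
            out.extend(nn.collect_layers(br))
        out.extend(nn.collect_layers(self.head))
        return out

    def reseed(self, seed: int) -> None:
        self._dropout_rng = np.random.default_rng(seed)
        for layer in self.layers():
            if isinstance(layer, nn.Dropout):
                layer.rng = self._dropout_rng

    # -- batching ----------------------------------------------------------

    def collate(self, records: list[FeatureRecord]) -> dict:
        """Pack records into per-stream padded (points, mask) batches."""
        B = len(records)
        all_streams = [rec.stream_arrays() for rec in records]
        # map stream spec -> index in FeatureRecord.stream_arrays() (fixed
        # layout: 30 shape, texture pd0, pd1, venation pd0, pd1)
        layout = [("shape", i) for i in range(30)] + \
            [("texture", 0), ("texture", 1), ("venation", 0), ("venation", 1)]
        pos = {spec: i for i, spec in enumerate(layout)}
        streams = []
        for spec in self.stream_specs:
            src = pos[spec]
            arrs = [s[src][0] for s in all_streams]
            nrs = [s[src][1] for s in all_streams]
            C = arrs[0].shape[0]
            nmax = max(1, max(int(np.max(nr)) for nr in nrs))
            pts = np.zeros((B, C, nmax, 2), np.float32)
            mask = np.zeros((B, C, nmax), np.float32)
            for b, (arr, nr) in enumerate(zip(arrs, nrs)):
                for c in range(C):
                    n = int(nr[c])
                    n = min(n, nmax)
                    pts[b, c, :n] = arr[c, :n]
                    mask[b, c, :n] = 1.0
            streams.append((pts, mask))
        if self.fcfg.use_image_branch:
            img = np.stack([
                rec.image_vector if rec.image_vector is not None
                else np.zeros(self.fcfg.image_branch_dim)
                for rec in records]).astype(np.float32)
        else:
            img = np.zeros((B, self.fcfg.image_branch_dim), np.float32)
        labels = np.array([rec.label for rec in records], np.int64)
        return {"streams": streams, "image": img, "labels": labels}

    # -- forward / backward ------------------------------------------------

    def forward(self, batch: dict, train: bool = False) -> np.ndarray:
        feats = [br.forward(x, train) for br, x in
                 zip(self.branches, batch["streams"])]
        concat = np.concatenate(feats + [batch["image"]], axis=1)
        assert concat.shape[1] == self.fcfg.concat_dim
        self._topo_width = sum(f.shape[1] for f in feats)
        logits = self.head.forward(concat, train)
        return nn.softmax(logits)

    def backward(self, probs: np.ndarray, labels: np.ndarray) -> None:
        B = len(labels)
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        dconcat = self.head.backward(dlogits.astype(np.float32))
        off = 0
        for br in self.branches:
            br.backward(dconcat[:, off:off + self.fcfg.stream_dim])
            off += self.fcfg.stream_dim


def build_fusion_model(fcfg: FusionConfig, n_classes: int,
                       seed: int = 0) -> FusionModel:
    return FusionModel(fcfg, n_classes, seed)


# -- training ---------------------------------------------------------------

def stratified_split(labels: np.ndarray, tcfg: TrainConfig
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(train, val, test) indices, stratified by label."""
    from sklearn.model_selection import train_test_split

    labels = np.asarray(labels)
    counts = np.bincount(labels)
    if (counts[counts > 0] < 2).any():
        raise ValueError("every class needs at least 2 images")
    idx = np.arange(len(labels))
    rest, test = train_test_split(idx, test_size=tcfg.test_fraction,
                                  stratify=labels, random_state=tcfg.seed)
    val_of_rest = tcfg.val_fraction / (1.0 - tcfg.test_fraction)
    train, val = train_test_split(rest, test_size=val_of_rest,
                                  stratify=labels[rest],
                                  random_state=tcfg.seed + 1)
    if (np.bincount(labels[train], minlength=len(counts))[counts > 0] < 2).any():
        raise ValueError("a class has fewer than 2 training images")
    return train, val, test


def _epoch_loss(model: FusionModel, records, idx, batch_size) -> float:
    losses, weights = [], []
    for s in range(0, len(idx), batch_size):
        chunk = [records[i] for i in idx[s:s + batch_size]]
        batch = model.collate(chunk)
        probs = model.forward(batch, train=False)
        losses.append(nn.cross_entropy(probs, batch["labels"]))
        weights.append(len(chunk))
    return float(np.average(losses, weights=weights))


def train(model: FusionModel, dataset: list[FeatureRecord],
          tcfg: TrainConfig) -> tuple[FusionModel, dict]:
    """Train with RMSProp, plateau LR halving, best-val-loss selection."""
    labels = np.array([r.label for r in dataset])
    if len(np.bincount(labels)) < 2:
        raise ValueError("dataset needs at least 2 classes")
    tr, va, te = stratified_split(labels, tcfg)
    rng = np.random.default_rng(tcfg.seed)
    model.reseed(int(rng.integers(0, 2**31)))
    opt = nn.RMSProp(lr=tcfg.initial_lr)
    layers = model.layers()

    history = {"train_loss": [], "val_loss": [], "lr": [],
               "split": {"train": tr.tolist(), "val": va.tolist(),
                          "test": te.tolist()}}
    best_loss = np.inf
    best_state = nn.get_param_state(layers)
    since_improve = 0
    for epoch in range(tcfg.epochs):
        order = rng.permutation(tr)
        ep_losses = []
        for s in range(0, len(order), tcfg.batch_size):
            chunk = [dataset[i] for i in order[s:s + tcfg.batch_size]]
            batch = model.collate(chunk)
            probs = model.forward(batch, train=True)
            ep_losses.append(nn.cross_entropy(probs, batch["labels"]))
            model.backward(probs, batch["labels"])
            opt.step(layers)
        val_loss = _epoch_loss(model, dataset, va, tcfg.batch_size)
        history["train_loss"].append(float(np.mean(ep_losses)))
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = nn.get_param_state(layers)
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= tcfg.lr_patience:
                opt.lr *= 0.5
                since_improve = 0
    nn.set_param_state(layers, best_state)
    history["best_val_loss"] = float(best_loss)
    return model, history


def predict(model: FusionModel, records) -> np.ndarray:
    """Class-probability vectors for one record or a list of records."""
    single = isinstance(records, FeatureRecord)
    recs = [records] if single else list(records)
    probs = []
    for s in range(0, len(recs), 64):
        batch = model.collate(recs[s:s + 64])
        probs.append(model.forward(batch, train=False))
    out = np.concatenate(probs, axis=0)
    return out[0] if single else out


def accuracy(model: FusionModel, dataset, idx) -> float:
    recs = [dataset[i] for i in idx]
    probs = predict(model, recs)
    pred = probs.argmax(axis=1)
    truth = np.array([r.label for r in recs])
    return float((pred == truth).mean())


# -- checkpointing ----------------------------------------------------------

def save_model(path, model: FusionModel, class_names=None) -> None:
    """Native .npz parameter dump plus a JSON sidecar with the config."""
    layers = model.layers()
    state = nn.get_param_state(layers)
    flat = {}
    for i, d in enumerate(state):
        for k, v in d.items():
            flat[f"layer{i:03d}/{k}"] = v
    np.savez_compressed(path, **flat)
    sidecar = {
        "fusion_config": asdict(model.fcfg),
        "n_classes": model.n_classes,
        "seed": model.seed,
        "class_names": list(class_names) if class_names is not None else None,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(path) -> tuple[FusionModel, list | None]:
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    fcfg_d = sidecar["fusion_config"]
    fcfg_d["stream_kinds"] = tuple(fcfg_d["stream_kinds"])
    fcfg = FusionConfig(**fcfg_d)
    model = FusionModel(fcfg, sidecar["n_classes"], seed=sidecar["seed"])
    layers = model.layers()
    state = nn.get_param_state(layers)
    with np.load(path) as z:
        for i, d in enumerate(state):
            for k in d:
                d[k] = z[f"layer{i:03d}/{k}"]
    nn.set_param_state(layers, state)
    return model, sidecar["class_names"]
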