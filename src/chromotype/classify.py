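"""Training of the 3-way classification head on frozen backbone features.

Transfer-learning contract: the convolutional backbone is a fixed feature
extractor; only the final fully connected layer (a 3-class affine map on
globally averaged features) is trained, by mini-batch stochastic gradient
descent on the softmax cross-entropy with a fixed step size.  After every
epoch the head is scored on a held-out validation set and the checkpoint
with the highest validation concordance is returned (model selection).

Features are standardized (per-dimension mean/SD computed on the training
set) before the affine map; the standardization constants are part of the
head, not of the backbone, so the freezing contract is untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .backbones import Backbone, BackboneSpec, build_backbone
from .preprocess import PreprocessConfig, preprocess_pipeline
from .synthetic import LABELS, LabeledImage

__all__ = [
    "TrainHyperParams",
    "TrainedModel",
    "extract_features",
    "pooled_features",
    "train_head",
    "predict",
    "predict_batch",
    "save_model",
    "load_model",
]

LABEL_TO_INDEX = {lab: i for i, lab in enumerate(LABELS)}


@dataclass(frozen=True)
class TrainHyperParams:
    epochs: int = 60
    batch_size: int = 32
    learning_rate: float = 0.2  # fixed step size on standardized features
    momentum: float = 0.9
    weight_decay: float = 3e-3
    init_scale: float = 0.01  # SD of the seeded head initialisation


@dataclass
class TrainedModel:
    """Frozen backbone + trained head + the preprocessing it expects."""

    backbone: Backbone
    head_weight: np.ndarray  # 3 x n_features
    head_bias: np.ndarray  # 3
    feat_mean: np.ndarray  # n_features
    feat_sd: np.ndarray  # n_features
    label_order: tuple[str, str, str] = LABELS
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    training_log: list[dict] = field(default_factory=list)
    seed: int | None = None

    def scores(self, pooled: np.ndarray) -> np.ndarray:
        """Pre-softmax class scores for pooled feature vector(s)."""
        z = (np.atleast_2d(pooled) - self.feat_mean) / self.feat_sd
        out = z @ self.head_weight.T + self.head_bias
        return out[0] if np.asarray(pooled).ndim == 1 else out


def extract_features(backbone: Backbone, preprocessed_image: np.ndarray) -> np.ndarray:
    """Final convolutional activation (channels x h x w) of one image.

    ``preprocessed_image`` is pipeline output, H x W x 3 (or channels-first).
    Deterministic for fixed backbone weights.
    """
    arr = np.asarray(preprocessed_image, dtype=np.float32)
    if arr.ndim == 3 and arr.shape[2] == 3 and arr.shape[0] != 3:
        arr = arr.transpose(2, 0, 1)
    return backbone.features(arr)


def pooled_features(
    backbone: Backbone,
    images: list[LabeledImage],
    config: PreprocessConfig,
    cache: dict | None = None,
) -> np.ndarray:
    """Preprocess + extract + global-average-pool a batch of images.

    ``cache`` (keyed by the image objects themselves, which also keeps them
    alive) lets repeated-trial protocols avoid recomputing features for
    images shared between trials; valid only while backbone and
    preprocessing stay fixed.
    """
    rows = []
    for im in images:
        if cache is not None and id(im) in cache:
            rows.append(cache[id(im)][1])
            continue
        x = preprocess_pipeline(im, config=config)
        arr = np.asarray(x, dtype=np.float32)
        if arr.ndim == 3 and arr.shape[2] == 3 and arr.shape[0] != 3:
            arr = arr.transpose(2, 0, 1)
        vec = backbone.pooled(arr)
        if cache is not None:
            # store the image alongside its features so its id stays unique
            cache[id(im)] = (im, vec)
        rows.append(vec)
    return np.asarray(rows, dtype=np.float64)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train_head(
    backbone: Backbone | BackboneSpec | str,
    train_set: list[LabeledImage],
    validation_set: list[LabeledImage],
    hyper: TrainHyperParams | None = None,
    seed: int = 0,
    preprocess: PreprocessConfig | None = None,
    feature_cache: dict | None = None,
) -> TrainedModel:
    """Train the 3-way head on frozen features; return the best-epoch model.

    Raises a data error if any label is missing from the training set, and a
    configuration error if the validation set is empty.
    """
    if not isinstance(backbone, Backbone):
        backbone = build_backbone(backbone)
    hyper = hyper or TrainHyperParams()
    preprocess = preprocess or PreprocessConfig()
    present = {im.label for im in train_set}
    missing = [lab for lab in LABELS if lab not in present]
    if missing:
        raise ValueError(f"training set lacks label(s) {missing}; all of {LABELS} required")
    if not validation_set:
        raise ValueError("validation set must be non-empty for model selection")

    X = pooled_features(backbone, train_set, preprocess, feature_cache)
    y = np.array([LABEL_TO_INDEX[im.label] for im in train_set])
    Xv = pooled_features(backbone, validation_set, preprocess, feature_cache)
    yv = np.array([LABEL_TO_INDEX[im.label] for im in validation_set])

    feat_mean = X.mean(axis=0)
    feat_sd = X.std(axis=0)
    feat_sd[feat_sd < 1e-9] = 1.0
    Z = (X - feat_mean) / feat_sd
    Zv = (Xv - feat_mean) / feat_sd

    rng = np.random.default_rng(seed)
    n, d = Z.shape
    W = rng.normal(0.0, hyper.init_scale, size=(3, d))
    b = np.zeros(3)
    vW, vb = np.zeros_like(W), np.zeros_like(b)
    onehot = np.eye(3)[y]

    best = {"epoch": -1, "val": -1.0, "W": W.copy(), "b": b.copy()}
    log = []
    for epoch in range(hyper.epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        for start in range(0, n, hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            zb, tb = Z[idx], onehot[idx]
            p = _softmax(zb @ W.T + b)
            total_loss += -np.sum(np.log(p[np.arange(len(idx)), y[idx]] + 1e-12))
            g = (p - tb) / len(idx)  # batch x 3
            vW = hyper.momentum * vW - hyper.learning_rate * (
                g.T @ zb + hyper.weight_decay * W
            )
            vb = hyper.momentum * vb - hyper.learning_rate * g.sum(axis=0)
            W += vW
            b += vb
        val_pred = np.argmax(Zv @ W.T + b, axis=1)
        val_conc = 100.0 * np.mean(val_pred == yv)
        log.append(
            {"epoch": epoch, "loss": total_loss / n, "val_concordance": val_conc}
        )
        # ties resolve to the later (more converged) epoch
        if val_conc >= best["val"]:
            best = {"epoch": epoch, "val": val_conc, "W": W.copy(), "b": b.copy()}

    return TrainedModel(
        backbone=backbone,
        head_weight=best["W"],
        head_bias=best["b"],
        feat_mean=feat_mean,
        feat_sd=feat_sd,
        preprocess=preprocess,
        training_log=log,
        seed=seed,
    )


def predict(
    model: TrainedModel, raw_image, mask: np.ndarray | None = None
) -> tuple[str, np.ndarray]:
    """Classify one raw image: preprocess with the model's stored config,
    extract frozen features, apply the head.

    Returns ``(label, class_scores)``; ties in the argmax resolve to the
    lowest label index (A < B < C).
    """
    x = preprocess_pipeline(raw_image, mask=mask, config=model.preprocess)
    arr = np.asarray(x, dtype=np.float32).transpose(2, 0, 1)
    vec = model.backbone.pooled(arr)
    scores = model.scores(vec)
    label = model.label_order[int(np.argmax(scores))]  # argmax takes first maximum
    return label, scores


def predict_batch(
    model: TrainedModel, images: list[LabeledImage], feature_cache: dict | None = None
) -> list[str]:
    """Predicted labels for a list of images, order-preserving."""
    if not images:
        return []
    vecs = pooled_features(model.backbone, images, model.preprocess, feature_cache)
    scores = model.scores(vecs)
    return [model.label_order[i] for i in np.argmax(scores, axis=1)]


_CHECKPOINT_VERSION = 1


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model to a single version-tagged ``.npz`` container."""
    meta = {
        "version": _CHECKPOINT_VERSION,
        "backbone_spec": asdict(model.backbone.spec),
        "label_order": list(model.label_order),
        "preprocess": {**asdict(model.preprocess),
                       "stage_order": list(model.preprocess.stage_order),
                       "white_value": list(model.preprocess.white_value)},
        "training_log": model.training_log,
        "seed": model.seed,
    }
    arrays = {
        "head_weight": model.head_weight,
        "head_bias": model.head_bias,
        "feat_mean": model.feat_mean,
        "feat_sd": model.feat_sd,
    }
    for key, arr in model.backbone.state_dict().items():
        arrays[f"backbone/{key}"] = arr
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]))
        if meta["version"] != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        spec = BackboneSpec(**meta["backbone_spec"])
        backbone = build_backbone(spec)
        state = {
            key[len("backbone/"):]: data[key]
            for key in data.files
            if key.startswith("backbone/")
        }
        backbone.load_weights(state)
        pp = meta["preprocess"]
        preprocess = PreprocessConfig(
            **{**pp, "stage_order": tuple(pp["stage_order"]),
               "white_value": tuple(pp["white_value"])}
        )
        return TrainedModel(
            backbone=backbone,
            head_weight=data["head_weight"],
            head_bias=data["head_bias"],
            feat_mean=data["feat_mean"],
            feat_sd=data["feat_sd"],
            label_order=tuple(meta["label_order"]),
            preprocess=preprocess,
            training_log=meta["training_log"],
            seed=meta["seed"],
        )
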