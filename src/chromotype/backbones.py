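"""Frozen convolutional feature extractors for transfer-style training.

Three compact backbone families are provided, mirroring the two reference
architectures used for chromosome-shape transfer learning plus a small
fallback:

* ``fire_module`` — stacked squeeze/expand (1x1 / 3x3) blocks in the style
  of lightweight SqueezeNet-type networks;
* ``residual_block`` — convolutional stages with identity shortcuts in the
  style of ResNet-type networks;
* ``small_scratch`` — a plain, wide three-stage convolutional stack.

All backbones are *frozen*: their weights are fixed at construction (seeded
He initialisation by default, or externally supplied pretrained weights via
``load_weights``) and are never touched by head training.  Features are the
final convolutional activation; a global average pool reduces them to the
vector the classification head consumes.

Because chromosome crops arrive at arbitrary orientation, the pooled
feature vector is by default averaged over the eight exact square
symmetries of the input (4 rotations x optional mirror).  This dihedral
pooling makes the features approximately orientation-invariant without any
training and is purely deterministic; it can be disabled in the spec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, Fire, GlobalAvgPool, MaxPool2d, ReLU, Residual, Sequential

__all__ = ["BackboneSpec", "Backbone", "build_backbone", "BACKBONE_FAMILIES"]

BACKBONE_FAMILIES = ("fire_module", "residual_block", "small_scratch")


@dataclass(frozen=True)
class BackboneSpec:
    """Declarative description of a frozen feature extractor."""

    family: str = "small_scratch"
    input_size: int = 224
    #: seed for the frozen weight initialisation (pretrained weights override)
    weight_seed: int = 12345
    pretrained: bool = False
    frozen: bool = True
    #: average pooled features over the 8 dihedral views of the input
    dihedral_pool: bool = True

    def __post_init__(self) -> None:
        if self.family not in BACKBONE_FAMILIES:
            raise ValueError(
                f"family must be one of {BACKBONE_FAMILIES}, got {self.family!r}"
            )
        if not self.frozen:
            raise ValueError("backbones are used as fixed feature extractors only")


def _build_small_scratch(rng) -> Sequential:
    return Sequential([
        ("conv1", Conv2d(3, 48, 11, stride=4, pad=5, rng=rng)),
        ("relu1", ReLU()),
        ("pool1", MaxPool2d(2)),           # 48 x 28 x 28
        ("conv2", Conv2d(48, 128, 5, pad=2, rng=rng)),
        ("relu2", ReLU()),
        ("pool2", MaxPool2d(2)),           # 128 x 14 x 14
        ("conv3", Conv2d(128, 256, 3, pad=1, rng=rng)),
        ("relu3", ReLU()),                 # 256 x 14 x 14
    ])


def _build_fire(rng) -> Sequential:
    return Sequential([
        ("conv1", Conv2d(3, 16, 3, stride=2, pad=1, rng=rng)),
        ("relu1", ReLU()),
        ("pool1", MaxPool2d(2)),          # 16 x 56 x 56
        ("fire2", Fire(16, 8, 16, rng)),  # 32 x 56 x 56
        ("pool2", MaxPool2d(2)),          # 32 x 28 x 28
        ("fire3", Fire(32, 16, 24, rng)),  # 48 x 28 x 28
        ("pool3", MaxPool2d(2)),          # 48 x 14 x 14
        ("fire4", Fire(48, 16, 32, rng)),  # 64 x 14 x 14
        ("pool4", MaxPool2d(2)),          # 64 x 7 x 7
    ])


def _build_residual(rng) -> Sequential:
    return Sequential([
        ("conv1", Conv2d(3, 16, 7, stride=2, pad=3, rng=rng)),
        ("relu1", ReLU()),
        ("pool1", MaxPool2d(2)),               # 16 x 56 x 56
        ("res2", Residual(16, 32, 2, rng)),    # 32 x 28 x 28
        ("res3", Residual(32, 64, 2, rng)),    # 64 x 14 x 14
        ("res4", Residual(64, 64, 1, rng)),    # 64 x 14 x 14
        ("pool4", MaxPool2d(2)),               # 64 x 7 x 7
    ])


_BUILDERS = {
    "small_scratch": _build_small_scratch,
    "fire_module": _build_fire,
    "residual_block": _build_residual,
}


class Backbone:
    """A frozen feature extractor with named internal activations."""

    def __init__(self, spec: BackboneSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.weight_seed)
        self.net = _BUILDERS[spec.family](rng)
        self.pool = GlobalAvgPool()
        probe = np.zeros((3, spec.input_size, spec.input_size), dtype=np.float32)
        feat = self.net.forward(probe)
        self.feature_shape = feat.shape  # channels x h x w
        self.n_features = feat.shape[0]

    @property
    def last_conv_layer(self) -> str:
        """Name of the last layer producing a spatial activation map."""
        return self.net.names[-1]

    def features(self, image_chw: np.ndarray, record: bool = False):
        """Final convolutional activation for one preprocessed image.

        ``image_chw`` is channels-first float; with ``record=True`` also
        returns the dict of every named intermediate activation.
        """
        x = np.ascontiguousarray(image_chw, dtype=np.float32)
        if x.shape != (3, self.spec.input_size, self.spec.input_size):
            raise ValueError(
                f"expected input of shape (3, {self.spec.input_size}, "
                f"{self.spec.input_size}), got {x.shape}"
            )
        return self.net.forward(x, record=record)

    def pooled(self, image_chw: np.ndarray) -> np.ndarray:
        """Globally averaged feature vector (length ``n_features``).

        With ``dihedral_pool`` (default) the vector is the mean over the
        eight square-symmetry views of the input, making it approximately
        invariant to crop orientation.
        """
        x = np.ascontiguousarray(image_chw, dtype=np.float32)
        if not self.spec.dihedral_pool:
            return self.pool.forward(self.features(x))
        total = None
        for flip in (False, True):
            base = x[:, :, ::-1] if flip else x
            for rot in range(4):
                view = np.ascontiguousarray(np.rot90(base, rot, axes=(1, 2)))
                vec = self.pool.forward(self.features(view))
                total = vec if total is None else total + vec
        return total / 8.0

    # -- weight access (hashing / optional pretrained plug-in) ---------------

    def _conv_layers(self):
        for name, layer in self.net.layers:
            if isinstance(layer, Conv2d):
                yield name, layer
            elif isinstance(layer, Fire):
                yield from (
                    (f"{name}.{sub}", getattr(layer, sub))
                    for sub in ("squeeze", "expand1", "expand3")
                )
            elif isinstance(layer, Residual):
                subs = ["conv1", "conv2"] + (["proj"] if layer.proj is not None else [])
                yield from ((f"{name}.{sub}", getattr(layer, sub)) for sub in subs)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for name, conv in self._conv_layers():
            state[f"{name}.weight"] = conv.weight
            if conv.bias is not None:
                state[f"{name}.bias"] = conv.bias
        return state

    def load_weights(self, state: dict[str, np.ndarray]) -> None:
        """Install externally supplied (e.g. pretrained) weights in place."""
        for name, conv in self._conv_layers():
            conv.weight = np.asarray(state[f"{name}.weight"], dtype=np.float32)
            if conv.bias is not None:
                conv.bias = np.asarray(state[f"{name}.bias"], dtype=np.float32)

    def weights_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for key in sorted(self.state_dict()):
            h.update(key.encode())
            h.update(np.ascontiguousarray(self.state_dict()[key]).tobytes())
        return h.hexdigest()


def build_backbone(spec: BackboneSpec | str) -> Backbone:
    """Construct a frozen backbone from a spec (or family name)."""
    if isinstance(spec, str):
        spec = BackboneSpec(family=spec)
    return Backbone(spec)
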