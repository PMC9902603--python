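"""Grad-CAM saliency maps over the frozen-backbone classifier.

Grad-CAM weights each feature map of a chosen convolutional layer by the
spatial mean of the gradient of the (pre-softmax) class score with respect
to that map, sums, and rectifies:

    map = ReLU( sum_k alpha_k A_k ),   alpha_k = mean_ij d(score_c)/dA_k[ij]

The map is normalized by its maximum (when positive) and bilinearly
upsampled to the input resolution.  The gradient is taken on the class
*score*, not the softmax probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .classify import TrainedModel, LABEL_TO_INDEX
from .preprocess import to_uint8_preview

__all__ = ["SaliencyMap", "Overlay", "grad_cam", "overlay"]


@dataclass
class SaliencyMap:
    values: np.ndarray  # h x w in [0,1] at feature resolution
    upsampled: np.ndarray  # H x W in [0,1] at input resolution
    target_class: str
    layer_id: str

    def center_of_mass(self) -> tuple[float, float]:
        """(row, col) intensity-weighted centroid of the upsampled map."""
        total = self.upsampled.sum()
        if total == 0:
            h, w = self.upsampled.shape
            return ((h - 1) / 2.0, (w - 1) / 2.0)
        rr, cc = np.indices(self.upsampled.shape)
        return (
            float((rr * self.upsampled).sum() / total),
            float((cc * self.upsampled).sum() / total),
        )


def grad_cam(
    model: TrainedModel,
    preprocessed_image: np.ndarray,
    target_class: str,
    layer_id: str | None = None,
) -> SaliencyMap:
    """Class-discriminative saliency for one preprocessed image.

    ``layer_id`` names a backbone activation (default: the last
    convolutional activation).  The gradient of the target class's
    pre-softmax score is backpropagated to that activation through the
    frozen network.
    """
    if target_class not in LABEL_TO_INDEX:
        raise ValueError(f"target_class must be one of {tuple(LABEL_TO_INDEX)}")
    backbone = model.backbone
    if layer_id is None:
        layer_id = backbone.last_conv_layer
    if layer_id not in backbone.net.names:
        raise KeyError(
            f"layer {layer_id!r} not in backbone; available: {backbone.net.names}"
        )

    arr = np.asarray(preprocessed_image, dtype=np.float32)
    if arr.ndim == 3 and arr.shape[2] == 3 and arr.shape[0] != 3:
        arr = arr.transpose(2, 0, 1)
    feat, acts = backbone.features(arr, record=True)
    c_idx = LABEL_TO_INDEX[target_class]

    # d(score)/d(pooled features): the head is affine on standardized pooled
    # features, so the gradient is the class row rescaled by the feature SDs.
    d_pooled = model.head_weight[c_idx] / model.feat_sd
    ch, fh, fw = feat.shape
    d_feat = np.broadcast_to(
        (d_pooled / (fh * fw)).astype(np.float32)[:, None, None], (ch, fh, fw)
    ).copy()
    grad = backbone.net.backward_to(d_feat, layer_id)

    activation = acts[layer_id]
    alpha = grad.mean(axis=(1, 2))
    cam = np.maximum((alpha[:, None, None] * activation).sum(axis=0), 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    input_size = arr.shape[1:]
    up = _sk_resize(cam, input_size, order=1, preserve_range=True, mode="reflect")
    up = np.clip(up, 0.0, 1.0)
    return SaliencyMap(
        values=cam, upsampled=up, target_class=target_class, layer_id=layer_id
    )


@dataclass
class Overlay:
    """Heat-map blend; the original image is recoverable from the stored alpha."""

    image: np.ndarray  # H x W x 3 uint8 blended render
    alpha: np.ndarray  # H x W per-pixel blend weight actually applied
    heat: np.ndarray  # H x W x 3 float colormap image (0-255)
    original: np.ndarray  # H x W x 3 float original pixels

    def recover_original(self) -> np.ndarray:
        """Invert the blend: (blended - alpha*heat) / (1 - alpha)."""
        blended = self._blended_float
        a = self.alpha[:, :, None]
        return (blended - a * self.heat) / np.clip(1.0 - a, 1e-9, None)


def overlay(
    image, saliency: SaliencyMap, colormap_name: str = "jet", max_alpha: float = 0.5
) -> Overlay:
    """Blend a saliency map over an image with a matplotlib colormap.

    Per-pixel blend weight is ``max_alpha * map``, so a zero map returns the
    image unchanged.  Deterministic.
    """
    import matplotlib

    arr = np.asarray(getattr(image, "pixels", image), dtype=np.float64)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.shape[:2] != saliency.upsampled.shape:
        raise ValueError(
            f"image size {arr.shape[:2]} does not match saliency map "
            f"{saliency.upsampled.shape}"
        )
    cmap = matplotlib.colormaps[colormap_name]
    heat = cmap(saliency.upsampled)[:, :, :3] * 255.0
    a = max_alpha * saliency.upsampled
    blended = (1.0 - a[:, :, None]) * arr + a[:, :, None] * heat
    out = Overlay(
        image=to_uint8_preview(blended), alpha=a, heat=heat, original=arr
    )
    out._blended_float = blended
    return out
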