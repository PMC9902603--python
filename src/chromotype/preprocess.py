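"""Image preprocessing chain applied before feature extraction.

The chain normalises cropped bright-field chromosome images so the model
sees shape rather than staining:

1. **white-out** — pixels belonging to extraneous objects (other chromosomes,
   photobombing fragments) are replaced with pure white (255, 255, 255);
2. **resize** — stretch to a square ``output_size`` (default 224), matching
   the input size of the feature extractors;
3. **contrast/brightness** — affine ``dst = alpha * src + beta`` per channel,
   clipped to [0, 255];
4. **gamma** — power-law ``y = (x / 255) ** gamma * 255``;
5. **standardization** — each RGB channel affinely rescaled so its sample
   mean and SD equal fixed targets (default 64 / 16), removing per-image
   differences in staining shade.

Defaults are ``alpha=3.0, beta=80.0, gamma=3.0``; the standardized output is
kept as real (unclipped) values — clipping would destroy the fixed mean/SD.
The stage order is recorded in the config and may be permuted for
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "PreprocessConfig",
    "DegenerateChannelError",
    "whiteout",
    "resize_image",
    "contrast_brightness",
    "gamma_correct",
    "standardize_channels",
    "preprocess_pipeline",
    "to_uint8_preview",
]

DEFAULT_STAGE_ORDER = ("whiteout", "resize", "contrast_brightness", "gamma", "standardize")


class DegenerateChannelError(ValueError):
    """A channel has zero sample SD and cannot be standardized."""


@dataclass(frozen=True)
class PreprocessConfig:
    alpha: float = 3.0  # contrast multiplier
    beta: float = 80.0  # brightness offset, 8-bit units
    gamma: float = 3.0  # gamma exponent
    target_mean: float = 64.0  # per-channel mean after standardization
    target_sd: float = 16.0  # per-channel SD after standardization
    output_size: int = 224
    white_value: tuple[int, int, int] = (255, 255, 255)
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.target_sd <= 0:
            raise ValueError("target_sd must be > 0")
        if self.output_size < 8:
            raise ValueError("output_size must be >= 8")
        if set(self.stage_order) != set(DEFAULT_STAGE_ORDER):
            raise ValueError(
                f"stage_order must be a permutation of {DEFAULT_STAGE_ORDER}"
            )


def _as_rgb_array(image) -> np.ndarray:
    """Accept LabeledImage or ndarray; grayscale is replicated to 3 channels."""
    pixels = getattr(image, "pixels", image)
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {arr.shape}")
    if arr.shape[0] == 0 or arr.shape[1] == 0:
        raise ValueError("image has a zero dimension")
    return arr


def whiteout(image, exclusion_mask: np.ndarray, white_value=(255, 255, 255)) -> np.ndarray:
    """Replace masked pixels with white; all other pixels are untouched."""
    arr = _as_rgb_array(image)
    mask = np.asarray(exclusion_mask, dtype=bool)
    if mask.shape != arr.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {arr.shape[:2]}"
        )
    out = arr.copy()
    out[mask] = np.asarray(white_value, dtype=np.float64)
    return out


def resize_image(image, output_size: int, order: int = 1) -> np.ndarray:
    """Stretch to ``output_size`` x ``output_size`` (no aspect padding).

    Bilinear by default (``order=1``) with a Gaussian anti-alias prefilter
    when downscaling, which keeps the image mean under area-style averaging;
    ``order=0`` selects nearest-neighbour.  A same-size call is an exact
    identity.
    """
    arr = _as_rgb_array(image)
    if output_size < 1:
        raise ValueError("output_size must be >= 1")
    if arr.shape[0] == output_size and arr.shape[1] == output_size:
        return arr.copy()
    downscaling = arr.shape[0] > output_size or arr.shape[1] > output_size
    out = _sk_resize(
        arr,
        (output_size, output_size, 3),
        order=order,
        anti_aliasing=downscaling and order > 0,
        preserve_range=True,
        mode="reflect",
    )
    return np.clip(out, 0.0, 255.0)


def contrast_brightness(image, alpha: float = 3.0, beta: float = 80.0) -> np.ndarray:
    """Affine contrast/brightness ``clip(alpha * src + beta, 0, 255)``."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    arr = _as_rgb_array(image)
    return np.clip(alpha * arr + beta, 0.0, 255.0)


def gamma_correct(image, gamma: float = 3.0) -> np.ndarray:
    """Power-law correction ``(x / 255) ** gamma * 255`` per channel.

    Fixes 0 and 255; monotone non-decreasing for gamma > 0.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    arr = _as_rgb_array(image)
    return (np.clip(arr, 0.0, 255.0) / 255.0) ** gamma * 255.0


def standardize_channels(
    image, target_mean: float = 64.0, target_sd: float = 16.0
) -> np.ndarray:
    """Force each channel's sample mean/SD to fixed targets (affine rescale).

    Output is real-valued and deliberately unclipped.  A constant channel
    cannot be rescaled and raises :class:`DegenerateChannelError`.
    """
    arr = _as_rgb_array(image)
    out = np.empty_like(arr)
    for c, name in enumerate("RGB"):
        chan = arr[:, :, c]
        sd = chan.std()
        if sd < 1e-9:
            raise DegenerateChannelError(
                f"channel {name} is constant (SD=0) and cannot be standardized"
            )
        out[:, :, c] = (chan - chan.mean()) / sd * target_sd + target_mean
    return out


def preprocess_pipeline(
    image, mask: np.ndarray | None = None, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Run the full preprocessing chain; returns a float H x W x 3 array.

    The stage order comes from ``config.stage_order``.  When ``mask`` is None
    and the image is a synthetic one carrying a ground-truth fragment mask,
    that mask is used for white-out automatically.
    """
    config = config or PreprocessConfig()
    arr = _as_rgb_array(image)
    if mask is None:
        geometry = getattr(image, "geometry", None)
        if geometry is not None and geometry.fragment_mask is not None:
            mask = geometry.fragment_mask
    stages = {
        "whiteout": lambda a: whiteout(a, mask, config.white_value)
        if mask is not None
        else a,
        "resize": lambda a: resize_image(a, config.output_size),
        "contrast_brightness": lambda a: contrast_brightness(a, config.alpha, config.beta),
        "gamma": lambda a: gamma_correct(a, config.gamma),
        "standardize": lambda a: standardize_channels(
            a, config.target_mean, config.target_sd
        ),
    }
    for stage in config.stage_order:
        arr = stages[stage](arr)
    return arr


def to_uint8_preview(image: np.ndarray) -> np.ndarray:
    """Clip/round a (possibly standardized) float image to uint8 for display."""
    return np.clip(np.rint(np.asarray(image)), 0, 255).astype(np.uint8)
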