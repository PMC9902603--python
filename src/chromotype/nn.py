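"""Minimal NumPy convolutional layers with input-gradient backpropagation.

Supports exactly what the frozen feature extractors need: 2-D convolution
(im2col), ReLU, non-overlapping max pooling, channel concatenation (fire
modules), additive shortcuts (residual blocks), and global average pooling.
Weights are never trained — only the classification head is — so layers
implement ``backward`` for input gradients only, which is all Grad-CAM
requires.

Arrays are channels-first ``(C, H, W)`` float32.  All operations are
deterministic for fixed weights.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Fire",
    "Residual",
    "Sequential",
]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    out_h = (x.shape[1] - kh) // stride + 1
    out_w = (x.shape[2] - kw) // stride + 1
    s0, s1, s2 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(c, out_h, out_w, kh, kw),
        strides=(s0, s1 * stride, s2 * stride, s1, s2),
        writeable=False,
    )
    cols = windows.transpose(1, 2, 0, 3, 4).reshape(out_h * out_w, c * kh * kw)
    return cols, out_h, out_w


class Conv2d:
    """2-D convolution (cross-correlation) with frozen weights."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=0, rng=None, bias=True):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_in = in_ch * kernel * kernel
        if rng is None:
            rng = np.random.default_rng(0)
        # He initialisation, appropriate for ReLU nonlinearities
        self.weight = (rng.standard_normal((out_ch, in_ch, kernel, kernel))
                       * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.bias = np.zeros(out_ch, dtype=np.float32) if bias else None
        self._x_shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        cols, oh, ow = _im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        wmat = self.weight.reshape(self.out_ch, -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out = out + self.bias
        return out.T.reshape(self.out_ch, oh, ow)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Gradient w.r.t. the input (weights are frozen)."""
        c, h, w = self._x_shape
        k, s, p = self.kernel, self.stride, self.pad
        oc, oh, ow = dy.shape
        wmat = self.weight.reshape(oc, -1)  # oc x (c*k*k)
        dcols = dy.reshape(oc, -1).T @ wmat  # (oh*ow) x (c*k*k)
        dx_pad = np.zeros((c, h + 2 * p, w + 2 * p), dtype=np.float32)
        dcols = dcols.reshape(oh, ow, c, k, k)
        for i in range(k):
            for j in range(k):
                dx_pad[:, i : i + oh * s : s, j : j + ow * s : s] += dcols[
                    :, :, :, i, j
                ].transpose(2, 0, 1)
        return dx_pad[:, p : p + h, p : p + w] if p else dx_pad


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return (dy * self._mask).astype(np.float32)


class MaxPool2d:
    """Non-overlapping max pooling; trailing rows/cols are truncated."""

    def __init__(self, size=2):
        self.size = size

    def forward(self, x):
        s = self.size
        c, h, w = x.shape
        oh, ow = h // s, w // s
        self._x_shape = x.shape
        view = x[:, : oh * s, : ow * s].reshape(c, oh, s, ow, s)
        flat = view.transpose(0, 1, 3, 2, 4).reshape(c, oh, ow, s * s)
        self._argmax = flat.argmax(axis=3)
        return flat.max(axis=3)

    def backward(self, dy):
        s = self.size
        c, h, w = self._x_shape
        oh, ow = dy.shape[1], dy.shape[2]
        dx = np.zeros((c, oh, ow, s * s), dtype=np.float32)
        idx = np.indices(self._argmax.shape)
        dx[idx[0], idx[1], idx[2], self._argmax] = dy
        dx = dx.reshape(c, oh, ow, s, s).transpose(0, 1, 3, 2, 4).reshape(
            c, oh * s, ow * s
        )
        full = np.zeros((c, h, w), dtype=np.float32)
        full[:, : oh * s, : ow * s] = dx
        return full


class GlobalAvgPool:
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        c, h, w = self._shape
        return (np.broadcast_to(dy[:, None, None], (c, h, w)) / (h * w)).astype(
            np.float32
        )


class Fire:
    """Squeeze (1x1) then parallel expand (1x1 and 3x3) with concatenation."""

    def __init__(self, in_ch, squeeze_ch, expand_ch, rng):
        self.squeeze = Conv2d(in_ch, squeeze_ch, 1, rng=rng)
        self.relu_s = ReLU()
        self.expand1 = Conv2d(squeeze_ch, expand_ch, 1, rng=rng)
        self.expand3 = Conv2d(squeeze_ch, expand_ch, 3, pad=1, rng=rng)
        self.relu_e = ReLU()
        self.out_ch = 2 * expand_ch

    def forward(self, x):
        s = self.relu_s.forward(self.squeeze.forward(x))
        e = np.concatenate([self.expand1.forward(s), self.expand3.forward(s)], axis=0)
        return self.relu_e.forward(e)

    def backward(self, dy):
        dy = self.relu_e.backward(dy)
        half = self.expand1.out_ch
        ds = self.expand1.backward(dy[:half]) + self.expand3.backward(dy[half:])
        ds = self.relu_s.backward(ds)
        return self.squeeze.backward(ds)


class Residual:
    """conv-ReLU-conv plus identity (or 1x1 projection) shortcut, then ReLU."""

    def __init__(self, in_ch, out_ch, stride, rng):
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, pad=1, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, pad=1, rng=rng)
        self.proj = (
            Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng, bias=False)
            if (in_ch != out_ch or stride != 1)
            else None
        )
        self.relu_out = ReLU()
        self.out_ch = out_ch

    def forward(self, x):
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        shortcut = self.proj.forward(x) if self.proj is not None else x
        return self.relu_out.forward(y + shortcut)

    def backward(self, dy):
        dy = self.relu_out.backward(dy)
        d_main = self.conv1.backward(self.relu1.backward(self.conv2.backward(dy)))
        d_short = self.proj.backward(dy) if self.proj is not None else dy
        return d_main + d_short


class Sequential:
    """Named layer chain with forward activation recording and backprop."""

    def __init__(self, layers: list[tuple[str, object]]):
        self.layers = layers

    @property
    def names(self):
        return [n for n, _ in self.layers]

    def forward(self, x: np.ndarray, record: bool = False):
        acts = {}
        for name, layer in self.layers:
            x = layer.forward(x)
            if record:
                acts[name] = x
        return (x, acts) if record else x

    def backward_to(self, dy: np.ndarray, layer_name: str) -> np.ndarray:
        """Backpropagate an output gradient to the activation of ``layer_name``.

        Must be called after ``forward`` (layers cache their inputs).
        Returns the gradient w.r.t. the *output* of the named layer.
        """
        names = self.names
        if layer_name not in names:
            raise KeyError(f"unknown layer {layer_name!r}; have {names}")
        stop = names.index(layer_name)
        for name, layer in reversed(self.layers[stop + 1 :]):
            dy = layer.backward(dy)
        return dy
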