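"""DenseNet-201 feature encoder implemented directly on numpy.

Only the inference path needed for feature extraction is provided: the
stem, the four dense blocks with their transitions, and the concatenation
output of the last dense block (the ``conv5_block32_concat`` tensor in the
Keras layer naming), globally average-pooled to a 1,920-vector.

The network can be instantiated *weight-free*: convolution kernels are then
drawn from a seeded He-normal distribution and batch-norm layers act as
identities.  That mode yields deterministic, architecture-faithful features
and verifies the output dimensionality without any download.  Pretrained
ImageNet kernels can be supplied as an ``.npz`` mapping layer names to
``(kh, kw, cin, cout)`` arrays (plus ``<name>/gamma|beta|mean|var`` entries
for batch norm) to reproduce transfer-learning features exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["DenseNet201Features", "FEATURE_DIM", "IMAGENET_MEAN",
           "IMAGENET_STD"]

#: Channel count of the conv5_block32_concat tensor:
#: 64 initial channels, growth rate 32, blocks of (6, 12, 48, 32) layers,
#: channel-halving transitions -> 896 + 32*32 = 1920.
FEATURE_DIM = 1920

BLOCK_CONFIG = (6, 12, 48, 32)
GROWTH_RATE = 32

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1,
            pad: int = 0) -> np.ndarray:
    """NHWC-free single-image convolution via im2col + BLAS matmul."""
    kh, kw, cin, cout = w.shape
    if pad:
        x = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    if kh == kw == 1:
        out = x[::stride, ::stride] @ w.reshape(cin, cout)
        return out
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(0, 1))
    win = win[::stride, ::stride]                  # (ho, wo, cin, kh, kw)
    ho, wo = win.shape[:2]
    col = win.transpose(0, 1, 3, 4, 2).reshape(ho * wo, kh * kw * cin)
    return (col @ w.reshape(kh * kw * cin, cout)).reshape(ho, wo, cout)


def _maxpool(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    if pad:
        x = np.pad(x, ((pad, pad), (pad, pad), (0, 0)),
                   constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(0, 1))
    return win[::stride, ::stride].max(axis=(-1, -2))


def _avgpool2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    return x[: h // 2 * 2, : w // 2 * 2].reshape(
        h // 2, 2, w // 2, 2, c).mean(axis=(1, 3))


class DenseNet201Features:
    """Forward pass of DenseNet-201 up to the pooled final concatenation.

    Parameters
    ----------
    weights : optional path to an ``.npz`` with pretrained kernels.  When
        omitted the network is weight-free (seeded He-normal kernels,
        identity batch norm).
    seed : seed for weight-free kernel generation; ignored when pretrained
        weights are given.
    """

    def __init__(self, weights: str | Path | None = None, seed: int = 0):
        self._loaded = dict(np.load(weights)) if weights is not None else None
        self._rng = np.random.default_rng(seed)
        self._cache: dict[str, np.ndarray] = {}
        self.pretrained = weights is not None

    # -- parameters ------------------------------------------------------
    def _kernel(self, name: str, shape: tuple[int, ...]) -> np.ndarray:
        if self._loaded is not None:
            return self._loaded[name].astype(np.float32)
        if name not in self._cache:
            fan_in = int(np.prod(shape[:3]))
            self._cache[name] = self._rng.normal(
                0.0, np.sqrt(2.0 / fan_in), shape).astype(np.float32)
        return self._cache[name]

    def _bn_relu(self, name: str, x: np.ndarray) -> np.ndarray:
        if self._loaded is not None:
            g = self._loaded[f"{name}/gamma"].astype(np.float32)
            b = self._loaded[f"{name}/beta"].astype(np.float32)
            m = self._loaded[f"{name}/mean"].astype(np.float32)
            v = self._loaded[f"{name}/var"].astype(np.float32)
            x = g * (x - m) / np.sqrt(v + 1.001e-5) + b
        return np.maximum(x, 0.0)

    # -- architecture ----------------------------------------------------
    def _dense_layer(self, block: int, layer: int, x: np.ndarray) -> np.ndarray:
        tag = f"conv{block}_block{layer}"
        y = self._bn_relu(f"{tag}_0_bn", x)
        y = _conv2d(y, self._kernel(f"{tag}_1_conv",
                                    (1, 1, y.shape[2], 4 * GROWTH_RATE)))
        y = self._bn_relu(f"{tag}_1_bn", y)
        y = _conv2d(y, self._kernel(f"{tag}_2_conv",
                                    (3, 3, 4 * GROWTH_RATE, GROWTH_RATE)),
                    pad=1)
        return np.concatenate([x, y], axis=2)

    def _transition(self, idx: int, x: np.ndarray) -> np.ndarray:
        x = self._bn_relu(f"pool{idx}_bn", x)
        x = _conv2d(x, self._kernel(f"pool{idx}_conv",
                                    (1, 1, x.shape[2], x.shape[2] // 2)))
        return _avgpool2(x)

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Pooled 1,920-vector for one 224x224x3 image in [0, 255]."""
        if image.shape != (224, 224, 3):
            raise ValueError(f"expected a 224x224x3 input, got {image.shape}")
        x = image.astype(np.float32) / 255.0
        x = (x - IMAGENET_MEAN) / IMAGENET_STD
        x = np.pad(x, ((3, 3), (3, 3), (0, 0)))
        x = _conv2d(x, self._kernel("conv1/conv", (7, 7, 3, 64)), stride=2)
        x = self._bn_relu("conv1/bn", x)
        x = _maxpool(x, 3, 2, 1)
        for b, n_layers in enumerate(BLOCK_CONFIG, start=2):
            for layer in range(1, n_layers + 1):
                x = self._dense_layer(b, layer, x)
            if b < len(BLOCK_CONFIG) + 1:
                x = self._transition(b, x)
        # conv5_block32_concat output, globally average-pooled
        return x.mean(axis=(0, 1)).astype(np.float64)
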