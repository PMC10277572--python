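"""Slice-wise deep feature extraction with cross-slice pooling.

Each polar slice passes independently through a frozen convolutional
backbone producing a 256×7×7 feature map; global average pooling over the
7×7 spatial grid gives a 256-vector per slice (n×256 for the stack), and an
elementwise maximum across slices collapses the stack to a single
256-vector per partition.  The max is permutation-invariant, so the result
does not depend on slice order.

The backbone is pluggable: any callable mapping an (n, C, H, W) batch to an
(n, 256, h, w) map satisfies the contract.  The default is a five-block
stride-2 convolutional network (3×3 kernels, ReLU) whose channel widths end
at 256 and whose spatial size at 224×224 input is 7×7, with seeded-random
He-initialized weights.  Random frozen weights keep the pipeline fully
reproducible offline; pretrained weights can be dropped in through
:meth:`ConvBackbone.set_weights` or :func:`load_backbone_weights`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features_hc import FeatureVector

__all__ = [
    "ConvBackbone",
    "extract_deep",
    "deep_feature_names",
    "load_backbone_weights",
]


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 2) -> np.ndarray:
    """3×3 convolution with padding 1 via im2col + matmul.

    x: (n, c_in, H, W); w: (c_out, c_in, 3, 3); returns (n, c_out, H', W')
    with H' = floor((H - 1) / stride) + 1.
    """
    n, c, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (n, c, H', W', 3, 3)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * 9)
    out = cols @ w.reshape(w.shape[0], -1).T + b
    return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)


class ConvBackbone:
    """Frozen five-block convolutional feature extractor (numpy, CPU).

    Deterministic once its weights are fixed.  At 224×224 input the final
    map is (out_channels, 7, 7); each 3×3 stride-2 block halves the spatial
    size.  Activations are ReLU, hence nonnegative outputs.
    """

    def __init__(
        self,
        seed: int = 0,
        channels: tuple[int, ...] = (16, 32, 64, 128, 256),
        in_channels: int = 3,
        dtype=np.float32,
    ) -> None:
        self.channels = tuple(channels)
        self.in_channels = in_channels
        self.out_channels = self.channels[-1]
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        fan_from = in_channels
        for c_out in self.channels:
            fan_in = fan_from * 9
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_from, 3, 3))
            self.weights.append(w.astype(dtype))
            self.biases.append(np.zeros(c_out, dtype=dtype))
            fan_from = c_out

    def set_weights(self, weights: list[np.ndarray], biases: list[np.ndarray]) -> None:
        if len(weights) != len(self.channels) or len(biases) != len(self.channels):
            raise ValueError("expected one weight/bias array per block")
        self.weights = [np.asarray(w, dtype=self.dtype) for w in weights]
        self.biases = [np.asarray(b, dtype=self.dtype) for b in biases]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (n, {self.in_channels}, H, W) input, got {x.shape}"
            )
        for w, b in zip(self.weights, self.biases):
            x = _conv2d(x, w, b)
            np.maximum(x, 0.0, out=x)  # ReLU
        return x


def load_backbone_weights(backbone: ConvBackbone, path) -> None:
    """Load weights saved with ``np.savez`` (arrays w0..wk, b0..bk)."""
    try:
        with np.load(path) as data:
            k = len(backbone.channels)
            backbone.set_weights(
                [data[f"w{i}"] for i in range(k)], [data[f"b{i}"] for i in range(k)]
            )
    except FileNotFoundError:
        raise FileNotFoundError(f"backbone weights file not found: {path!r}")


def deep_feature_names(n: int = 256, partition_tag: str = "") -> list[str]:
    suffix = f"_{partition_tag}" if partition_tag else ""
    return [f"dl_{k}{suffix}" for k in range(n)]


def extract_deep(
    stack: np.ndarray, backbone: ConvBackbone, partition_tag: str = ""
) -> FeatureVector:
    """Pool per-slice backbone maps into one fixed-length deep feature vector.

    ``stack`` is the channeled polar stack (n_slices, C, H, W).  The
    backbone must emit (n_slices, out_channels, h, w); anything else is a
    contract error.  Spatial global average pooling then cross-slice max
    pooling yield a vector of length ``backbone.out_channels`` (256 by
    default).
    """
    stack = np.asarray(stack)
    if stack.ndim != 4:
        raise ValueError(f"expected (n, C, H, W) stack, got shape {stack.shape}")
    maps = backbone(stack)
    maps = np.asarray(maps)
    expected_c = getattr(backbone, "out_channels", None)
    if maps.ndim != 4 or maps.shape[0] != stack.shape[0] or (
        expected_c is not None and maps.shape[1] != expected_c
    ):
        raise ValueError(
            f"backbone violated its contract: produced map shape {maps.shape}"
        )
    per_slice = maps.mean(axis=(2, 3))  # (n_slices, out_channels)
    pooled = per_slice.max(axis=0).astype(float)
    values = pd.Series(pooled, index=deep_feature_names(pooled.size))
    return FeatureVector(values, kind="deep", partition_tag=partition_tag)
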