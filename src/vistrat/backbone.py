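"""A compact 13-sublayer convolutional feature hierarchy.

The decoding analyses read activations from 13 named stages —
conv1, norm1, pool1, conv2, norm2, pool2, conv3, conv4, conv5, pool5,
fc6, fc7, fc8 — mirroring the sublayer division of the classic AlexNet
hierarchy.  The default backbone is a fixed-seed, randomly initialised
convolutional network operating directly on 100 x 100 grayscale input.
Random convolutional hierarchies retain the property the analyses rely on:
representational complexity increases with depth, early stages being closer
to pixel space and late stages mixing information globally.

Convolution and fully connected stages are recorded *before* rectification;
normalisation and pooling stages are recorded at their output.  Weights are
frozen: the backbone is a deterministic map from image to 13 activation
vectors.  Any object exposing ``sublayer_names``, ``layer_dims`` and
``extract_batch`` satisfies the backbone contract, so a pretrained network
can be plugged in behind the same surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SUBLAYER_NAMES = (
    "conv1", "norm1", "pool1",
    "conv2", "norm2", "pool2",
    "conv3", "conv4", "conv5", "pool5",
    "fc6", "fc7", "fc8",
)

N_SUBLAYERS = len(SUBLAYER_NAMES)

#: 1-based indices of the early and late sublayer blocks used by pair selection
EARLY_LAYERS = (1, 2, 3)
LATE_LAYERS = (11, 12, 13)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(B, C, H, W) -> (B, out_h*out_w, C*k*k) patch matrix."""
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        h, w = h + 2 * pad, w + 2 * pad
    out_h = (h - k) // stride + 1
    out_w = (w - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, c, out_h, out_w, k, k),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        writeable=False,
    )
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(b, out_h * out_w, c * k * k), out_h, out_w


def _conv(x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int = 0) -> np.ndarray:
    """Bias-free convolution. w: (out_c, in_c, k, k)."""
    out_c, in_c, k, _ = w.shape
    cols, oh, ow = _im2col(x, k, stride, pad)
    out = cols @ w.reshape(out_c, in_c * k * k).T
    return out.transpose(0, 2, 1).reshape(x.shape[0], out_c, oh, ow)


def _maxpool(x: np.ndarray, k: int = 3, stride: int = 2) -> np.ndarray:
    b, c, h, w = x.shape
    out_h = (h - k) // stride + 1
    out_w = (w - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, c, out_h, out_w, k, k),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        writeable=False,
    )
    return view.max(axis=(4, 5))


def _lrn(x: np.ndarray, size: int = 5, k: float = 2.0, alpha: float = 1e-4,
         beta: float = 0.75) -> np.ndarray:
    """Local response normalisation across channels."""
    sq = x * x
    c = x.shape[1]
    acc = np.empty_like(x)
    half = size // 2
    for ch in range(c):
        lo, hi = max(0, ch - half), min(c, ch + half + 1)
        acc[:, ch] = sq[:, lo:hi].sum(axis=1)
    return x / (k + alpha * acc) ** beta


@dataclass
class SyntheticBackbone:
    """Fixed-seed random convolutional hierarchy with the 13 named sublayers.

    Parameters
    ----------
    seed
        Seed of the frozen weight initialisation (He-scaled Gaussians).
    provenance
        Tag recorded with fitted decoders; the default backbone is
        ``"default-synthetic"``.
    """

    seed: int = 0
    provenance: str = "default-synthetic"

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)

        def he(shape):
            fan_in = int(np.prod(shape[1:]))
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        self.w_conv1 = he((8, 1, 7, 7))     # stride 3: 100 -> 32
        self.w_conv2 = he((12, 8, 5, 5))    # pad 2:  15 -> 15
        self.w_conv3 = he((16, 12, 3, 3))   # pad 1:   7 ->  7
        self.w_conv4 = he((16, 16, 3, 3))
        self.w_conv5 = he((12, 16, 3, 3))
        self.w_fc6 = he((64, 12 * 3 * 3))
        self.w_fc7 = he((48, 64))
        self.w_fc8 = he((32, 48))
        self._dims = None

    sublayer_names = SUBLAYER_NAMES

    @property
    def layer_dims(self) -> tuple[int, ...]:
        """Flattened dimensionality of each of the 13 activation vectors."""
        if self._dims is None:
            acts = self.extract_batch(np.zeros((1, 100, 100)))
            self._dims = tuple(a.shape[1] for a in acts)
        return self._dims

    def extract_batch(self, images: np.ndarray) -> list[np.ndarray]:
        """Map a (B, 100, 100) image batch to 13 flattened activation matrices.

        Conv/fc stages are recorded before ReLU; norm and pool stages at their
        output.  Raises on non-finite activations, naming the sublayer.
        """
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        if images.shape[1:] != (100, 100):
            raise ValueError(f"expected (B, 100, 100) input, got {images.shape}")
        b = images.shape[0]
        x = images[:, None]  # (B, 1, 100, 100)
        recorded: list[np.ndarray] = []

        def rec(a: np.ndarray, name: str) -> None:
            flat = a.reshape(b, -1)
            if not np.all(np.isfinite(flat)):
                raise FloatingPointError(f"non-finite activations at sublayer {name!r}")
            recorded.append(flat)

        x = _conv(x, self.w_conv1, stride=3)
        rec(x, "conv1")
        x = _lrn(np.maximum(x, 0.0))
        rec(x, "norm1")
        x = _maxpool(x)
        rec(x, "pool1")

        x = _conv(x, self.w_conv2, stride=1, pad=2)
        rec(x, "conv2")
        x = _lrn(np.maximum(x, 0.0))
        rec(x, "norm2")
        x = _maxpool(x)
        rec(x, "pool2")

        x = _conv(x, self.w_conv3, stride=1, pad=1)
        rec(x, "conv3")
        x = np.maximum(x, 0.0)
        x = _conv(x, self.w_conv4, stride=1, pad=1)
        rec(x, "conv4")
        x = np.maximum(x, 0.0)
        x = _conv(x, self.w_conv5, stride=1, pad=1)
        rec(x, "conv5")
        x = _maxpool(np.maximum(x, 0.0))
        rec(x, "pool5")

        x = x.reshape(b, -1) @ self.w_fc6.T
        rec(x, "fc6")
        x = np.maximum(x, 0.0) @ self.w_fc7.T
        rec(x, "fc7")
        x = np.maximum(x, 0.0) @ self.w_fc8.T
        rec(x, "fc8")
        return recorded

    def extract(self, image: np.ndarray) -> list[np.ndarray]:
        """13 activation vectors for a single image."""
        return [a[0] for a in self.extract_batch(np.asarray(image)[None])]
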