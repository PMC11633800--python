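"""Per-slice feature encoders: the f_e contract mapping a bag X to H ∈ R^{K×L}.

Each encoder maps an ordered slice stack (or precomputed feature rows) to a
K×L feature matrix, row k being the embedding of slice k, deterministically
in evaluation mode. Three encoders are provided:

``IdentityEncoder``
    Passes precomputed K×L feature rows through unchanged (feature-space
    synthetic bags, or features exported by an external backbone).

``ProjectionEncoder``
    Flatten-then-project: each slice is flattened and linearly projected to
    L dimensions. The projection is identity-initialized (``eye(L, in_dim)``)
    and trainable — the lightweight encoder used for CPU-scale experiments.

``ConvEncoder``
    A small CNN: two 3×3 convolution blocks (ReLU + max-pool) followed by
    global average pooling and a linear projection to L. Trainable end to
    end; its post-ReLU convolutional activations are the Grad-CAM target
    layers.

Grayscale slices are replicated to three channels when an encoder declares
``in_channels=3`` (the convention for RGB-pretrained backbones).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn


@dataclass
class EncoderSpec:
    """Declarative encoder configuration.

    ``name`` selects the encoder family (identity | projection | conv);
    ``output_dim`` is L; ``in_dim`` is the flattened slice size for the
    projection encoder; ``in_channels`` the conv encoder's input channels.
    """

    name: str = "conv"
    output_dim: int = 32
    pretrained: bool = False
    trainable: bool = True
    in_dim: int | None = None
    in_channels: int = 1
    channels: tuple[int, int] = (8, 16)
    pool: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")


def replicate_channels(image: np.ndarray, n: int = 3) -> np.ndarray:
    """Replicate a 2D grayscale slice into an (n, H, W) multi-channel array."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2D slice")
    return np.repeat(image[None], n, axis=0)


class Encoder:
    """Base class: forward maps (K, ...) input to (H, cache); backward returns grads."""

    out_dim: int
    trainable: bool = False
    params: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}

    def forward(self, X: np.ndarray):
        raise NotImplementedError

    def backward(self, gH: np.ndarray, cache):
        """Gradients of the loss w.r.t. encoder params given dL/dH."""
        return {}

    def encode(self, X: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", over="ignore"):
            H, _ = self.forward(X)
        if not np.all(np.isfinite(H)):
            bad = int(np.argwhere(~np.isfinite(H).all(axis=1))[0, 0])
            raise FloatingPointError(
                f"non-finite embedding for slice index {bad} (slice number {bad + 1})"
            )
        return H


class IdentityEncoder(Encoder):
    """Pass-through for precomputed K×L feature rows."""

    def __init__(self, out_dim: int):
        super().__init__()
        self.out_dim = out_dim

    def forward(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.out_dim:
            raise ValueError(f"expected (K, {self.out_dim}) features, got {X.shape}")
        return X, None


class ProjectionEncoder(Encoder):
    """Flatten each slice and apply a trainable linear projection to L dims.

    The weight is identity-initialized: with L == in_dim the encoder starts
    as the identity map, so feature-space inputs pass through unchanged at
    initialization.
    """

    def __init__(self, in_dim: int, out_dim: int, trainable: bool = True):
        super().__init__()
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.trainable = trainable
        self.params = {
            "W": np.eye(out_dim, in_dim),
            "b": np.zeros(out_dim),
        }

    def forward(self, X):
        X = np.asarray(X, dtype=float).reshape(len(X), -1)
        if X.shape[1] != self.in_dim:
            raise ValueError(f"expected flattened dim {self.in_dim}, got {X.shape[1]}")
        H, cache = _nn.linear_forward(X, self.params["W"], self.params["b"])
        return H, cache

    def backward(self, gH, cache):
        if not self.trainable:
            return {}
        _, gW, gb = _nn.linear_backward(gH, cache)
        return {"W": gW, "b": gb}


class ConvEncoder(Encoder):
    """Two conv blocks (3×3 conv → ReLU → max-pool) → GAP → linear projection.

    He-initialized from ``seed``. ``activations(X)`` exposes the post-ReLU
    conv feature maps per slice for Grad-CAM ('conv1', 'conv2').
    """

    def __init__(
        self,
        out_dim: int = 32,
        in_channels: int = 1,
        channels: tuple[int, int] = (8, 16),
        pool: int = 4,
        trainable: bool = True,
        seed: int = 0,
    ):
        super().__init__()
        rng = np.random.default_rng(seed)
        c1, c2 = channels
        self.out_dim = out_dim
        self.in_channels = in_channels
        self.pool = pool
        self.trainable = trainable
        self.params = {
            "conv1_W": rng.normal(0, np.sqrt(2.0 / (in_channels * 9)), (c1, in_channels, 3, 3)),
            "conv1_b": np.zeros(c1),
            "conv2_W": rng.normal(0, np.sqrt(2.0 / (c1 * 9)), (c2, c1, 3, 3)),
            "conv2_b": np.zeros(c2),
            "proj_W": rng.normal(0, np.sqrt(1.0 / c2), (out_dim, c2)),
            "proj_b": np.zeros(out_dim),
        }

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 2:
            if self.in_channels == 1:
                return x[None]
            return replicate_channels(x, self.in_channels)
        return x

    def _forward_slice(self, x: np.ndarray):
        p = self.params
        a1, c_conv1 = _nn.conv2d_forward(self._prepare(x), p["conv1_W"], p["conv1_b"])
        r1, m1 = _nn.relu_forward(a1)
        p1, c_pool1 = _nn.maxpool_forward(r1, self.pool)
        a2, c_conv2 = _nn.conv2d_forward(p1, p["conv2_W"], p["conv2_b"])
        r2, m2 = _nn.relu_forward(a2)
        p2, c_pool2 = _nn.maxpool_forward(r2, self.pool)
        g, c_gap = _nn.global_avgpool_forward(p2)
        h, c_lin = _nn.linear_forward(g, p["proj_W"], p["proj_b"])
        cache = dict(
            conv1=c_conv1, mask1=m1, pool1=c_pool1,
            conv2=c_conv2, mask2=m2, pool2=c_pool2,
            gap=c_gap, lin=c_lin, act1=r1, act2=r2,
        )
        return h, cache

    def forward(self, X):
        X = np.asarray(X, dtype=float)
        rows, caches = [], []
        for x in X:
            h, cache = self._forward_slice(x)
            rows.append(h)
            caches.append(cache)
        return np.stack(rows), caches

    def backward(self, gH, caches):
        if not self.trainable:
            return {}
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        for gh, cache in zip(gH, caches):
            if not np.any(gh):
                continue
            gg, gpW, gpb = _nn.linear_backward(gh, cache["lin"])
            grads["proj_W"] += gpW
            grads["proj_b"] += gpb
            gp2 = _nn.global_avgpool_backward(gg, cache["gap"])
            gr2 = _nn.maxpool_backward(gp2, cache["pool2"])
            ga2 = _nn.relu_backward(gr2, cache["mask2"])
            gp1, gW2, gb2 = _nn.conv2d_backward(ga2, cache["conv2"])
            grads["conv2_W"] += gW2
            grads["conv2_b"] += gb2
            gr1 = _nn.maxpool_backward(gp1, cache["pool1"])
            ga1 = _nn.relu_backward(gr1, cache["mask1"])
            _, gW1, gb1 = _nn.conv2d_backward(ga1, cache["conv1"])
            grads["conv1_W"] += gW1
            grads["conv1_b"] += gb1
        return grads

    def calibrate_output(self, sample_slices: np.ndarray, eps: float = 1e-6) -> None:
        """Standardize output features to zero mean / unit variance on a sample.

        Folds the per-dimension affine standardization into the final linear
        projection, so subsequent forwards (and Grad-CAM gradients) see the
        standardized features directly. Standard practice when a frozen
        feature extractor feeds a trainable head: raw GAP features live on
        arbitrary scales that swamp small between-slice differences.
        """
        H, _ = self.forward(np.asarray(sample_slices, dtype=float))
        mu = H.mean(axis=0)
        sd = H.std(axis=0) + eps
        self.params["proj_W"] /= sd[:, None]
        self.params["proj_b"][...] = (self.params["proj_b"] - mu) / sd

    def activation_gradient(self, gh: np.ndarray, cache, layer: str = "conv2") -> np.ndarray:
        """dL/d(activation) at a post-ReLU conv layer given dL/dh for one slice.

        'conv2' is the gradient w.r.t. the second block's ReLU output (the
        default Grad-CAM target); 'conv1' continues the chain down one block.
        """
        gg, _, _ = _nn.linear_backward(gh, cache["lin"])
        gp2 = _nn.global_avgpool_backward(gg, cache["gap"])
        gr2 = _nn.maxpool_backward(gp2, cache["pool2"])
        if layer == "conv2":
            return gr2
        ga2 = _nn.relu_backward(gr2, cache["mask2"])
        gp1, _, _ = _nn.conv2d_backward(ga2, cache["conv2"])
        gr1 = _nn.maxpool_backward(gp1, cache["pool1"])
        if layer == "conv1":
            return gr1
        raise ValueError(f"unknown target layer {layer!r}")


def build_encoder(spec: EncoderSpec) -> Encoder:
    """Instantiate an encoder from its spec."""
    if spec.name == "identity":
        return IdentityEncoder(spec.output_dim)
    if spec.name == "projection":
        if spec.in_dim is None:
            raise ValueError("projection encoder requires in_dim")
        return ProjectionEncoder(spec.in_dim, spec.output_dim, trainable=spec.trainable)
    if spec.name == "conv":
        return ConvEncoder(
            out_dim=spec.output_dim,
            in_channels=spec.in_channels,
            channels=spec.channels,
            pool=spec.pool,
            trainable=spec.trainable,
            seed=spec.seed,
        )
    raise ValueError(f"unknown encoder {spec.name!r}")
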