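"""Ranking-attention MIL pooling: attention scores, top-C selection, aggregation.

The model classifies a bag X = {x_1, …, x_K} of K instances via three stages:

1. **Feature extraction** — an encoder maps the bag to H ∈ R^{K×L} (row h_k).
2. **Ranking-attention pooling** — per-instance attention logits
   s_k = wᵀ tanh(V h_kᵀ) are softmax-normalized over the bag into scores
   a_k (Σ a_k = 1). The top C scores are selected by sorting in descending
   order (ties broken by the lower original index) and the bag embedding is
   the *unrescaled* weighted sum z = Σ_{c=1..C} a_c h_c — the selected
   scores keep their original softmax values, so Σ A_C ≤ 1.
3. **Classification** — a single linear unit plus sigmoid yields the bag
   probability q(X) = σ(u·z + b).

Baseline poolings (mean, max, full-bag attention, gated attention) share the
same head so variants differ only in the pooling stage. Gradients are
analytic: the softmax is computed over all K instances and the top-C gather
is a hard selection, so gradients reach selected instances directly and all
instances through the softmax denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._nn import sigmoid, stable_softmax
from .encoders import Encoder

VARIANTS = ("ramil", "attention", "gated", "mean", "max")
DEFAULT_C = 10
DEFAULT_D = 128


@dataclass
class AttentionParams:
    """Trainable attention parameters: V ∈ R^{D×L}, w ∈ R^D."""

    V: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.w = np.asarray(self.w, dtype=float).ravel()
        if self.V.ndim != 2 or self.V.shape[0] != self.w.shape[0]:
            raise ValueError("V must be (D, L) with D matching len(w)")

    @property
    def D(self) -> int:
        return self.w.shape[0]


@dataclass
class RankedSelection:
    """Top-C selection: 0-based indices, their exact (unrescaled) scores and rows."""

    indices: np.ndarray  # (C',) 0-based original instance indices
    scores: np.ndarray  # (C',) exact copies of the selected a_k
    features: np.ndarray  # (C', L)
    C: int  # configured C (C' = min(C, K))

    @property
    def slice_numbers(self) -> np.ndarray:
        """1-based slice numbers for human-facing reports."""
        return self.indices + 1


def attention_scores(H: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Softmax-normalized attention scores a_k over the K rows of H.

    a_k = exp(wᵀ tanh(V h_kᵀ)) / Σ_j exp(wᵀ tanh(V h_jᵀ)), stabilized by
    max-logit subtraction.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    if H.shape[1] != params.V.shape[1]:
        raise ValueError(
            f"feature dim {H.shape[1]} does not match V's L={params.V.shape[1]}"
        )
    logits = np.tanh(H @ params.V.T) @ params.w
    return stable_softmax(logits)


def rank_select(a: np.ndarray, H: np.ndarray, C: int) -> RankedSelection:
    """Select the top-C instances by descending score; ties keep the lower index.

    A pure gather: scores are never modified or renormalized. C is clamped
    to K when the bag is smaller than C.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    a = np.asarray(a, dtype=float).ravel()
    H = np.atleast_2d(np.asarray(H, dtype=float))
    order = np.argsort(-a, kind="stable")  # stable: ties by ascending index
    sel = order[: min(C, len(a))]
    return RankedSelection(indices=sel, scores=a[sel].copy(), features=H[sel].copy(), C=C)


def aggregate(sel: RankedSelection) -> np.ndarray:
    """Bag embedding z = Σ_c a_c h_c over the selected instances (unrescaled)."""
    return sel.scores @ sel.features


def classify(z: np.ndarray, weight: np.ndarray, bias: float) -> float:
    """Bag probability σ(weight·z + bias)."""
    return float(sigmoid(float(np.dot(weight, z)) + bias))


def pool_mean(H: np.ndarray) -> np.ndarray:
    """Column-wise mean of H."""
    return np.atleast_2d(H).mean(axis=0)


def pool_max(H: np.ndarray) -> np.ndarray:
    """Column-wise max of H."""
    return np.atleast_2d(H).max(axis=0)


def gated_attention_scores(
    H: np.ndarray, params: AttentionParams, U: np.ndarray
) -> np.ndarray:
    """Gated-attention scores: softmax of wᵀ(tanh(V h_kᵀ) ⊙ σ(U h_kᵀ))."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    t = np.tanh(H @ params.V.T)
    g = sigmoid(H @ U.T)
    return stable_softmax((t * g) @ params.w)


@dataclass
class ForwardResult:
    """Everything a forward pass produces, kept for interpretability and backprop."""

    probability: float
    logit: float
    attention: Optional[np.ndarray]  # (K,) scores, None for mean/max
    selection: Optional[RankedSelection]
    z: np.ndarray
    H: np.ndarray
    cache: dict = field(default_factory=dict, repr=False)


class MILModel:
    """A pooling variant + encoder + single-unit head, with analytic backprop.

    ``variant`` is one of 'ramil', 'attention', 'gated', 'mean', 'max'.
    'attention' is exactly 'ramil' with C = K (every instance selected).
    """

    def __init__(
        self,
        encoder: Encoder,
        variant: str = "ramil",
        C: int = DEFAULT_C,
        D: int = DEFAULT_D,
        seed: int = 0,
    ):
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        self.encoder = encoder
        self.variant = variant
        self.C = C
        self.D = D
        L = encoder.out_dim
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        if variant in ("ramil", "attention", "gated"):
            self.params["att_V"] = rng.normal(0, 1.0 / np.sqrt(L), (D, L))
            self.params["att_w"] = rng.normal(0, 1.0 / np.sqrt(D), D)
        if variant == "gated":
            self.params["att_U"] = rng.normal(0, 1.0 / np.sqrt(L), (D, L))
        self.params["head_w"] = rng.normal(0, 1.0 / np.sqrt(L), L)
        self.params["head_b"] = np.zeros(1)
        if encoder.trainable:
            for k, v in encoder.params.items():
                self.params[f"enc_{k}"] = v  # shared references: optimizer updates both

    # -- forward ----------------------------------------------------------

    @property
    def attention_params(self) -> AttentionParams:
        return AttentionParams(V=self.params["att_V"], w=self.params["att_w"])

    def forward(self, X: np.ndarray, precomputed_H: bool = False) -> ForwardResult:
        """Full bag forward pass.

        ``X`` is the raw bag input for the encoder, or a precomputed K×L
        feature matrix when ``precomputed_H`` (skips the encoder; used when
        features are cached for a frozen encoder).
        """
        if precomputed_H:
            H, enc_cache = np.asarray(X, dtype=float), None
        else:
            H, enc_cache = self.encoder.forward(X)
        cache: dict = {"enc": enc_cache, "precomputed": precomputed_H}
        a = sel = None
        if self.variant in ("ramil", "attention"):
            t = np.tanh(H @ self.params["att_V"].T)
            a = stable_softmax(t @ self.params["att_w"])
            C = len(a) if self.variant == "attention" else self.C
            sel = rank_select(a, H, C)
            z = aggregate(sel)
            cache["t"] = t
        elif self.variant == "gated":
            t = np.tanh(H @ self.params["att_V"].T)
            g = sigmoid(H @ self.params["att_U"].T)
            a = stable_softmax((t * g) @ self.params["att_w"])
            sel = rank_select(a, H, len(a))
            z = a @ H
            cache["t"], cache["g"] = t, g
        elif self.variant == "mean":
            z = pool_mean(H)
        else:  # max
            z = pool_max(H)
            cache["argmax"] = np.atleast_2d(H).argmax(axis=0)
        s = float(np.dot(self.params["head_w"], z)) + float(self.params["head_b"][0])
        return ForwardResult(
            probability=float(sigmoid(s)),
            logit=s,
            attention=a,
            selection=sel,
            z=z,
            H=H,
            cache=cache,
        )

    # -- backward ---------------------------------------------------------

    def backward(self, res: ForwardResult, g_logit: float) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. all params given dL/d(logit)."""
        H, a, sel = res.H, res.attention, res.selection
        K, L = H.shape
        grads: dict[str, np.ndarray] = {
            "head_w": g_logit * res.z,
            "head_b": np.array([g_logit]),
        }
        g_z = g_logit * self.params["head_w"]
        if self.variant == "mean":
            g_H = np.broadcast_to(g_z / K, H.shape).copy()
        elif self.variant == "max":
            g_H = np.zeros_like(H)
            g_H[res.cache["argmax"], np.arange(L)] = g_z
        else:
            # attention routes: z = Σ_sel a_c h_c (gated: all instances)
            g_a = np.zeros(K)
            g_H = np.zeros_like(H)
            g_a[sel.indices] = H[sel.indices] @ g_z
            g_H[sel.indices] = np.outer(a[sel.indices], g_z)
            # softmax backward over all K logits
            g_logits = a * (g_a - float(g_a @ a))
            t = res.cache["t"]
            w = self.params["att_w"]
            if self.variant == "gated":
                g = res.cache["g"]
                grads["att_w"] = (t * g).T @ g_logits
                g_tg = np.outer(g_logits, w)
                g_preV = g_tg * g * (1 - t**2)
                g_preU = g_tg * t * g * (1 - g)
                grads["att_U"] = g_preU.T @ H
                g_H = g_H + g_preU @ self.params["att_U"]
            else:
                grads["att_w"] = t.T @ g_logits
                g_preV = np.outer(g_logits, w) * (1 - t**2)
            grads["att_V"] = g_preV.T @ H
            g_H = g_H + g_preV @ self.params["att_V"]
        if not res.cache.get("precomputed") and self.encoder.trainable:
            for k, v in self.encoder.backward(g_H, res.cache["enc"]).items():
                grads[f"enc_{k}"] = v
        return grads

    # -- checkpointing ----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k not in self.params:
                raise KeyError(f"unexpected parameter {k!r}")
            if self.params[k].shape != v.shape:
                raise ValueError(
                    f"shape mismatch for {k}: {self.params[k].shape} vs {v.shape}"
                )
            self.params[k][...] = v  # in place: encoder shares these arrays


def forward(bag_input, encoder: Encoder, params: AttentionParams, head_w, head_b, C: int):
    """Functional composition encode → attention → rank-select → aggregate → classify.

    Returns (probability, attention scores, RankedSelection); provided for
    stepwise use and equivalence checks against :class:`MILModel`.
    """
    H = encoder.encode(bag_input)
    a = attention_scores(H, params)
    sel = rank_select(a, H, C)
    z = aggregate(sel)
    return classify(z, head_w, float(head_b)), a, sel
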