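"""Model explanation: attention-based slice ranking and Grad-CAM heatmaps.

The attention scores a_k are read as the contribution of each slice to the
bag prediction: a high-scoring slice is more informative. Grad-CAM localizes
*where* in a slice the model looks: channel weights are the spatial mean of
the gradient of the bag logit (pre-sigmoid) with respect to a convolutional
activation, and the map is the ReLU of the weighted activation sum,
bilinearly upsampled to slice size. Heatmaps are computed through the full
bag forward pass so the attention weighting participates in the gradient.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .encoders import ConvEncoder
from .pooling import ForwardResult, MILModel

logger = logging.getLogger(__name__)


def rank_slices(res: ForwardResult, patient_id: str = "") -> pd.DataFrame:
    """Slice report ordered by descending attention score (1-based slice numbers).

    Columns: slice_number, score, rank, selected (inside the top-C set).
    """
    if res.attention is None:
        raise ValueError("slice ranking requires an attention-based variant")
    a = res.attention
    K = len(a)
    order = np.argsort(-a, kind="stable")
    selected = np.zeros(K, dtype=bool)
    if res.selection is not None:
        selected[res.selection.indices] = True
    rows = [
        {
            "patient_id": patient_id,
            "slice_number": int(k + 1),
            "score": float(a[k]),
            "rank": rank + 1,
            "selected": bool(selected[k]),
        }
        for rank, k in enumerate(order)
    ]
    return pd.DataFrame(rows)


def _bag_logit_feature_grads(model: MILModel, res: ForwardResult) -> np.ndarray:
    """d(bag logit)/dH: gradient of the pre-sigmoid logit w.r.t. every h_k.

    Selected instances receive gradient directly through z; every instance
    receives gradient through the softmax denominator of the attention.
    """
    H, a, sel = res.H, res.attention, res.selection
    K, L = H.shape
    u = model.params["head_w"]
    gH = np.zeros_like(H)
    if a is None:  # mean / max variants
        if model.variant == "mean":
            gH[:] = u / K
        else:
            gH[res.cache["argmax"], np.arange(L)] = u
        return gH
    g_a = np.zeros(K)
    g_a[sel.indices] = H[sel.indices] @ u
    gH[sel.indices] = np.outer(a[sel.indices], u)
    g_logits = a * (g_a - float(g_a @ a))
    t = res.cache["t"]
    w = model.params["att_w"]
    if model.variant == "gated":
        g = res.cache["g"]
        g_tg = np.outer(g_logits, w)
        gH += (g_tg * g * (1 - t**2)) @ model.params["att_V"]
        gH += (g_tg * t * g * (1 - g)) @ model.params["att_U"]
    else:
        gH += (np.outer(g_logits, w) * (1 - t**2)) @ model.params["att_V"]
    return gH


def grad_cam(
    model: MILModel,
    bag_slices: np.ndarray,
    slice_index: int,
    target_layer: str = "conv2",
    normalize: bool = True,
) -> np.ndarray:
    """Grad-CAM heatmap for one slice of a bag, against the bag logit.

    ``bag_slices`` is the (K, H, W) stack; the forward pass runs on the full
    bag so attention weighting shapes the gradient. Channel weights are the
    spatial mean of d(logit)/d(activation) at ``target_layer`` (a post-ReLU
    convolutional activation of the encoder); the map is
    ReLU(Σ_c weight_c · activation_c) upsampled bilinearly to slice size.
    A slice with no gradient path yields an all-zero map with a warning.
    """
    if not isinstance(model.encoder, ConvEncoder):
        raise TypeError("grad_cam requires a convolutional encoder")
    res = model.forward(np.asarray(bag_slices, dtype=float))
    gH = _bag_logit_feature_grads(model, res)
    cache_k = res.cache["enc"][slice_index]
    g_act = model.encoder.activation_gradient(gH[slice_index], cache_k, target_layer)
    act = cache_k["act2"] if target_layer == "conv2" else cache_k["act1"]
    if not np.any(g_act):
        warnings.warn(
            f"zero gradient at slice {slice_index + 1}; returning an all-zero map",
            stacklevel=2,
        )
        return np.zeros(bag_slices.shape[1:])
    weights = g_act.mean(axis=(1, 2))
    cam = np.maximum(np.tensordot(weights, act, axes=1), 0.0)
    Ht, Wt = bag_slices.shape[1:]
    zoom = (Ht / cam.shape[0], Wt / cam.shape[1])
    cam = np.maximum(ndimage.zoom(cam, zoom, order=1), 0.0)
    if normalize and cam.max() > 0:
        cam = cam / cam.max()
    return cam


def export_overlays(
    bag_slices: np.ndarray,
    model: MILModel,
    out_dir: str | Path,
    patient_id: str = "patient",
    target_layer: str = "conv2",
    cmap: str = "jet",
    alpha: float = 0.4,
) -> list[Path]:
    """Write per-slice heatmap overlay PNGs plus a top/bottom summary panel.

    Filenames carry the attention rank and score. Returns the written paths
    (K overlays then the summary panel).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bag_slices = np.asarray(bag_slices, dtype=float)
    res = model.forward(bag_slices)
    report = rank_slices(res, patient_id=patient_id)
    rank_of = {int(r.slice_number): int(r.rank) for r in report.itertuples()}
    paths: list[Path] = []
    for k in range(bag_slices.shape[0]):
        heat = grad_cam(model, bag_slices, k, target_layer=target_layer)
        fig, ax = plt.subplots(figsize=(3, 3))
        ax.imshow(bag_slices[k], cmap="gray", vmin=0, vmax=1)
        ax.imshow(heat, cmap=cmap, alpha=alpha, vmin=0, vmax=1)
        score = float(res.attention[k]) if res.attention is not None else float("nan")
        ax.set_title(f"slice {k + 1} | rank {rank_of[k + 1]} | a={score:.3f}", fontsize=8)
        ax.axis("off")
        p = out_dir / f"{patient_id}_rank{rank_of[k + 1]:02d}_slice{k + 1:03d}_a{score:.4f}.png"
        fig.savefig(p, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    # summary panel: 3 highest- and 3 lowest-attention slices with overlays
    order = report.sort_values("rank")["slice_number"].to_numpy() - 1
    picks = list(order[:3]) + list(order[-3:])
    fig, axes = plt.subplots(2, len(picks), figsize=(2 * len(picks), 4.5))
    for j, k in enumerate(picks):
        axes[0, j].imshow(bag_slices[k], cmap="gray", vmin=0, vmax=1)
        axes[0, j].set_title(f"slice {k + 1} (rank {rank_of[k + 1]})", fontsize=7)
        heat = grad_cam(model, bag_slices, int(k), target_layer=target_layer)
        axes[1, j].imshow(bag_slices[k], cmap="gray", vmin=0, vmax=1)
        axes[1, j].imshow(heat, cmap=cmap, alpha=alpha, vmin=0, vmax=1)
        for ax in (axes[0, j], axes[1, j]):
            ax.axis("off")
    summary = out_dir / f"{patient_id}_summary.png"
    fig.savefig(summary, dpi=100, bbox_inches="tight")
    plt.close(fig)
    paths.append(summary)
    return paths
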