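"""Training: class-weighted BCE, augmentation, patient-level splits, Adam loop.

The loss is a class-weighted binary cross entropy over bags,

    L = β_P Σ_{Y=1} [−log q(X)] + β_N Σ_{Y=0} [−log(1 − q(X))],
    β_P = N / (P + N),   β_N = P / (P + N),

with P and N the positive/negative bag counts of the *training* set, so the
minority class receives the larger weight and β_P + β_N = 1.

Optimization is Adam (lr 2e-5, β₁ 0.9, β₂ 0.999, weight decay 1e-4 by
default) with batch size 1 — one bag per step, accommodating variable K.
Training monitors AUC on a held-out stratified validation split (10% of
training patients) and stops early after ``patience`` consecutive epochs
without a strict improvement, restoring the best-AUC parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ._nn import Adam
from .encoders import Encoder, IdentityEncoder
from .pooling import DEFAULT_C, DEFAULT_D, MILModel

logger = logging.getLogger(__name__)

PROB_CLAMP = 1e-7


@dataclass
class LossSpec:
    """Positive/negative bag counts of the training set; derives the class weights."""

    P: int
    N: int

    @property
    def beta_P(self) -> float:
        return self.N / (self.P + self.N)

    @property
    def beta_N(self) -> float:
        return self.P / (self.P + self.N)

    @classmethod
    def from_labels(cls, labels: Sequence[int]) -> "LossSpec":
        labels = np.asarray(labels)
        return cls(P=int((labels == 1).sum()), N=int((labels == 0).sum()))


def weighted_bce(
    predictions: Sequence[float], labels: Sequence[int], spec: LossSpec
) -> float:
    """Class-weighted binary cross entropy summed over bags.

    Probabilities are clamped to [1e-7, 1 − 1e-7]. If either class is absent
    from ``spec`` the weights are undefined; falls back to unweighted BCE
    (both weights 1) with a warning.
    """
    q = np.clip(np.asarray(predictions, dtype=float), PROB_CLAMP, 1 - PROB_CLAMP)
    y = np.asarray(labels)
    if spec.P == 0 or spec.N == 0:
        warnings.warn(
            "one class absent (P=%d, N=%d); using unweighted BCE" % (spec.P, spec.N),
            stacklevel=2,
        )
        bp = bn = 1.0
    else:
        bp, bn = spec.beta_P, spec.beta_N
    pos = -np.log(q[y == 1]).sum()
    neg = -np.log(1 - q[y == 0]).sum()
    return float(bp * pos + bn * neg)


# ---------------------------------------------------------------------------
# augmentation


@dataclass
class AugmentSpec:
    """Per-step augmentation: independent flips and rotation with set probabilities."""

    hflip_p: float = 0.5
    vflip_p: float = 0.5
    rotate_p: float = 0.2
    rotate_range: tuple[float, float] = (0.0, 40.0)


def augment(slice_2d: np.ndarray, spec: AugmentSpec, rng: np.random.Generator) -> np.ndarray:
    """Apply flips/rotation to one slice, each with its own probability.

    The rotation angle is uniform in ``rotate_range`` (degrees); rotation
    uses bilinear interpolation and keeps the original shape.
    """
    out = np.asarray(slice_2d)
    if rng.random() < spec.hflip_p:
        out = out[:, ::-1]
    if rng.random() < spec.vflip_p:
        out = out[::-1, :]
    if rng.random() < spec.rotate_p:
        angle = rng.uniform(*spec.rotate_range)
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="constant")
    return np.ascontiguousarray(out)


def augment_bag(slices: np.ndarray, spec: AugmentSpec, rng: np.random.Generator) -> np.ndarray:
    """Bag-coherent augmentation: one transform draw applied to every slice.

    Keeping the transform identical across a bag's slices preserves
    inter-slice anatomical consistency.
    """
    do_h = rng.random() < spec.hflip_p
    do_v = rng.random() < spec.vflip_p
    do_r = rng.random() < spec.rotate_p
    angle = rng.uniform(*spec.rotate_range) if do_r else 0.0
    out = np.asarray(slices)
    if do_h:
        out = out[:, :, ::-1]
    if do_v:
        out = out[:, ::-1, :]
    if do_r:
        out = np.stack(
            [ndimage.rotate(s, angle, reshape=False, order=1, mode="constant") for s in out]
        )
    return np.ascontiguousarray(out)


# ---------------------------------------------------------------------------
# splits


def split_validation(
    labels: Sequence[int], val_fraction: float = 0.10, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified patient-level train/validation index split.

    The validation size is the nearest integer to ``n * val_fraction``, with
    at least one bag of each class; class counts are allocated
    proportionally (nearest integer). Deterministic per seed.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must be in (0, 1)")
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes are required for a stratified split")
    n_val = int(round(n * val_fraction))
    n_val = max(2, n_val)
    n_val_pos = int(round(n_val * len(pos) / n))
    n_val_pos = min(max(n_val_pos, 1), n_val - 1)
    n_val_neg = n_val - n_val_pos
    rng = np.random.default_rng(seed)
    val = np.concatenate(
        [
            rng.choice(pos, size=n_val_pos, replace=False),
            rng.choice(neg, size=n_val_neg, replace=False),
        ]
    )
    val.sort()
    train = np.setdiff1d(np.arange(n), val)
    return train, val


def stratified_kfold(labels: Sequence[int], k: int = 5, seed: int = 0):
    """Stratified k-fold split; returns a list of (train_idx, test_idx) pairs.

    Folds are disjoint, exhaustive, and balanced: per-fold positive counts
    differ by at most one.
    """
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


# ---------------------------------------------------------------------------
# config, early stopping, training loop


@dataclass
class TrainConfig:
    """Optimization protocol; defaults follow the clinical training recipe."""

    learning_rate: float = 2e-5
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    weight_decay: float = 1e-4
    batch_size: int = 1
    max_epochs: int = 200
    patience: int = 20
    val_fraction: float = 0.10
    C: int = DEFAULT_C
    D: int = DEFAULT_D
    seed: int = 0
    augment: Optional[AugmentSpec] = None

    def __post_init__(self) -> None:
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without strict AUC improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, epoch: int, metric: float) -> bool:
        """Record one epoch; returns True when training should stop (improved resets)."""
        if metric > self.best:
            self.best = metric
            self.best_epoch = epoch
            self.stale = 0
            return False
        self.stale += 1
        return self.stale >= self.patience


@dataclass
class TrainResult:
    model: MILModel
    history: pd.DataFrame
    best_epoch: int
    best_val_auc: float
    loss_spec: LossSpec


def _as_feature_list(bags) -> list[np.ndarray]:
    out = []
    for b in bags:
        out.append(np.asarray(b, dtype=float))
    return out


def train(
    train_bags: Sequence,
    train_labels: Sequence[int],
    config: TrainConfig,
    variant: str = "ramil",
    encoder: Optional[Encoder] = None,
    image_bags: bool = False,
) -> TrainResult:
    """Train a MIL model on bags with Adam, early stopping, and best-epoch restore.

    ``train_bags`` are K×L feature matrices (``image_bags=False``, default)
    or (K, H, W) slice stacks. With a frozen encoder and no augmentation,
    features are computed once and cached. Raises on a single-class training
    set and aborts with diagnostics on a non-finite loss.
    """
    labels = np.asarray(train_labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(config.seed)
    tr_idx, val_idx = split_validation(labels, config.val_fraction, seed=int(rng.integers(2**31)))
    loss_spec = LossSpec.from_labels(labels[tr_idx])

    if encoder is None:
        L = np.asarray(train_bags[0]).shape[-1]
        encoder = IdentityEncoder(L)
        image_bags = False
    model = MILModel(
        encoder, variant=variant, C=config.C, D=config.D, seed=int(rng.integers(2**31))
    )
    opt = Adam(
        model.params,
        lr=config.learning_rate,
        beta1=config.adam_beta1,
        beta2=config.adam_beta2,
        weight_decay=config.weight_decay,
    )

    cache_features = (not encoder.trainable or isinstance(encoder, IdentityEncoder)) and (
        config.augment is None
    )
    if cache_features:
        feats = [encoder.encode(b) for b in train_bags]
    else:
        feats = None

    aug_rng = np.random.default_rng(int(rng.integers(2**31)))
    order_rng = np.random.default_rng(int(rng.integers(2**31)))

    def bag_forward(i: int, training: bool):
        if feats is not None:
            return model.forward(feats[i], precomputed_H=True)
        X = np.asarray(train_bags[i], dtype=float)
        if training and config.augment is not None and image_bags:
            X = augment_bag(X, config.augment, aug_rng)
        return model.forward(X)

    def val_auc() -> float:
        from .evaluation import auc

        probs = [bag_forward(i, training=False).probability for i in val_idx]
        return auc(probs, labels[val_idx])

    stopper = EarlyStopper(config.patience)
    best_state = model.state_dict()
    rows = []
    for epoch in range(1, config.max_epochs + 1):
        order = tr_idx.copy()
        order_rng.shuffle(order)
        epoch_loss = 0.0
        for i in order:
            res = bag_forward(int(i), training=True)
            y = labels[i]
            q = float(np.clip(res.probability, PROB_CLAMP, 1 - PROB_CLAMP))
            beta = loss_spec.beta_P if y == 1 else loss_spec.beta_N
            epoch_loss += -beta * (np.log(q) if y == 1 else np.log(1 - q))
            g_logit = beta * (res.probability - y)
            grads = model.backward(res, g_logit)
            opt.step(grads)
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch} (loss={epoch_loss}); aborting"
            )
        auc_now = val_auc()
        rows.append({"epoch": epoch, "train_loss": epoch_loss, "val_auc": auc_now})
        improved = auc_now > stopper.best
        stop = stopper.update(epoch, auc_now)
        if improved:
            best_state = model.state_dict()
        if stop:
            logger.info(
                "early stop at epoch %d (best val AUC %.4f at epoch %d)",
                epoch,
                stopper.best,
                stopper.best_epoch,
            )
            break
    model.load_state_dict(best_state)
    history = pd.DataFrame(rows)
    return TrainResult(
        model=model,
        history=history,
        best_epoch=stopper.best_epoch,
        best_val_auc=float(stopper.best),
        loss_spec=loss_spec,
    )
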