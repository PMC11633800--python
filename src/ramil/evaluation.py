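"""Classification metrics, rank-based AUC with bootstrap CI, Mann–Whitney U,
and the C-sweep / pooling-comparison experiment harnesses.

AUC is computed by the rank (Mann–Whitney) formulation with half-credit for
ties: AUC = U⁺ / (n_pos · n_neg) where U⁺ counts positive-over-negative wins.
Thresholded metrics use a fixed operating point of 0.5 (prediction positive
iff probability ≥ 0.5); all threshold-free statements use AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .training import TrainConfig, train

DEFAULT_THRESHOLD = 0.5


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


class Metrics(NamedTuple):
    acc: float
    pre: float
    rec: float
    spe: float
    f1: float


def confusion(
    probabilities: Sequence[float],
    labels: Sequence[int],
    threshold: float = DEFAULT_THRESHOLD,
) -> ConfusionCounts:
    """Confusion counts at a probability threshold (positive iff p ≥ threshold)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have the same length")
    pred = p >= threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & (y == 1))),
        FP=int(np.sum(pred & (y == 0))),
        FN=int(np.sum(~pred & (y == 1))),
        TN=int(np.sum(~pred & (y == 0))),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: 0/0 encountered, reporting 0", stacklevel=3)
        return 0.0
    return num / den


def metrics(cc: ConfusionCounts) -> Metrics:
    """Accuracy, precision, recall, specificity, F1 from confusion counts.

    Undefined ratios (0/0) are reported as 0 with a warning.
    """
    acc = _safe_div(cc.TP + cc.TN, cc.n, "accuracy")
    pre = _safe_div(cc.TP, cc.TP + cc.FP, "precision")
    rec = _safe_div(cc.TP, cc.TP + cc.FN, "recall")
    spe = _safe_div(cc.TN, cc.TN + cc.FP, "specificity")
    f1 = _safe_div(2 * pre * rec, pre + rec, "f1")
    return Metrics(acc=acc, pre=pre, rec=rec, spe=spe, f1=f1)


def auc(probabilities: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC with tie correction (ties count one half).

    Equals U⁺/(n_pos·n_neg), U⁺ being the Mann–Whitney statistic of the
    positive scores against the negatives.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one positive and one negative")
    ranks = stats.rankdata(p)  # average ranks handle ties
    u_pos = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u_pos / (n_pos * n_neg))


def auc_ci(
    probabilities: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Stratified percentile-bootstrap CI for the AUC (resampling within class)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = p[y == 1]
    neg = p[y == 0]
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    yb = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    for b in range(n_boot):
        pb = np.concatenate(
            [rng.choice(pos, len(pos), replace=True), rng.choice(neg, len(neg), replace=True)]
        )
        vals[b] = auc(pb, yb)
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of sample_a, p-value).

    Uses exact enumeration when min(n_a, n_b) ≤ 8 and there are no ties,
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def roc_points(probabilities: Sequence[float], labels: Sequence[int]) -> pd.DataFrame:
    """ROC curve points as a DataFrame (fpr, tpr, threshold)."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, probabilities)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class EvalReport:
    """Full evaluation of one model on one test set."""

    acc: float
    pre: float
    rec: float
    spe: float
    f1: float
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int
    probabilities: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k) for k in ("acc", "pre", "rec", "spe", "f1", "auc")
        }
        d["auc_ci_low"], d["auc_ci_high"] = self.auc_ci
        d["n_pos"], d["n_neg"] = self.n_pos, self.n_neg
        return d


def evaluate_probabilities(
    probabilities: Sequence[float],
    labels: Sequence[int],
    threshold: float = DEFAULT_THRESHOLD,
    ci_seed: int = 0,
) -> EvalReport:
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    m = metrics(confusion(p, y, threshold))
    return EvalReport(
        acc=m.acc,
        pre=m.pre,
        rec=m.rec,
        spe=m.spe,
        f1=m.f1,
        auc=auc(p, y),
        auc_ci=auc_ci(p, y, seed=ci_seed),
        n_pos=int((y == 1).sum()),
        n_neg=int((y == 0).sum()),
        probabilities=p,
        labels=y,
    )


def evaluate_model(model, test_bags, test_labels, precomputed=True) -> EvalReport:
    """Run the model on every test bag and compute the full report."""
    probs = [
        model.forward(np.asarray(b, dtype=float), precomputed_H=precomputed).probability
        for b in test_bags
    ]
    return evaluate_probabilities(probs, test_labels)


# ---------------------------------------------------------------------------
# experiment harnesses


def sweep_c(
    train_bags,
    train_labels,
    test_bags,
    test_labels,
    c_values: Sequence[int] = (6, 8, 10, 12, 14),
    config: Optional[TrainConfig] = None,
) -> pd.DataFrame:
    """Retrain the ranking-attention model per C (shared seed) and tabulate metrics."""
    config = config or TrainConfig()
    rows = []
    for c in c_values:
        cfg = TrainConfig(**{**_cfg_dict(config), "C": int(c)})
        result = train(train_bags, train_labels, cfg, variant="ramil")
        rep = evaluate_model(result.model, test_bags, test_labels)
        rows.append({"C": int(c), **rep.to_dict()})
    return pd.DataFrame(rows)


def compare_poolings(
    train_bags,
    train_labels,
    test_bags,
    test_labels,
    variants: Sequence[str] = ("ramil", "attention", "gated", "mean", "max"),
    config: Optional[TrainConfig] = None,
    reference: str = "ramil",
) -> tuple[pd.DataFrame, dict[str, EvalReport]]:
    """Train each pooling variant on identical splits/seeds and compare.

    The p-value column is a two-sided Mann–Whitney U test comparing each
    variant's per-bag correct-class probabilities (probability assigned to
    the true class of each test bag) against the reference variant's;
    reports are keyed by variant so per-bag probabilities stay available.
    """
    config = config or TrainConfig()
    reports: dict[str, EvalReport] = {}
    for v in variants:
        result = train(train_bags, train_labels, config, variant=v)
        reports[v] = evaluate_model(result.model, test_bags, test_labels)

    def correct_class_probs(rep: EvalReport) -> np.ndarray:
        return np.where(rep.labels == 1, rep.probabilities, 1 - rep.probabilities)

    ref = correct_class_probs(reports[reference])
    rows = []
    for v in variants:
        d = reports[v].to_dict()
        if v == reference:
            d["p_value"] = np.nan
        else:
            _, p = mann_whitney_u(ref, correct_class_probs(reports[v]))
            d["p_value"] = p
        rows.append({"variant": v, **d})
    return pd.DataFrame(rows), reports


def _cfg_dict(config: TrainConfig) -> dict:
    from dataclasses import asdict

    d = asdict(config)
    if d.get("augment") is not None:
        from .training import AugmentSpec

        d["augment"] = AugmentSpec(**d["augment"])
    return d
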