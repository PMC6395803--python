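"""Data splitting and model evaluation metrics.

Evaluation follows a two-level scheme: one external 70/30 split whose 30%
evaluation plots are never touched during model building, plus ten
internal 70/30 resplits of the calibration plots for repeated
cross-validation.

Metrics: AUC (Mann-Whitney formulation, ties counted one half), maximised
TSS (sensitivity + specificity - 1) and Cohen's kappa over an exact
threshold grid, overall accuracy at a given threshold, and explained
deviance D2 for the binomial regression techniques.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "SplitScheme",
    "MetricSet",
    "make_split_scheme",
    "auc",
    "tss_max",
    "kappa_max",
    "accuracy_at",
    "binomial_deviance",
    "d2_from_scores",
    "explained_deviance",
    "evaluate_scores",
]

_EPS = 1e-10


@dataclass
class SplitScheme:
    """External 70/30 split plus repeated internal 70/30 splits of the
    calibration subset."""

    calibration_ids: np.ndarray
    evaluation_ids: np.ndarray
    internal_splits: list[tuple[np.ndarray, np.ndarray]] = field(
        default_factory=list
    )
    seed: int = 0


def make_split_scheme(
    plot_ids,
    seed: int,
    n_internal: int = 10,
    eval_fraction: float = 0.3,
) -> SplitScheme:
    """Uniform random external split (floor(eval_fraction * n) plots to
    evaluation), then ``n_internal`` seeded resplits of the calibration
    subset with the same fraction."""
    plot_ids = np.asarray(plot_ids)
    n = len(plot_ids)
    if n < 10:
        raise ValueError(f"need at least 10 plots, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def split(ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        k = int(np.floor(eval_fraction * len(ids)))
        if k == 0 or k == len(ids):
            raise ValueError("split would produce an empty partition")
        perm = rng.permutation(len(ids))
        return ids[np.sort(perm[k:])], ids[np.sort(perm[:k])]

    calibration, evaluation = split(plot_ids)
    internal = [split(calibration) for _ in range(n_internal)]
    return SplitScheme(
        calibration_ids=calibration,
        evaluation_ids=evaluation,
        internal_splits=internal,
        seed=seed,
    )


def _check_labels(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("labels contain a single class")


def auc(scores, labels) -> float:
    """Area under the ROC curve: fraction of (presence, absence) pairs
    ranked correctly, ties counted one half (Mann-Whitney U)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_labels(labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = len(labels) - n1
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _threshold_grid(scores: np.ndarray) -> np.ndarray:
    """All midpoints between consecutive sorted unique scores, plus the
    endpoints 0 and 1 — an exact maximiser grid for threshold metrics."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.unique(np.concatenate([[0.0], u, mids, [1.0]]))


def _confusion_curves(scores, labels):
    """(thresholds, TP, FP, FN, TN) arrays under the rule score >= t."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_labels(labels)
    thr = _threshold_grid(scores)
    pred = scores[None, :] >= thr[:, None]
    pos = labels == 1
    tp = (pred & pos).sum(axis=1)
    fp = (pred & ~pos).sum(axis=1)
    fn = (~pred & pos).sum(axis=1)
    tn = (~pred & ~pos).sum(axis=1)
    return thr, tp, fp, fn, tn


def tss_max(scores, labels) -> tuple[float, float]:
    """Maximum of sensitivity + specificity - 1 over the threshold grid,
    and the maximising threshold."""
    thr, tp, fp, fn, tn = _confusion_curves(scores, labels)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    tss = sens + spec - 1.0
    i = int(np.argmax(tss))
    return float(tss[i]), float(thr[i])


def kappa_max(scores, labels) -> tuple[float, float]:
    """Maximum Cohen's kappa over the threshold grid and its threshold.

    Degenerate thresholds with chance agreement 1 are defined as kappa 0.
    """
    thr, tp, fp, fn, tn = _confusion_curves(scores, labels)
    n = tp + fp + fn + tn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(pe < 1.0, (po - pe) / (1.0 - pe), 0.0)
    i = int(np.argmax(kappa))
    return float(kappa[i]), float(thr[i])


def accuracy_at(scores, labels, threshold: float) -> float:
    """Proportion of correct predictions under the rule score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = (scores >= threshold).astype(int)
    return float((pred == labels).mean())


def binomial_deviance(p, y) -> float:
    """-2 log-likelihood of Bernoulli observations under probabilities p
    (clipped away from 0/1 for numerical safety)."""
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1.0 - _EPS)
    y = np.asarray(y, dtype=float)
    return float(-2.0 * np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def d2_from_scores(p, y) -> float:
    """Explained deviance D2 = 1 - Dev(model) / Dev(null), where the null
    model is the intercept-only fit (constant mean(y)) on the same data."""
    y = np.asarray(y, dtype=float)
    null = binomial_deviance(np.full_like(y, y.mean()), y)
    if null == 0:
        raise ValueError("null deviance is zero (constant labels)")
    return 1.0 - binomial_deviance(p, y) / null


def explained_deviance(model, X, y) -> float | None:
    """D2 for GLM/GAM models; None (not applicable) for other techniques.

    On evaluation data the null deviance of the evaluation subset is used,
    keeping D2 a pure evaluation-set quantity (it may then be negative).
    """
    if model.spec.technique not in ("GLM", "GAM"):
        return None
    from .engines import predict_sdm

    return d2_from_scores(predict_sdm(model, X), y)


@dataclass
class MetricSet:
    auc: float
    tss: float
    kappa: float
    accuracy: float
    d2: float | None
    threshold_tss: float
    threshold_kappa: float


def evaluate_scores(scores, labels, d2: float | None = None) -> MetricSet:
    """All threshold metrics for one score vector; accuracy is reported at
    the TSS-maximising threshold."""
    a = auc(scores, labels)
    tss, t_tss = tss_max(scores, labels)
    kap, t_kap = kappa_max(scores, labels)
    acc = accuracy_at(scores, labels, t_tss)
    return MetricSet(
        auc=a,
        tss=tss,
        kappa=kap,
        accuracy=acc,
        d2=d2,
        threshold_tss=t_tss,
        threshold_kappa=t_kap,
    )
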