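"""Confusion-matrix metrics, ROC/AUC and k-fold cross-validation."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

if TYPE_CHECKING:  # pragma: no cover
    from .model import PipelineConfig
    from .sequence_io import FragmentDataset


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: float | None = None

    def rounded(self, ndigits: int = 3) -> "Metrics":
        r = lambda v: None if v is None else round(v, ndigits)
        return Metrics(
            r(self.sensitivity), r(self.specificity), r(self.accuracy),
            r(self.mcc), r(self.auc),
        )


def confusion(labels: Sequence[int], calls: Sequence[int]) -> ConfusionCounts:
    """Tally a 2x2 confusion matrix from binary label and call vectors."""
    labels = np.asarray(labels, dtype=int)
    calls = np.asarray(calls, dtype=int)
    if labels.shape != calls.shape:
        raise ValueError("labels and calls must have equal length")
    return ConfusionCounts(
        tp=int(((labels == 1) & (calls == 1)).sum()),
        fn=int(((labels == 1) & (calls == 0)).sum()),
        tn=int(((labels == 0) & (calls == 0)).sum()),
        fp=int(((labels == 0) & (calls == 1)).sum()),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return math.nan
    return num / den


def metrics(counts: ConfusionCounts, auc: float | None = None) -> Metrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
    (TP+TN)/total and the Matthews correlation coefficient.

    Undefined ratios give NaN with a warning; an MCC with a zero
    denominator is reported as 0.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    sn = _ratio(tp, tp + fn, "sensitivity")
    sp = _ratio(tn, tn + fp, "specificity")
    acc = (tp + tn) / counts.total
    denom = math.sqrt(
        float(tp + fn) * float(tn + fp) * float(tp + fp) * float(tn + fn)
    )
    mcc = 0.0 if denom == 0 else (tp * tn - fn * fp) / denom
    return Metrics(sn, sp, acc, mcc, auc)


def roc_auc(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[np.ndarray, float]:
    """ROC curve points (FPR, TPR, threshold) and the area under the curve.

    The AUC equals the probability that a random positive outscores a
    random negative, with ties counting one half.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(labels, scores)
    curve = np.column_stack([fpr, tpr, thr])
    return curve, float(roc_auc_score(labels, scores))


def kfold_cv(
    dataset: "FragmentDataset",
    k: int = 5,
    config: "PipelineConfig | None" = None,
    seed: int = 0,
) -> tuple[Metrics, np.ndarray]:
    """Stratified k-fold cross-validation of the full two-layer pipeline.

    The motif tree and both SVM layers are re-learned inside every training
    fold; held-out predictions from all folds are pooled into a single
    confusion matrix and ROC.  Folds are stratified and seeded; with
    k equal to the dataset size the split degenerates to leave-one-out
    (unstratified by necessity).
    """
    from .model import PipelineConfig, predict_fragments, train_two_layer

    config = config or PipelineConfig()
    fragments = list(dataset.fragments)
    labels = np.array([1 if f.is_positive else 0 for f in fragments])
    if k < 2:
        raise ValueError("k must be >= 2")
    class_counts = np.bincount(labels, minlength=2)
    if k == len(fragments):
        splitter = KFold(n_splits=k)  # leave-one-out
    elif class_counts.min() < k:
        raise ValueError("dataset too small to stratify into k folds")
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    from .sequence_io import FragmentDataset as _FD

    pooled_scores = np.zeros(len(fragments))
    tested = np.zeros(len(fragments), dtype=bool)
    for fold_idx, (train_idx, test_idx) in enumerate(
        splitter.split(np.zeros(len(fragments)), labels)
    ):
        train = _FD([fragments[i] for i in train_idx], n=dataset.n)
        model = train_two_layer(train, tree=None, config=config, seed=seed + fold_idx)
        pooled_scores[test_idx] = predict_fragments(
            [fragments[i] for i in test_idx], model
        )
        tested[test_idx] = True
    assert tested.all(), "every fragment must be scored exactly once"

    calls = (pooled_scores >= config.threshold).astype(int)
    curve, auc = roc_auc(labels, pooled_scores)
    return metrics(confusion(labels, calls), auc=auc), curve
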