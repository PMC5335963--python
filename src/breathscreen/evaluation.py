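"""Leave-one-out cross-validation and screening metrics.

Each ORIGINAL sample is held out once; the classifier is trained on all
remaining original samples plus the fixed oversampled synthetic set, with
the z-score normalization refit inside every fold, and the held-out
sample is predicted. Synthetic samples are never held out and never
counted in the metrics: true positives/false negatives are tallied over
original cancer samples, true negatives/false positives over original
healthy samples.

Metrics (reported as percentages):

    TPR = TP / (TP + FN)            sensitivity, cancer detection rate
    TNR = TN / (TN + FP)            specificity over the healthy controls
    ACC = (TP + TN) / (P + N)       overall accuracy

which ties them by the identity ACC * (P + N) = TPR * P + TNR * N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CANCER, HEALTHY, VOCTable
from .svm import KernelParams, labels_to_y, train_svm


@dataclass(frozen=True)
class FoldRecord:
    """One LOOCV fold: the held-out sample and the fold model's complexity."""

    sample_id: str
    true_label: str
    predicted_label: str
    decision_value: float
    sv_count: int


@dataclass
class SubsetResult:
    """LOOCV performance of one VOC subset."""

    subset: tuple
    tp: int
    fn: int
    tn: int
    fp: int
    mean_sv_count: float
    sv_fraction: float
    folds: list = field(default_factory=list, repr=False)

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def tpr(self) -> float:
        """True positive rate, percent (full precision)."""
        return 100.0 * self.tp / self.n_pos

    @property
    def tnr(self) -> float:
        return 100.0 * self.tn / self.n_neg

    @property
    def acc(self) -> float:
        return 100.0 * (self.tp + self.tn) / (self.n_pos + self.n_neg)


def loocv_subset(table: VOCTable, subset, params: KernelParams | None = None,
                 strict: bool = False, keep_folds: bool = True) -> SubsetResult:
    """Evaluate one VOC subset by leave-one-out cross-validation.

    ``table`` is the post-oversampling cohort. For every original sample,
    an SVM is trained on all other samples (originals plus the fixed
    synthetic set) and the left-out sample is predicted. With
    ``strict=True`` synthetic samples interpolated from the left-out
    sample are also removed from the fold's training set (the
    leakage-free variant); the default replicates the fixed-set
    procedure, in which a held-out control's synthetic descendants remain
    in training.
    """
    params = params or KernelParams()
    subset = tuple(subset)
    X = table.values(subset)
    y = labels_to_y(table.labels)
    orig_idx = np.flatnonzero(table.is_original())
    if len(orig_idx) == 0:
        raise ValueError("no original samples to cross-validate")
    if len(np.unique(y[orig_idx])) < 2:
        raise ValueError("both classes must be present among original samples")

    folds = []
    tp = fn = tn = fp = 0
    sv_counts = np.empty(len(orig_idx))
    for k, i in enumerate(orig_idx):
        mask = np.ones(table.n_samples, dtype=bool)
        mask[i] = False
        if strict:
            left_out_id = table.sample_ids[i]
            for j, par in enumerate(table.parents):
                if par is not None and left_out_id in par:
                    mask[j] = False
        model = train_svm(X[mask], subset=subset, params=params, y=y[mask])
        f = float(model.decision_values(X[i:i + 1], subset_applied=True)[0])
        pred = CANCER if f > 0 else HEALTHY
        truth = table.labels[i]
        if truth == CANCER:
            tp += pred == CANCER
            fn += pred == HEALTHY
        else:
            tn += pred == HEALTHY
            fp += pred == CANCER
        sv_counts[k] = model.n_support
        if keep_folds:
            folds.append(FoldRecord(table.sample_ids[i], truth, pred, f,
                                    int(sv_counts[k])))
    train_n = table.n_samples - 1  # nominal fold training size
    return SubsetResult(
        subset=subset, tp=int(tp), fn=int(fn), tn=int(tn), fp=int(fp),
        mean_sv_count=float(sv_counts.mean()),
        sv_fraction=float(sv_counts.mean() / train_n),
        folds=folds,
    )


def metrics_from_counts(tp: int, fn: int, tn: int, fp: int) -> dict:
    """TPR/TNR/ACC percentages from a confusion-count quadruple."""
    p, n = tp + fn, tn + fp
    return {
        "tpr": 100.0 * tp / p,
        "tnr": 100.0 * tn / n,
        "acc": 100.0 * (tp + tn) / (p + n),
    }


def reconstruct_counts(tpr_pct: float, tnr_pct: float,
                       n_pos: int, n_neg: int) -> tuple[int, int, float]:
    """Recover integer (TP, TN) from rounded printed rates and class sizes.

    Published screening tables print TPR/TNR rounded to one decimal; with
    the class sizes known, the underlying integer confusion counts are
    recoverable as the integers whose exact rates round back to the
    printed values. Returns ``(tp, tn, acc_pct)`` with ACC at full
    precision (the caller rounds for display). Raises if no integer count
    is consistent with a printed rate.
    """

    def _recover(rate_pct, n):
        cand = int(round(rate_pct / 100.0 * n))
        # the nearest integer must round back to the printed one decimal
        for c in (cand, cand - 1, cand + 1):
            if 0 <= c <= n and round(100.0 * c / n, 1) == round(rate_pct, 1):
                return c
        raise ValueError(f"no integer count of {n} yields a rate of {rate_pct}%")

    tp = _recover(tpr_pct, n_pos)
    tn = _recover(tnr_pct, n_neg)
    acc = 100.0 * (tp + tn) / (n_pos + n_neg)
    return tp, tn, acc
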