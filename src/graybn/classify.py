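"""Density-based group classification.

A subject is assigned to the group whose fitted network gives the larger
log joint density of the subject's ROI-volume vector (equal priors; each
model applies its own stored standardization, with the Jacobian term
included so the two densities are compared on the common raw scale).  The
difference of the two log densities is the decision score, which also
drives the ROC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from .cohort import CohortTable
from .group import GroupModels, learn_group_models

__all__ = [
    "ClassificationResult",
    "assign_group",
    "classify_cohort",
    "roc_curve",
]


def _positive_label(models: GroupModels, positive: str | None) -> str:
    """Default positive class: 'young' when present, else the larger group."""
    if positive is not None:
        if positive not in models.labels:
            raise ValueError(f"positive label {positive!r} not in {models.labels}")
        return positive
    if "young" in models.labels:
        return "young"
    a, b = models.labels
    return a if models.results[a].network.n >= models.results[b].network.n else b


@dataclass
class ClassificationResult:
    """Per-subject scores/predictions plus aggregate discrimination metrics.

    ``table`` has one row per subject: true label, both log densities, the
    score (positive-model log density minus negative-model), and the
    prediction.  ``sensitivity`` is the true-positive rate of the positive
    class, ``specificity`` the true-negative rate.
    """

    table: pd.DataFrame
    positive_label: str
    negative_label: str
    tp: int
    fn: int
    tn: int
    fp: int
    roc_points: tuple[np.ndarray, np.ndarray]
    auc: float
    mode: str = "post_hoc"

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @classmethod
    def from_confusion(
        cls,
        tp: int,
        fn: int,
        tn: int,
        fp: int,
        positive_label: str = "positive",
        negative_label: str = "negative",
    ) -> "ClassificationResult":
        """Metrics from bare confusion counts (no per-subject table/ROC)."""
        return cls(
            table=pd.DataFrame(),
            positive_label=positive_label,
            negative_label=negative_label,
            tp=int(tp),
            fn=int(fn),
            tn=int(tn),
            fp=int(fp),
            roc_points=(np.array([0.0, 1.0]), np.array([0.0, 1.0])),
            auc=float("nan"),
        )

    def summary(self) -> str:
        lines = [
            "Density-based group classification",
            "=" * 46,
            f"Positive class: {self.positive_label!r}   mode: {self.mode}",
            f"Confusion: TP={self.tp} FN={self.fn} TN={self.tn} FP={self.fp}",
            f"Accuracy:    {100 * self.accuracy:6.2f}%",
            f"Sensitivity: {100 * self.sensitivity:6.2f}%",
            f"Specificity: {100 * self.specificity:6.2f}%",
        ]
        if np.isfinite(self.auc):
            lines.append(f"AUC:         {self.auc:7.3f}")
        return "\n".join(lines)

    def plot_roc(self, ax=None):  # pragma: no cover - thin plotting helper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fpr, tpr = self.roc_points
        ax.plot(fpr, tpr, label=f"AUC = {self.auc:.3f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend()
        return ax


def assign_group(
    models: GroupModels, x: np.ndarray, positive: str | None = None
) -> tuple[str, float]:
    """Classify one raw ROI-volume vector.

    Returns ``(label, score)`` with score = log density under the positive
    group's model minus log density under the other.  A score of exactly 0
    (identical models, say) assigns the positive class.
    """
    pos = _positive_label(models, positive)
    neg = models.labels[1] if pos == models.labels[0] else models.labels[0]
    lp = models.results[pos].network.logpdf(x)
    ln = models.results[neg].network.logpdf(x)
    if not (np.all(np.isfinite(lp)) and np.all(np.isfinite(ln))):
        raise ValueError("non-finite log density")
    score = float(lp - ln)
    return (pos if score >= 0 else neg), score


def roc_curve(
    scores, labels, positive
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC by threshold sweep over the scores, with trapezoidal AUC.

    Returns ``(fpr, tpr, auc)``; the curve starts at (0, 0), ends at
    (1, 1), and is non-decreasing in both coordinates.  Requires both
    classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels == positive
    if y.all() or not y.any():
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, _ = skmetrics.roc_curve(y, scores)
    return fpr, tpr, float(skmetrics.auc(fpr, tpr))


def classify_cohort(
    models: GroupModels,
    cohort: CohortTable,
    mode: str = "post_hoc",
    positive: str | None = None,
    config=None,
) -> ClassificationResult:
    """Classify every cohort subject and aggregate the metrics.

    ``mode="post_hoc"`` (default) scores the subjects under the already
    fitted group models — the in-sample procedure, optimistic by nature.
    ``mode="loocv"`` re-learns both group models without the held-out
    subject for every fold (the honest but much slower variant).
    """
    if mode not in ("post_hoc", "loocv"):
        raise ValueError(f"unknown mode {mode!r}")
    pos = _positive_label(models, positive)
    neg = models.labels[1] if pos == models.labels[0] else models.labels[0]
    a, b = models.labels
    d = len(models.nodes)
    sub = cohort.df[cohort.df["group"].isin([a, b])].reset_index(drop=True)
    X = sub[list(cohort.roi_names)].to_numpy(dtype=float)
    truths = sub["group"].to_numpy()

    if mode == "loocv":
        counts = sub["group"].value_counts()
        if (counts - 1).min() < d + 2:
            raise ValueError(
                f"loocv infeasible: smallest group would fall below n = d+2 = {d + 2}"
            )
        lp = np.empty(len(sub))
        ln = np.empty(len(sub))
        for i, sid in enumerate(sub["subject_id"]):
            fold = learn_group_models(
                cohort.drop_subject(sid), config=config, groups=(a, b)
            )
            lp[i] = fold.results[pos].network.logpdf(X[i])
            ln[i] = fold.results[neg].network.logpdf(X[i])
    else:
        lp = np.atleast_1d(models.results[pos].network.logpdf(X))
        ln = np.atleast_1d(models.results[neg].network.logpdf(X))
    if not (np.all(np.isfinite(lp)) and np.all(np.isfinite(ln))):
        raise ValueError("non-finite log density")
    score = lp - ln
    pred = np.where(score >= 0, pos, neg)
    tp = int(((truths == pos) & (pred == pos)).sum())
    fn = int(((truths == pos) & (pred == neg)).sum())
    tn = int(((truths == neg) & (pred == neg)).sum())
    fp = int(((truths == neg) & (pred == pos)).sum())
    fpr, tpr, auc = roc_curve(score, truths, pos)
    table = pd.DataFrame(
        {
            "subject_id": sub["subject_id"],
            "true_group": truths,
            f"log_density_{pos}": lp,
            f"log_density_{neg}": ln,
            "score": score,
            "predicted_group": pred,
        }
    )
    return ClassificationResult(
        table=table,
        positive_label=pos,
        negative_label=neg,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        roc_points=(fpr, tpr),
        auc=auc,
        mode=mode,
    )
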