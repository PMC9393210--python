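"""Confusion-matrix metric panel, repeated-training protocol, model comparison.

The panel mirrors the standard binary-classification ratios (positive =
pathological): accuracy, sensitivity/TPR, specificity/TNR, precision/PPV,
negative predictive value, false positive/negative/discovery rates, and the
trapezoidal ROC AUC.  Robustness is assessed by retraining a model many
times (30 by default) on a fixed train/test split and comparing per-run
accuracies between architectures with a two-sample t-test (Welch by
default) at a 0.01 significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "RepeatedRunSummary",
    "confusion_from_predictions",
    "metrics",
    "repeated_protocol",
    "compare_models",
]


@dataclass
class ConfusionMatrix:
    """Binary confusion counts; the positive class is pathological (label 1)."""

    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FN", "FP", "TN"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN

    @property
    def correct(self) -> int:
        return self.TP + self.TN


@dataclass
class MetricsReport:
    """The eight-ratio panel plus AUC; undefined ratios are NaN."""

    ACC: float
    TPR: float
    TNR: float
    PPV: float
    NPV: float
    FPR: float
    FNR: float
    FDR: float
    AUC: float = float("nan")

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {k: round(v, ndigits) for k, v in vars(self).items()}


@dataclass
class RepeatedRunSummary:
    """Per-run accuracies and mean metrics over a repeated-training protocol."""

    model_name: str
    accuracies: list[float]
    reports: list[MetricsReport] = field(default_factory=list)
    confusions: list[ConfusionMatrix] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    def mean_metrics(self) -> MetricsReport:
        fields = ["ACC", "TPR", "TNR", "PPV", "NPV", "FPR", "FNR", "FDR", "AUC"]
        means = {
            f: float(np.nanmean([getattr(r, f) for r in self.reports])) for f in fields
        }
        return MetricsReport(**means)

    def mean_confusion(self) -> ConfusionMatrix:
        """Element-wise rounded mean of the per-run confusion matrices."""
        arr = np.array([[c.TP, c.FN, c.FP, c.TN] for c in self.confusions], dtype=float)
        tp, fn, fp, tn = np.round(arr.mean(axis=0)).astype(int)
        return ConfusionMatrix(TP=tp, FN=fn, FP=fp, TN=tn)


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionMatrix(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def metrics(
    cm: ConfusionMatrix,
    scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
) -> MetricsReport:
    """Compute the metric panel from a confusion matrix.

    ``TPR = TP/(TP+FN)``, ``TNR = TN/(TN+FP)``, ``PPV = TP/(TP+FP)``,
    ``NPV = TN/(TN+FN)``, ``FPR = FP/(FP+TN)``, ``FNR = FN/(TP+FN)``,
    ``FDR = FP/(TP+FP)``.  A ratio with a zero denominator is reported as
    NaN (undefined), never silently 0.  AUC needs per-segment positive-class
    ``scores`` aligned with ``y_true``; without them it is NaN.
    """
    report = MetricsReport(
        ACC=_ratio(cm.correct, cm.total),
        TPR=_ratio(cm.TP, cm.TP + cm.FN),
        TNR=_ratio(cm.TN, cm.TN + cm.FP),
        PPV=_ratio(cm.TP, cm.TP + cm.FP),
        NPV=_ratio(cm.TN, cm.TN + cm.FN),
        FPR=_ratio(cm.FP, cm.FP + cm.TN),
        FNR=_ratio(cm.FN, cm.TP + cm.FN),
        FDR=_ratio(cm.FP, cm.TP + cm.FP),
    )
    if scores is not None and y_true is not None and len(np.unique(y_true)) == 2:
        report.AUC = float(roc_auc_score(y_true, scores))
    return report


def repeated_protocol(
    builder,
    x,
    labels: np.ndarray,
    repetitions: int = 30,
    test_fraction: float = 0.2,
    seed: int = 0,
    model_name: str = "model",
) -> RepeatedRunSummary:
    """Retrain and evaluate a model ``repetitions`` times on one fixed split.

    ``builder(x_train, y_train, run_seed)`` must return a trained model
    exposing ``predict`` (probabilities ``(n, 2)``).  The 80/20 train/test
    split is stratified and drawn once; each repetition reuses it with a
    distinct training seed, so run-to-run spread reflects training
    stochasticity only.
    """
    if repetitions < 2:
        raise ValueError("need at least 2 repetitions for a model comparison")
    labels = np.asarray(labels, dtype=int)
    idx_train, idx_test = train_test_split(
        np.arange(len(labels)),
        test_size=test_fraction,
        stratify=labels,
        random_state=seed % (2**32),
    )

    def take(data, idx):
        if isinstance(data, (tuple, list)):
            return tuple(d[idx] for d in data)
        return data[idx]

    summary = RepeatedRunSummary(model_name=model_name, accuracies=[])
    y_test = labels[idx_test]
    for run in range(repetitions):
        run_seed = (seed + 1000 * (run + 1)) % (2**31)
        trained = builder(take(x, idx_train), labels[idx_train], run_seed)
        probs = trained.predict(take(x, idx_test))
        y_pred = probs.argmax(axis=1)
        cm = confusion_from_predictions(y_test, y_pred)
        report = metrics(cm, scores=probs[:, 1], y_true=y_test)
        summary.accuracies.append(report.ACC)
        summary.reports.append(report)
        summary.confusions.append(cm)
    return summary


def compare_models(
    summary_a: RepeatedRunSummary,
    summary_b: RepeatedRunSummary,
    alpha: float = 0.01,
    equal_var: bool = False,
):
    """Two-sample t-test on per-run accuracies (Welch by default).

    Returns ``(t_statistic, p_value, reject)`` where ``reject`` is True iff
    the null hypothesis of equal mean accuracy is refused at level
    ``alpha``.  Two degenerate zero-variance samples with equal means give
    p = 1 by convention.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    a = np.asarray(summary_a.accuracies, dtype=float)
    b = np.asarray(summary_b.accuracies, dtype=float)
    if len(a) != len(b):
        raise ValueError("summaries must have the same repetition count")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0, True
    t_stat, p_value = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t_stat), float(p_value), bool(p_value < alpha)
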