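"""Classifier and counter evaluation.

Accuracy / F1 / one-vs-rest ROC-AUC with raw and row-normalized confusion
matrices, per-class sensitivity/specificity, and wheeze-rate agreement
between an algorithmic count and a reference annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score, roc_auc_score

from .audio_io import CLASSES
from .counting import CountReport

__all__ = [
    "ClassMetrics",
    "RateComparison",
    "compute_metrics",
    "sensitivity_specificity",
    "compare_rates",
    "plot_probabilities",
]


@dataclass(frozen=True)
class ClassMetrics:
    accuracy: float
    f1: float
    f1_average: str
    roc_auc_ovr: float | None
    confusion: np.ndarray
    confusion_normalized: np.ndarray
    per_class: dict[str, dict[str, float | None]]

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "f1_average": self.f1_average,
            "roc_auc_ovr": self.roc_auc_ovr,
            "confusion": self.confusion.tolist(),
            "confusion_normalized": self.confusion_normalized.tolist(),
            "per_class": self.per_class,
        }


@dataclass(frozen=True)
class RateComparison:
    algo_rate: float
    annotated_rate: float
    abs_error: float
    algo_rate_rounded: float
    annotated_rate_rounded: float
    counts: tuple[int, int, int, int]  # algo_wheeze, algo_breaths, annotated_wheeze, annotated_breaths

    def as_dict(self) -> dict:
        return {
            "algo_rate": self.algo_rate,
            "annotated_rate": self.annotated_rate,
            "abs_error": self.abs_error,
            "algo_rate_rounded": self.algo_rate_rounded,
            "annotated_rate_rounded": self.annotated_rate_rounded,
            "counts": list(self.counts),
        }


def sensitivity_specificity(
    confusion: np.ndarray, class_idx: int
) -> tuple[float | None, float]:
    """One-vs-rest sensitivity and specificity from a 3x3 count matrix."""
    confusion = np.asarray(confusion)
    if confusion.sum() <= 0:
        raise ValueError("confusion matrix has no counts")
    tp = confusion[class_idx, class_idx]
    fn = confusion[class_idx].sum() - tp
    fp = confusion[:, class_idx].sum() - tp
    tn = confusion.sum() - tp - fn - fp
    if tp + fn == 0:
        warnings.warn(
            f"class {class_idx} has no support; sensitivity undefined", stacklevel=2
        )
        sensitivity = None
    else:
        sensitivity = float(tp / (tp + fn))
    specificity = float(tn / (tn + fp)) if tn + fp else 0.0
    return sensitivity, specificity


def compute_metrics(true_labels: np.ndarray, probs: np.ndarray) -> ClassMetrics:
    """Evaluate probability predictions against integer labels.

    Predictions are argmax with ties to the lower index; F1 is weighted by
    class support (the averaging mode is recorded in the result); ROC-AUC is
    one-vs-rest, macro-averaged, and omitted with a warning when the truth
    contains a single class.
    """
    y = np.asarray(true_labels, dtype=np.int64)
    probs = np.asarray(probs, dtype=np.float64)
    if len(y) != len(probs):
        raise ValueError("label and probability lengths differ")
    pred = probs.argmax(axis=1)
    labels = [0, 1, 2]
    acc = float(accuracy_score(y, pred))
    f1 = float(f1_score(y, pred, labels=labels, average="weighted", zero_division=0))
    conf = confusion_matrix(y, pred, labels=labels)
    row_sums = conf.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        conf_norm = np.where(row_sums > 0, conf / np.maximum(row_sums, 1), 0.0)

    present = np.unique(y)
    if len(present) < 2:
        warnings.warn("single-class truth: ROC-AUC undefined", stacklevel=2)
        auc = None
    else:
        # macro average over the one-vs-rest binary problems with both
        # outcomes; per-class scoring keeps the AUC purely rank-based
        aucs = [
            roc_auc_score((y == k).astype(int), probs[:, k])
            for k in present
        ]
        auc = float(np.mean(aucs))

    per_class: dict[str, dict[str, float | None]] = {}
    for k, name in enumerate(CLASSES):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sens, spec = sensitivity_specificity(conf, k)
        support = int(conf[k].sum())
        class_acc = float(conf_norm[k, k]) if support else None
        per_class[name] = {"sensitivity": sens, "specificity": spec, "accuracy": class_acc}

    return ClassMetrics(
        accuracy=acc,
        f1=f1,
        f1_average="weighted",
        roc_auc_ovr=auc,
        confusion=conf,
        confusion_normalized=conf_norm,
        per_class=per_class,
    )


def compare_rates(
    algo: CountReport, annotated_wheeze: int, annotated_breaths: int
) -> RateComparison:
    """Wheeze-rate agreement between the counter and a reference annotation."""
    if annotated_breaths <= 0:
        raise ValueError("annotated_breaths must be positive")
    algo_rate = algo.wheeze_rate
    annotated_rate = annotated_wheeze / annotated_breaths
    return RateComparison(
        algo_rate=algo_rate,
        annotated_rate=annotated_rate,
        abs_error=abs(algo_rate - annotated_rate),
        algo_rate_rounded=round(algo_rate, 2),
        annotated_rate_rounded=round(annotated_rate, 2),
        counts=(algo.n_wheeze, algo.n_respiration, annotated_wheeze, annotated_breaths),
    )


def plot_probabilities(
    features, probs: np.ndarray, path, true_labels: np.ndarray | None = None
) -> None:
    """Probability traces over the Mel spectrogram, written to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_mel, ax_prob) = plt.subplots(
        2, 1, figsize=(12, 6), sharex=True, height_ratios=[2, 1]
    )
    times = features.frame_times
    ax_mel.imshow(
        features.features.T,
        origin="lower",
        aspect="auto",
        extent=[times[0], times[-1], 0, features.n_mels],
        cmap="magma",
    )
    ax_mel.set_ylabel("Mel band")
    colors = {"break": "tab:green", "normal": "tab:blue", "wheeze": "tab:red"}
    for k, name in enumerate(CLASSES):
        ax_prob.plot(times, probs[:, k], color=colors[name], label=name)
        if true_labels is not None:
            ax_prob.plot(
                times, (np.asarray(true_labels) == k).astype(float),
                color=colors[name], linestyle=":", alpha=0.6,
            )
    ax_prob.set_xlabel("time (s)")
    ax_prob.set_ylabel("probability")
    ax_prob.set_ylim(-0.05, 1.05)
    ax_prob.legend(loc="upper right", ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
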