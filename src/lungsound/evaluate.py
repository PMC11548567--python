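"""Four-class evaluation: confusion matrix, per-class and macro metrics.

Conventions: confusion rows are true classes, columns predictions;
precision = diagonal / column sum, recall = diagonal / row sum; F1 is their
harmonic mean with the 0/0 case defined as 0 (and logged).  Sensitivity and
specificity for the multiclass problem are one-vs-rest, macro-averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from lungsound.labels import CLASS_NAMES, N_CLASSES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass(frozen=True)
class EvalReport:
    confusion: np.ndarray  # (4, 4) counts, rows = true
    accuracy: float
    per_class: dict[str, ClassMetrics]
    macro_sensitivity: float
    macro_specificity: float
    macro_precision: float
    macro_f1: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
            "confusion": self.confusion.tolist(),
            "per_class": {
                k: {"precision": m.precision, "recall": m.recall, "f1": m.f1, "support": m.support}
                for k, m in self.per_class.items()
            },
        }

    def as_text(self) -> str:
        lines = [f"accuracy: {self.accuracy:.4f}", ""]
        lines.append(f"{'class':<10}{'precision':>10}{'recall':>10}{'f1':>10}{'support':>10}")
        for name, m in self.per_class.items():
            lines.append(f"{name:<10}{m.precision:>10.4f}{m.recall:>10.4f}{m.f1:>10.4f}{m.support:>10}")
        lines.append("")
        lines.append(
            f"macro: sensitivity {self.macro_sensitivity:.4f}  specificity {self.macro_specificity:.4f}  "
            f"precision {self.macro_precision:.4f}  f1 {self.macro_f1:.4f}"
        )
        return "\n".join(lines)


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (np.asarray(y_true, dtype=int), np.asarray(y_pred, dtype=int)), 1)
    return m


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.debug("undefined %s (0/0); reporting 0", what)
        return 0.0
    return num / den


def report_from_confusion(confusion: np.ndarray) -> EvalReport:
    """All metrics from a (rows = true, cols = predicted) count matrix."""
    confusion = np.asarray(confusion, dtype=np.int64)
    total = int(confusion.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(confusion).astype(float)
    row = confusion.sum(axis=1).astype(float)  # supports
    col = confusion.sum(axis=0).astype(float)

    per_class: dict[str, ClassMetrics] = {}
    precs, recs, f1s, specs = [], [], [], []
    for c, name in enumerate(CLASS_NAMES):
        prec = _safe_div(diag[c], col[c], f"precision[{name}]")
        rec = _safe_div(diag[c], row[c], f"recall[{name}]")
        f1 = _safe_div(2 * prec * rec, prec + rec, f"f1[{name}]")
        tn = total - row[c] - col[c] + diag[c]
        spec = _safe_div(tn, total - row[c], f"specificity[{name}]")
        per_class[name] = ClassMetrics(prec, rec, f1, int(row[c]))
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
        specs.append(spec)

    return EvalReport(
        confusion=confusion,
        accuracy=float(diag.sum() / total),
        per_class=per_class,
        macro_sensitivity=float(np.mean(recs)),
        macro_specificity=float(np.mean(specs)),
        macro_precision=float(np.mean(precs)),
        macro_f1=float(np.mean(f1s)),
    )


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    """Evaluate hard predictions against true labels."""
    y_true = np.asarray(y_true)
    if len(y_true) == 0:
        raise ValueError("cannot evaluate on an empty test set")
    return report_from_confusion(confusion_matrix(y_true, y_pred))


def plot_confusion(report: EvalReport, path) -> None:
    """Render the confusion matrix as a heatmap image (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(report.confusion, cmap="Blues")
    ax.set_xticks(range(N_CLASSES), CLASS_NAMES, rotation=45)
    ax.set_yticks(range(N_CLASSES), CLASS_NAMES)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(N_CLASSES):
        for j in range(N_CLASSES):
            ax.text(j, i, str(report.confusion[i, j]), ha="center", va="center", fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
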