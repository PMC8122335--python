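"""Classification evaluation: confusion matrices, accuracy and Cohen's kappa.

The per-class figure reported alongside overall accuracy is class recall
(diagonal count over true-class total); kappa is the chance-corrected
agreement ``K = (p_o - p_e) / (1 - p_e)`` with ``p_o`` the observed
agreement and ``p_e`` the agreement expected from the marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import CLASS_ORDER

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion_matrix",
    "accuracy",
    "kappa",
    "per_class_accuracy",
    "report",
    "plot_confusion_matrix",
]


@dataclass
class ConfusionMatrix:
    """Count matrix, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{k} classes"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.class_order != other.class_order:
            raise ValueError("class orders differ")
        return ConfusionMatrix(self.counts + other.counts, self.class_order)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_order),
                            columns=list(self.class_order))


def confusion_matrix(y_true, y_pred, class_order=CLASS_ORDER) -> ConfusionMatrix:
    """Count matrix over a fixed class order; unknown labels are an error."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    index = {c: i for i, c in enumerate(class_order)}
    unknown = (set(np.unique(y_true)) | set(np.unique(y_pred))) - set(class_order)
    if unknown:
        raise ValueError(f"labels outside class order: {sorted(map(str, unknown))}")
    k = len(class_order)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(class_order))


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy A = trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa K = (p_o - p_e) / (1 - p_e)."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm.counts) / n
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    p_e = float(row @ col) / n**2
    if p_e == 1.0:
        raise ValueError("degenerate one-class matrix: kappa undefined (p_e = 1)")
    return float((p_o - p_e) / (1.0 - p_e))


def per_class_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    """Class recall diag_i / row_i; NaN marks classes absent from y_true."""
    row = cm.counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(row > 0, np.diag(cm.counts) / row, np.nan)


@dataclass
class EvalReport:
    """One evaluated (method, preprocessing, dataset, split) combination."""

    cm: ConfusionMatrix
    method: str
    preprocessing: str = "NoP"
    dataset: str = ""
    split: str = "LOO"
    extra: dict = field(default_factory=dict)

    @property
    def A(self) -> float:
        return accuracy(self.cm)

    @property
    def K(self) -> float:
        return kappa(self.cm)

    def row(self) -> dict:
        out = {"method": self.method, "preprocessing": self.preprocessing,
               "dataset": self.dataset, "split": self.split}
        for cls, v in zip(self.cm.class_order, per_class_accuracy(self.cm)):
            out[cls] = float(v) if np.isfinite(v) else np.nan
        out["A"] = self.A
        out["K"] = self.K
        out.update(self.extra)
        return out


def report(results, path=None) -> pd.DataFrame:
    """Long-format results table (method x preprocessing x per-class x A x K).

    Column order follows the per-class header (Hundred .. BG) then A and K.
    Written to ``path`` as CSV at full precision when given.
    """
    if not results:
        raise ValueError("no evaluation results to report")
    df = pd.DataFrame([r.row() for r in results])
    lead = ["method", "preprocessing", "dataset", "split"]
    cols = lead + [c for c in CLASS_ORDER] + ["A", "K"]
    cols += [c for c in df.columns if c not in cols]
    df = df[[c for c in cols if c in df.columns]]
    if path is not None:
        df.to_csv(Path(path), index=False)
    return df


def plot_confusion_matrix(cm: ConfusionMatrix, path, title: str = "") -> Path:
    """Heatmap PNG of a confusion matrix (counts annotated)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xticks(range(len(cm.class_order)), cm.class_order, rotation=45)
    ax.set_yticks(range(len(cm.class_order)), cm.class_order)
    ax.set_xlabel("Predicted")
    ax.set_ylabel("True")
    if title:
        ax.set_title(title)
    for i in range(len(cm.class_order)):
        for j in range(len(cm.class_order)):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center",
                    color="black", fontsize=8)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
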