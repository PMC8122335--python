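"""1-D convolutional network for seven-way spectral classification.

Architecture (input = one 128-band reflectance spectrum):

====================  ==================  ============  ==========
Layer                 Type                Output shape  Parameters
====================  ==================  ============  ==========
Conv1d_1              Conv1D (k=5)        (124, 40)     240
Average_pooling1d_1   AveragePooling1D    (62, 40)      0
Max_pooling1d_1       MaxPooling1D        (31, 40)      0
Conv1d_2              Conv1D (k=3)        (29, 20)      2,420
Average_pooling1d_2   AveragePooling1D    (14, 20)      0
Max_pooling1d_2       MaxPooling1D        (7, 20)       0
Flatten_1             Flatten             140           0
Dense_1               Dense + ReLU        500           70,500
Dropout_1             Dropout (0.5)       500           0
Dense_2               Dense + ReLU        100           50,100
Dense_3               Dense (softmax)     7             707
====================  ==================  ============  ==========

123,967 trainable parameters in total for 128 bands and 7 classes.
Convolutions are valid (no padding), stride 1, ReLU; training minimizes
categorical cross-entropy with Adam.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .evaluate import ConfusionMatrix, accuracy as cm_accuracy, confusion_matrix
from .nn import (
    Adam,
    AvgPool1D,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    MaxPool1D,
    ReLU,
    Sequential,
    TrainHistory,
    softmax,
    softmax_ce_loss,
)
from .spectra import CLASS_ORDER, LabeledSpectra

__all__ = [
    "Cnn1dSpec",
    "SplitData",
    "build_cnn1d",
    "summary",
    "split_calibration_validation",
    "CNN1DClassifier",
    "train_cnn1d",
    "evaluate_cnn1d",
]


@dataclass
class Cnn1dSpec:
    """Structural parameters of the spectral CNN."""

    input_length: int = 128
    n_classes: int = 7
    conv1_filters: int = 40
    conv1_kernel: int = 5
    conv2_filters: int = 20
    conv2_kernel: int = 3
    dense1: int = 500
    dense2: int = 100
    dropout: float = 0.5

    def layer_table(self) -> list[tuple[str, str, tuple, int]]:
        """(name, type, output shape, parameter count) per layer.

        Lengths follow the valid-conv / pool-2 recurrence
        ``L -> L - k + 1`` and ``L -> floor(L / 2)``; conv parameters are
        ``(k * c_in + 1) * c_out`` and dense ``(d_in + 1) * d_out``.
        """
        L = self.input_length
        rows = []
        L = L - self.conv1_kernel + 1
        if L < 1:
            raise ValueError("input too short for the first convolution")
        rows.append(("Conv1d_1", "Conv1D", (L, self.conv1_filters),
                     (self.conv1_kernel * 1 + 1) * self.conv1_filters))
        L //= 2
        rows.append(("Average_pooling1d_1", "AveragePooling1D", (L, self.conv1_filters), 0))
        L //= 2
        rows.append(("Max_pooling1d_1", "MaxPooling1D", (L, self.conv1_filters), 0))
        L = L - self.conv2_kernel + 1
        if L < 1:
            raise ValueError("input too short to survive both conv/pool stages")
        rows.append(("Conv1d_2", "Conv1D", (L, self.conv2_filters),
                     (self.conv2_kernel * self.conv1_filters + 1) * self.conv2_filters))
        L //= 2
        rows.append(("Average_pooling1d_2", "AveragePooling1D", (L, self.conv2_filters), 0))
        L //= 2
        rows.append(("Max_pooling1d_2", "MaxPooling1D", (L, self.conv2_filters), 0))
        flat = L * self.conv2_filters
        if flat < 1:
            raise ValueError("input too short to survive both conv/pool stages")
        rows.append(("Flatten_1", "Flatten", (flat,), 0))
        rows.append(("Dense_1", "Dense", (self.dense1,), (flat + 1) * self.dense1))
        rows.append(("Dropout_1", "Dropout", (self.dense1,), 0))
        rows.append(("Dense_2", "Dense", (self.dense2,), (self.dense1 + 1) * self.dense2))
        rows.append(("Dense_3", "Dense", (self.n_classes,), (self.dense2 + 1) * self.n_classes))
        return rows

    @property
    def n_params(self) -> int:
        return sum(r[3] for r in self.layer_table())

    @property
    def flatten_length(self) -> int:
        return next(r[2][0] for r in self.layer_table() if r[0] == "Flatten_1")


def build_cnn1d(spec: Cnn1dSpec | None = None, seed: int = 0) -> Sequential:
    """Construct the network; raises for inputs too short for the stack."""
    spec = spec or Cnn1dSpec()
    table = spec.layer_table()  # validates the shape recurrence
    rng = np.random.default_rng(seed)
    model = Sequential(
        Conv1D(1, spec.conv1_filters, spec.conv1_kernel, rng),
        ReLU(),
        AvgPool1D(),
        MaxPool1D(),
        Conv1D(spec.conv1_filters, spec.conv2_filters, spec.conv2_kernel, rng),
        ReLU(),
        AvgPool1D(),
        MaxPool1D(),
        Flatten(),
        Dense(spec.flatten_length, spec.dense1, rng),
        ReLU(),
        Dropout(spec.dropout, rng),
        Dense(spec.dense1, spec.dense2, rng),
        ReLU(),
        Dense(spec.dense2, spec.n_classes, rng),
    )
    assert model.n_params == sum(r[3] for r in table)
    return model


def summary(spec: Cnn1dSpec | None = None) -> str:
    """Model summary in the familiar layer/type/shape/params layout."""
    spec = spec or Cnn1dSpec()
    lines = [f"{'Layer':<22}{'Type':<20}{'Output Shape':<16}{'# of Parameter':>14}"]
    for name, typ, shape, n in spec.layer_table():
        shp = ", ".join(str(s) for s in shape)
        lines.append(f"{name:<22}{typ:<20}{shp:<16}{n:>14,}")
    total = spec.n_params
    lines.append(f"Total parameters: {total:,}, Trainable parameters: {total:,}")
    return "\n".join(lines)


@dataclass
class SplitData:
    """Stratified calibration/validation split of labeled spectra."""

    calibration: LabeledSpectra
    validation: LabeledSpectra
    fraction: float
    seed: int


def split_calibration_validation(spectra: LabeledSpectra, fraction: float = 0.7,
                                 seed: int = 0) -> SplitData:
    """Disjoint stratified split; every class needs >= 2 samples."""
    counts = spectra.class_counts()
    singletons = [c for c, n in counts.items() if n < 2]
    if singletons:
        raise ValueError(f"classes with a single sample cannot be split: {singletons}")
    idx = np.arange(len(spectra))
    cal_idx, val_idx = train_test_split(
        idx, train_size=fraction, stratify=spectra.y, random_state=seed
    )
    return SplitData(spectra.subset(np.sort(cal_idx)), spectra.subset(np.sort(val_idx)),
                     fraction, seed)


class CNN1DClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style estimator around the spectral CNN.

    Default schedule is 500 epochs (configurable up to thousands; training
    may be stopped early on a loss plateau via ``patience``).  All
    randomness -- weight init, dropout, batch shuffling -- derives from
    ``random_state``, so two fits with the same seed produce identical
    histories.

    Attributes (post-fit): ``classes_``, ``model_``, ``history_`` (per-epoch
    cross-entropy loss and mean absolute error of the class probabilities).
    """

    def __init__(self, epochs: int = 500, batch_size: int = 32, lr: float = 1e-3,
                 dropout: float = 0.5, patience: int | None = None,
                 min_delta: float = 1e-6, random_state: int = 0):
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.dropout = dropout
        self.patience = patience
        self.min_delta = min_delta
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be (n_samples, n_bands)")
        if len(X) == 0:
            raise ValueError("empty calibration set")
        present = set(map(str, np.unique(y)))
        if present <= set(CLASS_ORDER):
            self.classes_ = np.array([c for c in CLASS_ORDER if c in present])
        else:
            self.classes_ = np.unique(y)
        spec = Cnn1dSpec(input_length=X.shape[1], n_classes=len(self.classes_),
                         dropout=self.dropout)
        self.spec_ = spec
        self.model_ = build_cnn1d(spec, seed=self.random_state)
        opt = Adam(self.model_, lr=self.lr)
        rng = np.random.default_rng(self.random_state + 1)
        Y = (y[:, None] == self.classes_[None, :]).astype(np.float32)
        Xin = X[..., None]
        n = len(X)
        self.history_ = TrainHistory(metric_name="mae")
        best, wait = np.inf, 0
        for _ in range(self.epochs):
            order = rng.permutation(n)
            ep_loss = ep_mae = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self.model_.forward(Xin[idx], train=True)
                loss, grad = softmax_ce_loss(logits, Y[idx])
                self.model_.backward(grad)
                opt.step()
                ep_loss += loss * len(idx)
                ep_mae += float(np.abs(softmax(logits) - Y[idx]).mean()) * len(idx)
            self.history_.append(ep_loss / n, ep_mae / n)
            if self.patience is not None:
                if self.history_.loss[-1] < best - self.min_delta:
                    best, wait = self.history_.loss[-1], 0
                else:
                    wait += 1
                    if wait >= self.patience:
                        break
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=np.float32)
        return self.model_.forward(X[..., None], train=False)

    def predict_proba(self, X):
        return softmax(self.decision_function(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def evaluate(self, X, y, class_order=None) -> tuple[ConfusionMatrix, float]:
        """Confusion matrix and overall accuracy on a labeled subset."""
        order = tuple(class_order) if class_order is not None else CLASS_ORDER
        cm = confusion_matrix(np.asarray(y), self.predict(X), order)
        return cm, cm_accuracy(cm)

    def save(self, path) -> Path:
        check_is_fitted(self, "model_")
        path = Path(path)
        np.savez(path, *self.model_.params(),
                 classes=np.array(self.classes_, dtype="U"))
        return path


def train_cnn1d(model_or_split, split: SplitData | None = None, epochs: int = 500,
                seed: int = 0, **kw) -> tuple[CNN1DClassifier, TrainHistory]:
    """Train a :class:`CNN1DClassifier` on the calibration half of a split."""
    split = split if split is not None else model_or_split
    if not isinstance(split, SplitData):
        raise TypeError("expected a SplitData")
    if len(split.calibration) == 0:
        raise ValueError("empty calibration set")
    clf = CNN1DClassifier(epochs=epochs, random_state=seed, **kw)
    clf.fit(split.calibration.X, split.calibration.y)
    return clf, clf.history_


def evaluate_cnn1d(clf: CNN1DClassifier, subset: LabeledSpectra) -> tuple[ConfusionMatrix, float]:
    """Confusion matrix + accuracy of a fitted classifier on one subset."""
    return clf.evaluate(subset.X, subset.y)
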