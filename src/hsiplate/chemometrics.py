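"""Chemometric classifiers for per-pixel spectra with leave-one-out CV.

Six methods: linear discriminant analysis (LDA), partial least squares
discriminant analysis (PLS-DA, NIPALS), support vector machine (SVM,
RBF), decision tree (DT), least-squares SVM (LSSVM) and random forest
(RF).  LDA, PLS-DA and LSSVM are implemented from their defining linear
algebra; SVM, DT and RF delegate to scikit-learn behind the same
estimator interface, mirroring how such pipelines are run in practice.

All estimators are scikit-learn compatible (``fit``/``predict``/
``get_params``), so they compose with pipelines and model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import LeaveOneOut
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .evaluate import ConfusionMatrix, confusion_matrix
from .spectra import CLASS_ORDER

__all__ = [
    "ClassifierSpec",
    "LinearDiscriminantClassifier",
    "PLSDAClassifier",
    "LSSVMClassifier",
    "lssvm_solve",
    "make_classifier",
    "train",
    "predict",
    "loo_cv",
    "CHEMOMETRIC_METHODS",
]

CHEMOMETRIC_METHODS = ("LDA", "PLSDA", "SVM", "DT", "LSSVM", "RF")


def _ordered_classes(y: np.ndarray) -> np.ndarray:
    """Unique labels in the package's fixed class order when applicable."""
    present = set(map(str, np.unique(y)))
    if present <= set(CLASS_ORDER):
        return np.array([c for c in CLASS_ORDER if c in present])
    return np.unique(y)


def _check_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != len(X):
        raise ValueError("X must be (n_samples, n_features) with matching y")
    classes = _ordered_classes(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    if len(X) <= len(classes):
        raise ValueError("need n_samples > n_classes")
    return X, y, classes


class LinearDiscriminantClassifier(BaseEstimator, ClassifierMixin):
    """LDA with pooled within-class covariance and Ledoit-Wolf shrinkage.

    Discriminant score for class c:
    ``x^T S^-1 mu_c - mu_c^T S^-1 mu_c / 2 + log pi_c``.
    Per-pixel spectra have many correlated bands, so the pooled covariance
    is routinely ill-conditioned; it is therefore shrunk toward a scaled
    identity as ``(1 - lam) S + lam tr(S)/d I``.  ``shrinkage='auto'``
    (default) estimates ``lam`` by the Ledoit-Wolf formula on the
    within-class residuals; a float fixes it; 0 disables shrinkage, in
    which case a singular covariance falls back to a small ridge with a
    warning.
    """

    def __init__(self, shrinkage: float | str = "auto"):
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X, y, self.classes_ = _check_Xy(X, y)
        n, d = X.shape
        k = len(self.classes_)
        self.means_ = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        idx_of = {c: i for i, c in enumerate(self.classes_)}
        resid = X - self.means_[[idx_of[c] for c in y]]
        Sw = resid.T @ resid / max(n - k, 1)
        if self.shrinkage == "auto":
            from sklearn.covariance import ledoit_wolf

            _, lam = ledoit_wolf(resid, assume_centered=True)
        else:
            lam = float(self.shrinkage)
        self.shrinkage_ = lam
        mu_tr = np.trace(Sw) / d
        Sreg = (1.0 - lam) * Sw + lam * mu_tr * np.eye(d)
        try:
            coef = np.linalg.solve(Sreg, self.means_.T)
            if not np.all(np.isfinite(coef)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            ridge = 1e-6 * (mu_tr if mu_tr > 0 else 1.0)
            warnings.warn(
                f"singular pooled covariance; applying shrinkage ridge {ridge:.3e}"
            )
            coef = np.linalg.solve(Sreg + ridge * np.eye(d), self.means_.T)
        self.coef_ = coef  # (d, k)
        self.intercept_ = -0.5 * np.einsum("kd,dk->k", self.means_, coef) + np.log(
            self.priors_
        )
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """PLS-DA: NIPALS PLS2 regression on one-hot targets, argmax decision."""

    def __init__(self, n_components: int = 10, max_iter: int = 500, tol: float = 1e-10):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X, y, self.classes_ = _check_Xy(X, y)
        Y = (y[:, None] == self.classes_[None, :]).astype(float)
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        E = X - self.x_mean_
        F = Y - self.y_mean_
        n_comp = min(self.n_components, np.linalg.matrix_rank(E))
        d, k = X.shape[1], Y.shape[1]
        W = np.zeros((d, n_comp))
        P = np.zeros((d, n_comp))
        Q = np.zeros((k, n_comp))
        for a in range(n_comp):
            u = F[:, np.argmax(F.var(axis=0))]
            t_old = None
            for _ in range(self.max_iter):
                w = E.T @ u
                w /= np.linalg.norm(w)
                t = E @ w
                q = F.T @ t / (t @ t)
                if np.linalg.norm(q) == 0:
                    break
                u = F @ q / (q @ q)
                if t_old is not None and np.linalg.norm(t - t_old) < self.tol * np.linalg.norm(t):
                    break
                t_old = t
            p = E.T @ t / (t @ t)
            E = E - np.outer(t, p)
            F = F - np.outer(t, q)
            W[:, a], P[:, a], Q[:, a] = w, p, q
        self.coef_ = W @ np.linalg.pinv(P.T @ W) @ Q.T
        self.n_components_ = n_comp
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def lssvm_solve(K: np.ndarray, y: np.ndarray, gamma: float,
                sym_tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Solve the LSSVM dual linear system for one or more output columns.

    ``[[0, 1^T], [1, K + I/gamma]] @ [b; alpha] = [0; y]`` with ``K`` the
    symmetric PSD kernel Gram matrix.  Returns ``(alpha, b)`` where alpha
    has the shape of ``y`` and ``b`` one intercept per output column.  A
    singular system is re-solved with a small ridge bump (warning).
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    if not np.allclose(K, K.T, atol=sym_tol):
        raise ValueError("K must be symmetric")
    y = np.asarray(y, dtype=float)
    y2 = y[:, None] if y.ndim == 1 else y
    n = K.shape[0]
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.vstack([np.zeros((1, y2.shape[1])), y2])
    try:
        sol = np.linalg.solve(A, rhs)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular LSSVM system; applying ridge bump 1e-10")
        A[1:, 1:] += 1e-10 * np.eye(n)
        sol = np.linalg.solve(A, rhs)
    b = sol[0]
    alpha = sol[1:]
    if y.ndim == 1:
        return alpha[:, 0], float(b[0])
    return alpha, b


class LSSVMClassifier(BaseEstimator, ClassifierMixin):
    """One-vs-rest least-squares SVM with an RBF kernel.

    ``gamma`` is the regularization weight of the equality-constrained
    least-squares problem; ``width`` the RBF kernel length scale (default:
    median pairwise training distance, set at fit time).
    """

    def __init__(self, gamma: float = 10.0, width: float | None = None):
        self.gamma = gamma
        self.width = width

    def _kernel(self, A, B, width):
        d2 = (
            np.sum(A**2, axis=1)[:, None]
            + np.sum(B**2, axis=1)[None, :]
            - 2.0 * A @ B.T
        )
        return np.exp(-np.maximum(d2, 0.0) / (2.0 * width**2))

    def fit(self, X, y):
        X, y, self.classes_ = _check_Xy(X, y)
        self.X_ = X
        if self.width is None:
            rng = np.random.default_rng(0)
            m = min(len(X), 200)
            idx = rng.choice(len(X), size=m, replace=False)
            d2 = (
                np.sum(X[idx] ** 2, axis=1)[:, None]
                + np.sum(X[idx] ** 2, axis=1)[None, :]
                - 2.0 * X[idx] @ X[idx].T
            )
            med = float(np.median(np.sqrt(np.maximum(d2, 0.0))))
            self.width_ = med if med > 0 else 1.0
        else:
            self.width_ = float(self.width)
        K = self._kernel(X, X, self.width_)
        Y = np.where(y[:, None] == self.classes_[None, :], 1.0, -1.0)
        self.alpha_, self.b_ = lssvm_solve(K, Y, self.gamma)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "alpha_")
        K = self._kernel(np.asarray(X, dtype=float), self.X_, self.width_)
        return K @ self.alpha_ + self.b_

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


class _OrderedVoteRF(RandomForestClassifier):
    """RF whose prediction ties resolve to the lowest fixed-order class."""

    def predict(self, X):
        proba = self.predict_proba(X)
        order = _ordered_classes(self.classes_)
        # column index of each ordered class within sklearn's classes_
        cols = [int(np.flatnonzero(self.classes_ == c)[0]) for c in order]
        reordered = proba[:, cols]
        return order[np.argmax(reordered, axis=1)]


@dataclass
class ClassifierSpec:
    """Method name plus hyperparameters; factory input for the six models."""

    method: str = "SVM"
    pls_components: int = 10
    svm_C: float = 10.0
    svm_gamma: float | str = "scale"  # variance-adaptive 1 / (n_bands * var(X))
    dt_max_depth: int | None = None
    dt_min_split: int = 2
    lssvm_gamma: float = 10.0
    lssvm_width: float | None = None
    rf_n_trees: int = 500
    rf_max_features: str | int = "sqrt"
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in CHEMOMETRIC_METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; choose from {CHEMOMETRIC_METHODS}"
            )


def make_classifier(spec: ClassifierSpec | str):
    """Instantiate the estimator for a :class:`ClassifierSpec`."""
    if isinstance(spec, str):
        spec = ClassifierSpec(method=spec)
    m = spec.method
    if m == "LDA":
        return LinearDiscriminantClassifier(**spec.extra)
    if m == "PLSDA":
        return PLSDAClassifier(n_components=spec.pls_components, **spec.extra)
    if m == "SVM":
        return SVC(C=spec.svm_C, gamma=spec.svm_gamma, kernel="rbf",
                   random_state=spec.seed, **spec.extra)
    if m == "DT":
        return DecisionTreeClassifier(
            max_depth=spec.dt_max_depth, min_samples_split=spec.dt_min_split,
            random_state=spec.seed, **spec.extra)
    if m == "LSSVM":
        return LSSVMClassifier(gamma=spec.lssvm_gamma, width=spec.lssvm_width,
                               **spec.extra)
    return _OrderedVoteRF(
        n_estimators=spec.rf_n_trees, max_features=spec.rf_max_features,
        random_state=spec.seed, **spec.extra)


def train(spec: ClassifierSpec | str, X, y):
    """Fit a fresh estimator for ``spec`` on (X, y); deterministic per seed."""
    est = make_classifier(spec)
    X, y, _ = _check_Xy(X, y)
    return est.fit(X, y)


def predict(model, X) -> np.ndarray:
    """Predicted labels, one per row of X."""
    return np.asarray(model.predict(np.asarray(X, dtype=float)))


def loo_cv(spec, X, y, class_order=CLASS_ORDER, fit_callback=None) -> ConfusionMatrix:
    """Leave-one-out cross-validation aggregated into one confusion matrix.

    Runs ``n_samples`` independent fits.  ``fit_callback``, when given, is
    invoked once per fold (instrumentation hook).  Folds whose training set
    misses a class are still run, with a warning.
    """
    X, y, classes = _check_Xy(X, y)
    if len(X) < len(classes) + 1:
        raise ValueError("LOO needs n_samples >= n_classes + 1")
    est = make_classifier(spec) if isinstance(spec, (ClassifierSpec, str)) else spec
    preds = np.empty(len(y), dtype=y.dtype)
    for train_idx, test_idx in LeaveOneOut().split(X):
        if len(np.unique(y[train_idx])) < len(classes):
            warnings.warn("LOO fold misses a class in its training set")
        model = clone(est).fit(X[train_idx], y[train_idx])
        if fit_callback is not None:
            fit_callback(model)
        preds[test_idx] = model.predict(X[test_idx])
    return confusion_matrix(y, preds, class_order)
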