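"""Spectral preprocessing: the six chemometric pretreatments.

``NoP`` (none), ``D1``/``D2`` (first/second Savitzky-Golay derivatives),
``MSC`` (multiplicative scatter correction), ``MA`` (moving average) and
``NM`` (per-spectrum min-max normalization).  ``SNV`` (standard normal
variate) is provided as an alternative reading of "normalization".

Derivatives and smoothing use mirror padding at the spectrum edges so every
method is length-preserving, and all methods leave sample count and labels
untouched.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import LabeledSpectra

__all__ = [
    "PREPROCESS_METHODS",
    "sg_derivative",
    "msc_correct",
    "moving_average",
    "normalize",
    "snv",
    "SpectralPreprocessor",
    "preprocess",
]

PREPROCESS_METHODS = ("NoP", "D1", "D2", "MSC", "MA", "NM", "SNV")


def sg_derivative(spectrum: np.ndarray, window: int = 11, polyorder: int = 2,
                  deriv: int = 1) -> np.ndarray:
    """Savitzky-Golay derivative w.r.t. band index, mirror-padded edges.

    At interior points the result is the ``deriv``-th derivative of the
    local least-squares polynomial fit, hence exact for polynomials of
    degree <= ``polyorder``.
    """
    if deriv not in (1, 2):
        raise ValueError("deriv must be 1 or 2")
    if window % 2 == 0 or window <= polyorder or polyorder < deriv:
        raise ValueError(
            f"need odd window > polyorder >= deriv, got window={window}, "
            f"polyorder={polyorder}, deriv={deriv}"
        )
    x = np.asarray(spectrum, dtype=float)
    return savgol_filter(x, window, polyorder, deriv=deriv, delta=1.0,
                         mode="mirror", axis=-1)


def msc_correct(spectra: np.ndarray, reference: np.ndarray | None = None,
                b_tol: float = 1e-8) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum ``x`` is regressed as ``x = a + b * reference`` (ordinary
    least squares) and returned as ``(x - a) / b``.  The reference defaults
    to the mean spectrum of the set, which that mean then maps to itself.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if np.ptp(ref) == 0:
        raise ValueError("constant reference spectrum: MSC regression undefined")
    rc = ref - ref.mean()
    denom = float(rc @ rc)
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(np.abs(b) < b_tol):
        bad = int(np.argmin(np.abs(b)))
        raise ValueError(
            f"degenerate MSC fit for spectrum {bad}: slope {b[bad]:.2e} ~ 0"
        )
    a = X.mean(axis=1) - b * ref.mean()
    out = (X - a[:, None]) / b[:, None]
    return out if np.asarray(spectra).ndim > 1 else out[0]


def moving_average(spectrum: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered mean filter with mirror-padded edges, length-preserving."""
    x = np.asarray(spectrum, dtype=float)
    n = x.shape[-1]
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window >= 2 * n:
        raise ValueError(f"window {window} too large for {n} bands")
    return uniform_filter1d(x, size=window, mode="mirror", axis=-1)


def normalize(spectrum: np.ndarray) -> np.ndarray:
    """Per-spectrum min-max scaling onto [0, 1]."""
    x = np.atleast_2d(np.asarray(spectrum, dtype=float))
    lo = x.min(axis=1, keepdims=True)
    rng = x.max(axis=1, keepdims=True) - lo
    if np.any(rng == 0):
        raise ValueError("constant spectrum cannot be min-max normalized")
    out = (x - lo) / rng
    return out if np.asarray(spectrum).ndim > 1 else out[0]


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centering and unit scaling."""
    x = np.atleast_2d(np.asarray(spectrum, dtype=float))
    sd = x.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant spectrum cannot be SNV scaled")
    out = (x - x.mean(axis=1, keepdims=True)) / sd
    return out if np.asarray(spectrum).ndim > 1 else out[0]


class SpectralPreprocessor(BaseEstimator, TransformerMixin):
    """Dispatching transformer over the named pretreatments.

    Stateless except for MSC, whose reference spectrum is learned as the
    training-set mean in :meth:`fit` (and reused at transform time, so
    train/test processing is consistent).

    Parameters
    ----------
    method : one of ``NoP, D1, D2, MSC, MA, NM, SNV``
    sg_window, sg_polyorder : Savitzky-Golay settings for D1/D2
    ma_window : moving-average window
    """

    def __init__(self, method: str = "NoP", sg_window: int = 11,
                 sg_polyorder: int = 2, ma_window: int = 5):
        self.method = method
        self.sg_window = sg_window
        self.sg_polyorder = sg_polyorder
        self.ma_window = ma_window

    def _check(self):
        if self.method not in PREPROCESS_METHODS:
            raise ValueError(
                f"unknown preprocessing method {self.method!r}; "
                f"choose from {PREPROCESS_METHODS}"
            )

    def fit(self, X, y=None):
        self._check()
        X = np.asarray(X, dtype=float)
        self.reference_ = X.mean(axis=0) if self.method == "MSC" else None
        return self

    def transform(self, X):
        self._check()
        if self.method == "MSC" and not hasattr(self, "reference_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        if self.method == "NoP":
            return X.copy()
        if self.method == "D1":
            return sg_derivative(X, self.sg_window, self.sg_polyorder, deriv=1)
        if self.method == "D2":
            return sg_derivative(X, self.sg_window, self.sg_polyorder, deriv=2)
        if self.method == "MSC":
            return msc_correct(X, self.reference_)
        if self.method == "MA":
            return moving_average(X, self.ma_window)
        if self.method == "NM":
            return normalize(X)
        return snv(X)


def preprocess(spectra: LabeledSpectra, config: SpectralPreprocessor | str) -> LabeledSpectra:
    """Apply a pretreatment to labeled spectra; labels pass through."""
    proc = (
        SpectralPreprocessor(method=config) if isinstance(config, str) else config
    )
    Xt = proc.fit(spectra.X).transform(spectra.X)
    return LabeledSpectra(Xt, spectra.y.copy(), spectra.wavelengths,
                          {**spectra.meta, "preprocess": proc.method})
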