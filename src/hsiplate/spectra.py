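"""Labeled per-pixel spectra: the tabular interface between segmentation
and classification.

Class order is fixed everywhere in the package: the six juice dilutions from
undiluted (``Hundred`` = 100%) down to 1:100 (``One`` = 1%), then the bare
stainless-steel background ``BG``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["CLASS_ORDER", "DILUTION_OF_CLASS", "LabeledSpectra"]

CLASS_ORDER: tuple[str, ...] = ("Hundred", "Twenty", "Ten", "Five", "Two", "One", "BG")

#: juice volume fraction represented by each dilution class
DILUTION_OF_CLASS: dict[str, float] = {
    "Hundred": 1.00,
    "Twenty": 0.20,
    "Ten": 0.10,
    "Five": 0.05,
    "Two": 0.02,
    "One": 0.01,
}


@dataclass
class LabeledSpectra:
    """Matrix of per-pixel reflectance spectra with 7-way class labels.

    Attributes
    ----------
    X : ndarray, shape (n_samples, n_bands)
    y : ndarray of str, shape (n_samples,)
        Labels drawn from :data:`CLASS_ORDER`.
    wavelengths : ndarray, shape (n_bands,)
    """

    X: np.ndarray
    y: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_bands)")
        if len(self.y) != len(self.X):
            raise ValueError("label vector length must equal n_samples")
        if self.X.shape[1] != len(self.wavelengths):
            raise ValueError("n_bands must match wavelength axis length")
        unknown = set(np.unique(self.y)) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.y, return_counts=True)
        return {str(l): int(c) for l, c in zip(labels, counts)}

    def subset(self, idx) -> "LabeledSpectra":
        return LabeledSpectra(self.X[idx], self.y[idx], self.wavelengths, dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{w:.2f}nm" for w in self.wavelengths]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "class", self.y)
        df.insert(0, "sample_id", np.arange(len(self)))
        return df

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path) -> "LabeledSpectra":
        df = pd.read_csv(path)
        band_cols = [c for c in df.columns if c.endswith("nm")]
        wavelengths = np.array([float(c[:-2]) for c in band_cols])
        return cls(df[band_cols].to_numpy(), df["class"].to_numpy(), wavelengths)

    def to_hdf5(self, path) -> Path:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=self.X)
            f.create_dataset("y", data=np.array(self.y, dtype="S"))
            f.create_dataset("wavelengths", data=self.wavelengths)
        return path

    @classmethod
    def from_hdf5(cls, path) -> "LabeledSpectra":
        with h5py.File(path, "r") as f:
            return cls(
                f["X"][()],
                np.array([s.decode() for s in f["y"][()]]),
                f["wavelengths"][()],
            )
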