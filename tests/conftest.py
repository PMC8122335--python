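"""Shared fixtures.

Expensive trained models (U-net, CNN-1D) are session-scoped so the
segmentation and acceptance suites share a single training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from hsiplate.io import calibrate_reflectance
from hsiplate.simulate import (
    PlateLayout,
    SpectralModel,
    generate_plate,
    generate_training_pairs,
)
from hsiplate.spectra import CLASS_ORDER, DILUTION_OF_CLASS, LabeledSpectra


@pytest.fixture(scope="session")
def gauss7():
    """Well-separated 7-class Gaussian fixture: d=128, 20/class, dmu=10sigma."""
    rng = np.random.default_rng(42)
    d, per = 128, 20
    X = np.concatenate(
        [10.0 * np.eye(d)[i][None, :] + rng.standard_normal((per, d)) for i in range(7)]
    )
    y = np.array([c for c in CLASS_ORDER for _ in range(per)])
    return X, y


@pytest.fixture(scope="session")
def plate_sigma0():
    """Noise-free default plate: (raw, dark, white, truth, reflectance)."""
    layout = PlateLayout()
    model = SpectralModel(noise_sigma=0.0)
    raw, dark, white, truth = generate_plate(layout, model, seed=1)
    refl = calibrate_reflectance(raw, dark, white)
    return raw, dark, white, truth, refl


@pytest.fixture(scope="session")
def small_layout():
    """Reduced plate for fast end-to-end runs (24 droplets)."""
    return dict(
        plate_shape=[96, 112], n_rows=4, row_spacing=20, col_spacing=16,
        droplet_radius=5, origin=[10, 14],
    )


@pytest.fixture(scope="session")
def highsnr_spectra():
    """High-SNR synthetic spectra: 7 classes x 100, reflectance noise 0.005."""
    from hsiplate.io import DEFAULT_WAVELENGTHS
    from hsiplate.simulate import droplet_reflectance

    model = SpectralModel()
    rng = np.random.default_rng(7)
    rows, labels = [], []
    for cls in CLASS_ORDER:
        c = DILUTION_OF_CLASS.get(cls, 0.0)
        base = droplet_reflectance(model, c)
        rows.append(base[None, :] + rng.normal(0, 0.005, (100, 128)))
        labels += [cls] * 100
    return LabeledSpectra(np.concatenate(rows), np.array(labels), DEFAULT_WAVELENGTHS)


@pytest.fixture(scope="session")
def trained_cnn(highsnr_spectra):
    """CNN-1D trained 200 epochs on the 70% calibration half (seeded)."""
    from hsiplate.cnn1d import CNN1DClassifier, split_calibration_validation

    split = split_calibration_validation(highsnr_spectra, 0.7, seed=5)
    clf = CNN1DClassifier(epochs=200, random_state=5)
    clf.fit(split.calibration.X, split.calibration.y)
    return clf, split


@pytest.fixture(scope="session")
def trained_unet():
    """U-net trained on 20 randomized synthetic pairs for 30 epochs."""
    from hsiplate.unet import UNetSegmenter

    pairs = generate_training_pairs(20, seed=11)
    seg = UNetSegmenter(epochs=30, random_state=3)
    seg.fit_pairs(pairs)
    return seg
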