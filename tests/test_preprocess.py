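"""Spectral pretreatments: derivatives, scatter correction, smoothing."""

import numpy as np
import pytest

from hsiplate.preprocess import (
    PREPROCESS_METHODS,
    SpectralPreprocessor,
    moving_average,
    msc_correct,
    normalize,
    preprocess,
    sg_derivative,
    snv,
)
from hsiplate.spectra import LabeledSpectra


class TestSavitzkyGolay:
    def test_exact_first_derivative_of_line(self):
        i = np.arange(128, dtype=float)
        spec = 3.0 + 0.25 * i
        d1 = sg_derivative(spec, window=11, polyorder=2, deriv=1)
        half = 5
        np.testing.assert_allclose(d1[half:-half], 0.25, atol=1e-10)

    def test_exact_second_derivative_of_quadratic(self):
        i = np.arange(128, dtype=float)
        spec = 1.0 - 0.5 * i + 0.03 * i**2
        d2 = sg_derivative(spec, window=11, polyorder=2, deriv=2)
        np.testing.assert_allclose(d2[5:-5], 0.06, atol=1e-9)

    def test_matches_per_window_polyfit_oracle(self):
        rng = np.random.default_rng(4)
        spec = rng.random(40)
        w, p = 5, 2
        d1 = sg_derivative(spec, window=w, polyorder=p, deriv=1)
        half = w // 2
        for center in range(half, 40 - half):
            xs = np.arange(-half, half + 1, dtype=float)
            coeffs = np.polynomial.polynomial.polyfit(xs, spec[center - half : center + half + 1], p)
            # derivative of the local fit at the window center
            assert d1[center] == pytest.approx(coeffs[1], abs=1e-9)

    @pytest.mark.parametrize("window,polyorder,deriv", [(4, 2, 1), (5, 5, 1), (5, 1, 2), (5, 2, 3)])
    def test_invalid_parameters_rejected(self, window, polyorder, deriv):
        with pytest.raises(ValueError):
            sg_derivative(np.zeros(20), window, polyorder, deriv)


class TestMSC:
    def test_reference_spectrum_maps_to_itself(self):
        rng = np.random.default_rng(0)
        ref = rng.random(64) + 0.5
        out = msc_correct(ref[None, :], reference=ref)
        np.testing.assert_allclose(out[0], ref, atol=1e-10)

    def test_affine_distortion_inverted_exactly(self):
        rng = np.random.default_rng(1)
        ref = rng.random(64) + 0.5
        x = 3.0 + 2.0 * ref
        out = msc_correct(x[None, :], reference=ref)
        np.testing.assert_allclose(out[0], ref, atol=1e-9)

    def test_refit_oracle_gives_unit_slope_zero_offset(self):
        rng = np.random.default_rng(2)
        X = rng.random((20, 64)) + 0.2
        ref = X.mean(axis=0)
        out = msc_correct(X)
        for row in out:
            b, a = np.polyfit(ref, row, 1)
            assert a == pytest.approx(0.0, abs=1e-8)
            assert b == pytest.approx(1.0, abs=1e-8)

    def test_set_mean_fixed_under_scatter_model(self):
        # under the MSC model (every spectrum an affine transform of one
        # underlying signal, offsets summing to 0 and slopes averaging 1)
        # the set mean IS the reference and correction restores it exactly
        rng = np.random.default_rng(3)
        ref = rng.random(64) + 0.5
        a = rng.normal(0, 0.3, 10)
        a -= a.mean()
        b = 1.0 + rng.normal(0, 0.2, 10)
        b += 1.0 - b.mean()
        X = a[:, None] + b[:, None] * ref[None, :]
        np.testing.assert_allclose(X.mean(axis=0), ref, atol=1e-12)
        out = msc_correct(X)
        np.testing.assert_allclose(out.mean(axis=0), X.mean(axis=0), atol=1e-10)
        np.testing.assert_allclose(out, np.broadcast_to(ref, out.shape), atol=1e-10)

    def test_degenerate_slope_rejected(self):
        ref = np.linspace(0.2, 0.8, 64)
        flat = np.full((1, 64), 0.5)  # zero correlation with the reference
        with pytest.raises(ValueError, match="degenerate"):
            msc_correct(flat, reference=ref)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            msc_correct(np.random.default_rng(0).random((3, 10)), reference=np.ones(10))


class TestMovingAverage:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(moving_average(np.full(50, 3.3), 5), 3.3)

    def test_unit_impulse_window3(self):
        x = np.zeros(21)
        x[10] = 1.0
        out = moving_average(x, 3)
        np.testing.assert_allclose(out[9:12], 1 / 3)
        assert out.sum() == pytest.approx(1.0)

    def test_line_unchanged_at_interior(self):
        x = 2.0 + 0.7 * np.arange(60)
        out = moving_average(x, 5)
        np.testing.assert_allclose(out[2:-2], x[2:-2], atol=1e-10)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            moving_average(np.zeros(20), 4)
        with pytest.raises(ValueError):
            moving_average(np.zeros(10), 21)


class TestNormalize:
    def test_range_and_idempotence(self):
        rng = np.random.default_rng(5)
        x = rng.random(40) * 7 - 2
        out = normalize(x)
        assert out.min() == pytest.approx(0.0) and out.max() == pytest.approx(1.0)
        np.testing.assert_allclose(normalize(out), out, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.random(40)
        np.testing.assert_allclose(normalize(3.2 * x + 1.7), normalize(x), atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.full(10, 2.0))
        with pytest.raises(ValueError):
            snv(np.full(10, 2.0))


class TestPreprocessDispatch:
    @pytest.fixture()
    def spectra(self):
        rng = np.random.default_rng(9)
        X = rng.random((30, 128)) + 0.1
        y = np.array((["Hundred"] * 10) + (["One"] * 10) + (["BG"] * 10))
        return LabeledSpectra(X, y, np.linspace(400, 1000, 128))

    def test_nop_is_identity(self, spectra):
        out = preprocess(spectra, "NoP")
        np.testing.assert_array_equal(out.X, spectra.X)
        np.testing.assert_array_equal(out.y, spectra.y)

    @pytest.mark.parametrize("method", PREPROCESS_METHODS)
    def test_every_method_preserves_samples_and_labels(self, spectra, method):
        out = preprocess(spectra, method)
        assert out.X.shape == spectra.X.shape
        np.testing.assert_array_equal(out.y, spectra.y)
        assert out.meta["preprocess"] == method

    def test_unknown_method_rejected(self, spectra):
        with pytest.raises(ValueError, match="unknown"):
            preprocess(spectra, "SNV2")

    def test_d1_feeds_classification_end_to_end(self, highsnr_spectra):
        from hsiplate.chemometrics import LinearDiscriminantClassifier

        pre = preprocess(highsnr_spectra, "D1")
        idx = np.random.default_rng(0).permutation(len(pre))
        tr, te = idx[:500], idx[500:]
        clf = LinearDiscriminantClassifier().fit(pre.X[tr], pre.y[tr])
        assert (clf.predict(pre.X[te]) == pre.y[te]).mean() > 0.9

    def test_sklearn_transformer_contract(self, spectra):
        proc = SpectralPreprocessor(method="MSC")
        Xt = proc.fit_transform(spectra.X)
        assert proc.get_params()["method"] == "MSC"
        np.testing.assert_allclose(proc.reference_, spectra.X.mean(axis=0))
        assert Xt.shape == spectra.X.shape
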