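"""Synthetic plate simulator: forward model, ground truth, invariants."""

import numpy as np
import pytest

from hsiplate.io import DEFAULT_WAVELENGTHS, calibrate_reflectance
from hsiplate.simulate import (
    LayoutError,
    PlateLayout,
    SpectralModel,
    droplet_reflectance,
    extract_labeled_spectra,
    generate_plate,
    generate_training_pairs,
)
from hsiplate.spectra import CLASS_ORDER, DILUTION_OF_CLASS


class TestDropletReflectance:
    def test_zero_concentration_is_bare_background(self):
        m = SpectralModel()
        np.testing.assert_array_equal(
            droplet_reflectance(m, 0.0), m.background_profile()
        )

    def test_strictly_decreasing_in_concentration_at_features(self):
        m = SpectralModel()
        for lam in m.feature_wavelengths:
            wl = np.array([lam])
            vals = [float(droplet_reflectance(m, c, wl)[0])
                    for c in (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 1.0)]
            assert np.all(np.diff(vals) < 0)

    def test_unit_depth_halving(self):
        # with contrast gain ln 2 and c = 1, tau * A = ln 2 at the unit peak
        m = SpectralModel(contrast_gain=np.log(2.0))
        A = m.absorber_profile()
        peak = int(np.argmax(A))
        r = droplet_reflectance(m, 1.0)
        np.testing.assert_allclose(r[peak], m.background_profile()[peak] / 2.0, rtol=1e-9)

    @pytest.mark.parametrize("c", [-0.1, 1.5])
    def test_concentration_bounds(self, c):
        with pytest.raises(ValueError):
            droplet_reflectance(SpectralModel(), c)


class TestGeneratePlate:
    def test_default_layout_has_90_disjoint_droplets(self, plate_sigma0):
        *_, truth, _ = plate_sigma0
        lm = truth.label_map
        assert lm.n_droplets == 90
        # disjoint: every nonzero label pixel carries exactly one id, and
        # the union of droplets equals the truth mask
        assert set(np.unique(lm.labels)) == set(range(91))
        np.testing.assert_array_equal(lm.labels > 0, truth.mask)
        area = truth.layout.droplet_area
        counts = np.bincount(lm.labels.ravel())[1:]
        assert np.all(counts == area)

    def test_noise_free_calibration_inverts_forward_model(self, plate_sigma0):
        raw, dark, white, truth, refl = plate_sigma0
        np.testing.assert_allclose(refl.data, truth.reflectance, atol=2e-5)

    def test_seed_determinism(self, small_layout):
        lay = PlateLayout(**small_layout)
        a = generate_plate(lay, SpectralModel(), seed=9)
        b = generate_plate(lay, SpectralModel(), seed=9)
        for x, y in zip(a[:3], b[:3]):
            np.testing.assert_array_equal(x.data, y.data)
        c = generate_plate(lay, SpectralModel(), seed=10)
        assert not np.array_equal(a[0].data, c[0].data)

    def test_calibration_error_shrinks_with_noise(self, small_layout):
        lay = PlateLayout(**small_layout)
        mads = []
        for sigma in (25.0, 5.0, 0.0):
            raw, dark, white, truth = generate_plate(
                lay, SpectralModel(noise_sigma=sigma), seed=2
            )
            refl = calibrate_reflectance(raw, dark, white)
            mads.append(float(np.abs(refl.data - truth.reflectance).mean()))
        assert mads[0] > mads[1] > mads[2]
        assert mads[2] < 1e-4

    def test_overlapping_layout_rejected(self):
        with pytest.raises(LayoutError, match="overlap"):
            PlateLayout(row_spacing=8, droplet_radius=6)

    def test_droplet_outside_plate_rejected(self):
        with pytest.raises(LayoutError, match="outside"):
            PlateLayout(plate_shape=(100, 220))


class TestTrainingPairs:
    def test_single_pair_mask_area(self):
        pairs = generate_training_pairs(1, seed=0)
        assert len(pairs) == 1
        img, mask = pairs[0]
        assert img.data.shape == mask.shape == (128, 128)
        # 16 grid droplets of radius 5..7 discs
        from skimage.measure import label

        assert label(mask, connectivity=2).max() == 16
        assert mask.sum() > 16 * 60  # at least the smallest-disc area each

    def test_seeded_reproducibility(self):
        a = generate_training_pairs(3, seed=5)
        b = generate_training_pairs(3, seed=5)
        for (ia, ma), (ib, mb) in zip(a, b):
            np.testing.assert_array_equal(ia.data, ib.data)
            np.testing.assert_array_equal(ma, mb)

    def test_jitter_keeps_droplets_inside_frame(self):
        # exhaustive check over 50 seeded plates: no mask pixel on the border
        for seed in range(50):
            _, mask = generate_training_pairs(1, seed=seed)[0]
            assert mask[0, :].sum() == 0 and mask[-1, :].sum() == 0
            assert mask[:, 0].sum() == 0 and mask[:, -1].sum() == 0

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError):
            generate_training_pairs(0)
        with pytest.raises(ValueError):
            generate_training_pairs(1, tau_range=(0.5, 0.1))


class TestExtractLabeledSpectra:
    def test_noise_free_droplet_pixels_identical(self, plate_sigma0):
        *_, truth, refl = plate_sigma0
        spectra = extract_labeled_spectra(refl, truth)
        lab = truth.label_map
        # pixels of droplet 1 all share one spectrum (up to the rim split)
        px = refl.data[lab.labels == 1]
        interior_rows = np.unique(np.round(px, 6), axis=0)
        assert len(interior_rows) <= 2  # interior value + rim value

    def test_class_histogram_matches_droplet_areas(self, plate_sigma0):
        *_, truth, refl = plate_sigma0
        spectra = extract_labeled_spectra(refl, truth)
        counts = spectra.class_counts()
        area = truth.layout.droplet_area
        for cls in DILUTION_OF_CLASS:
            assert counts[cls] == truth.layout.n_rows * area
        assert counts["BG"] == 12 * 10 * 10

    def test_bg_spectra_equal_background_profile_at_zero_noise(self, plate_sigma0):
        *_, truth, refl = plate_sigma0
        spectra = extract_labeled_spectra(refl, truth)
        bg = spectra.X[spectra.y == "BG"]
        model = SpectralModel()
        assert np.abs(bg - model.background_profile()[None, :]).max() < 2e-5

    def test_misaligned_dimensions_rejected(self, plate_sigma0, small_layout):
        *_, truth, _ = plate_sigma0
        raw, dark, white, _ = generate_plate(PlateLayout(**small_layout), seed=0)
        refl = calibrate_reflectance(raw, dark, white)
        with pytest.raises(ValueError, match="spatial"):
            extract_labeled_spectra(refl, truth)


class TestDropletMeanSpectra:
    def test_one_row_per_droplet_plus_bg_regions(self, plate_sigma0):
        from hsiplate.simulate import droplet_mean_spectra

        *_, truth, refl = plate_sigma0
        sp = droplet_mean_spectra(refl, truth)
        assert len(sp) == 90 + 12
        assert sp.class_counts()["BG"] == 12
        assert all(sp.class_counts()[c] == 15 for c in DILUTION_OF_CLASS)

    def test_mean_merges_rim_and_interior(self, plate_sigma0):
        from hsiplate.simulate import droplet_mean_spectra

        *_, truth, refl = plate_sigma0
        sp = droplet_mean_spectra(refl, truth)
        lab = truth.label_map.labels
        expect = refl.data[lab == 1].mean(axis=0)
        np.testing.assert_allclose(sp.X[0], expect, rtol=1e-6)


class TestSeparabilityControl:
    def test_class_means_pairwise_distinct_at_zero_noise(self, plate_sigma0):
        *_, truth, refl = plate_sigma0
        spectra = extract_labeled_spectra(refl, truth)
        means = {c: spectra.X[spectra.y == c].mean(axis=0) for c in CLASS_ORDER}
        for i, a in enumerate(CLASS_ORDER):
            for b in CLASS_ORDER[i + 1 :]:
                assert np.abs(means[a] - means[b]).max() > 1e-3

    def test_low_dilutions_overlap_in_pc_space_at_high_noise(self, small_layout):
        from sklearn.decomposition import PCA

        lay = PlateLayout(**small_layout)
        raw, dark, white, truth = generate_plate(
            lay, SpectralModel(noise_sigma=200.0), seed=3
        )
        refl = calibrate_reflectance(raw, dark, white, clip_policy=None)
        spectra = extract_labeled_spectra(refl, truth)
        scores = PCA(n_components=2).fit_transform(spectra.X - spectra.X.mean(axis=0))
        cls = spectra.y
        # between-mean distance of the faint classes below the within spread
        for a, b in (("Two", "One"), ("Five", "Two")):
            mu_a, mu_b = scores[cls == a].mean(axis=0), scores[cls == b].mean(axis=0)
            spread = 0.5 * (scores[cls == a].std(axis=0) + scores[cls == b].std(axis=0))
            assert np.linalg.norm(mu_a - mu_b) < 2.0 * np.linalg.norm(spread)
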