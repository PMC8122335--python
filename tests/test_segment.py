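"""Otsu / PCA droplet masking, labeling and background sampling."""

import warnings

import numpy as np
import pytest

from hsiplate.io import Hypercube
from hsiplate.segment import (
    LabelMap,
    MaskImage,
    apply_threshold,
    assign_classes,
    enhance_band_image,
    label_droplets,
    otsu_mask,
    otsu_threshold,
    pca_mask,
    sample_background_regions,
    to_8bit,
)
from hsiplate.simulate import PlateLayout, SpectralModel, generate_plate
from hsiplate.io import calibrate_reflectance


def exhaustive_otsu(hist: np.ndarray) -> int:
    """Independent oracle: brute-force between-class variance maximizer."""
    total = hist.sum()
    best_t, best_v = 0, -1.0
    levels = np.arange(256)
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * levels[: t + 1]).sum() / w0
        mu1 = (hist[t + 1 :] * levels[t + 1 :]).sum() / w1
        v = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_two_value_image_separated(self):
        img = np.concatenate([np.full(500, 10), np.full(500, 200)]).reshape(25, 40)
        t = otsu_threshold(img)
        hist = np.bincount(img.ravel(), minlength=256)
        assert t == exhaustive_otsu(hist)
        assert 10 <= t < 200

    def test_bimodal_gaussian_threshold_between_modes(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate(
            [rng.normal(60, 10, 5000), rng.normal(180, 10, 5000)]
        ).clip(0, 255).astype(np.uint8)
        t = otsu_threshold(vals.reshape(100, 100))
        assert t == exhaustive_otsu(np.bincount(vals, minlength=256))
        assert 60 < t < 180

    def test_matches_exhaustive_oracle_on_random_histograms(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n_levels = int(rng.integers(2, 40))
            levels = rng.choice(256, size=n_levels, replace=False)
            counts = rng.integers(1, 500, size=n_levels)
            img = np.repeat(levels, counts).astype(np.uint8)
            assert otsu_threshold(img.reshape(1, -1)) == exhaustive_otsu(
                np.bincount(img, minlength=256)
            )

    def test_agrees_with_skimage_on_smooth_histogram(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(5)
        img = np.concatenate(
            [rng.normal(70, 12, 4000), rng.normal(190, 15, 6000)]
        ).clip(0, 255).astype(np.uint8)
        t = otsu_threshold(img.reshape(100, 100))
        t_ref = threshold_otsu(img)
        assert abs(int(t) - int(t_ref)) <= 1  # bin-edge convention difference

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="single gray level"):
            otsu_threshold(np.full((10, 10), 42))


class TestApplyThreshold:
    def test_extremes_and_complement(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(16, 16))
        assert not apply_threshold(img, 255, "above").data.any()
        assert apply_threshold(img, -1, "above").data.all()
        above = apply_threshold(img, 100, "above").data
        below = apply_threshold(img, 100, "below").data
        np.testing.assert_array_equal(above, ~below)

    def test_unknown_polarity(self):
        with pytest.raises(ValueError):
            apply_threshold(np.zeros((4, 4)), 1, "sideways")


class TestEnhance:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 7.0)
        np.testing.assert_allclose(enhance_band_image(img).data, img, atol=1e-9)

    def test_salt_pixel_removed_by_median(self):
        from scipy.ndimage import median_filter

        img = np.full((21, 21), 10.0)
        img[10, 10] = 255.0
        out = enhance_band_image(img).data
        # oracle: direct 3x3 median evaluation removes the outlier entirely
        oracle = median_filter(img, size=3, mode="reflect")
        assert oracle[10, 10] == 10.0
        np.testing.assert_allclose(out, 10.0, atol=1e-6)

    def test_output_shape_preserved(self):
        rng = np.random.default_rng(2)
        img = rng.random((17, 31))
        assert enhance_band_image(img).data.shape == (17, 31)


class TestPcaMask:
    def test_two_band_toy_recovers_truth_via_eigen_oracle(self):
        # droplet pixels (1, 0), background (0, 1)
        truth = np.zeros((20, 20), dtype=bool)
        truth[5:9, 5:9] = True
        data = np.zeros((20, 20, 2))
        data[truth] = [1.0, 0.0]
        data[~truth] = [0.0, 1.0]
        cube = Hypercube(data, np.array([500.0, 700.0]), kind="reflectance")
        mask = pca_mask(cube)
        np.testing.assert_array_equal(mask.data, truth)
        # oracle: eigendecomposition of the 2x2 covariance separates groups
        X = data.reshape(-1, 2) - data.reshape(-1, 2).mean(axis=0)
        evals, evecs = np.linalg.eigh(X.T @ X / len(X))
        scores = X @ evecs[:, -1]
        assert (scores[truth.ravel()].mean() * scores[~truth.ravel()].mean()) < 0

    def test_explained_variance_sums_to_one_with_full_components(self, small_layout):
        raw, dark, white, _ = generate_plate(
            PlateLayout(**small_layout), SpectralModel(), seed=1
        )
        refl = calibrate_reflectance(raw, dark, white)
        mask = pca_mask(refl, n_components=refl.bands)
        assert mask.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_noise_free_plate_mask_identical_to_truth(self, plate_sigma0):
        *_, truth, refl = plate_sigma0
        mask = pca_mask(refl)
        np.testing.assert_array_equal(mask.data, truth.mask)
        assert mask.provenance == "pca"

    def test_constant_cube_rejected(self):
        cube = Hypercube(np.ones((8, 8, 4)), np.array([1.0, 2, 3, 4]), kind="reflectance")
        with pytest.raises(ValueError, match="constant"):
            pca_mask(cube)


class TestLabelDroplets:
    def test_empty_mask(self):
        assert label_droplets(np.zeros((10, 10), dtype=bool)).n_droplets == 0

    def test_single_circle(self):
        yy, xx = np.mgrid[-10:11, -10:11]
        mask = (yy**2 + xx**2) <= 36
        lm = label_droplets(mask)
        assert lm.n_droplets == 1
        np.testing.assert_array_equal(lm.labels > 0, mask)

    def test_noise_free_plate_yields_90(self, plate_sigma0):
        *_, truth, refl = plate_sigma0
        mask = otsu_mask(refl)
        lm = label_droplets(mask, min_area=int(0.25 * truth.layout.droplet_area))
        assert lm.n_droplets == 90

    def test_min_area_filters_speckle(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:6, 2:6] = True  # area 16
        mask[15, 15] = True  # speckle
        assert label_droplets(mask, min_area=4).n_droplets == 1
        assert label_droplets(mask, min_area=0).n_droplets == 2

    def test_raster_order_ids_stable(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[8:10, 1:3] = True  # lower-left, later in raster order
        mask[1:3, 8:10] = True  # upper-right, earlier
        lm = label_droplets(mask)
        assert lm.labels[1, 8] == 1 and lm.labels[8, 1] == 2
        # component pixel sets identical regardless of labeling pass
        np.testing.assert_array_equal(lm.labels > 0, mask)


class TestAssignClasses:
    def test_truth_mask_labeling_matches_ground_truth(self, plate_sigma0):
        *_, truth, refl = plate_sigma0
        lm = label_droplets(truth.mask)
        assigned = assign_classes(lm, truth.layout)
        assert assigned.id_to_class == truth.label_map.id_to_class

    def test_shifted_mask_keeps_classes(self, plate_sigma0):
        *_, truth, _ = plate_sigma0
        shifted = np.roll(truth.mask, shift=(2, 2), axis=(0, 1))
        assigned = assign_classes(label_droplets(shifted), truth.layout)
        assert assigned.id_to_class == truth.label_map.id_to_class

    def test_spurious_blob_flagged_unassigned(self, plate_sigma0):
        *_, truth, _ = plate_sigma0
        layout = truth.layout
        mask = truth.mask.copy()
        mask[246:252, 206:212] = True  # far corner, off the droplet grid
        with pytest.warns(UserWarning, match="unassigned"):
            assigned = assign_classes(label_droplets(mask), layout)
        assert None in assigned.id_to_class.values()
        assert sum(v is None for v in assigned.id_to_class.values()) == 1


class TestBackgroundRegions:
    def test_default_call_yields_12_disjoint_regions(self, plate_sigma0):
        *_, truth, _ = plate_sigma0
        regions = sample_background_regions(truth.mask, seed=4)
        assert len(regions) == 12
        cover = np.zeros_like(truth.mask, dtype=int)
        for r, c, s in regions:
            cover[r : r + s, c : c + s] += 1
        assert cover.max() == 1  # pairwise disjoint
        assert not (cover.astype(bool) & truth.mask).any()

    def test_seed_determinism(self, plate_sigma0):
        *_, truth, _ = plate_sigma0
        assert sample_background_regions(truth.mask, seed=4) == sample_background_regions(
            truth.mask, seed=4
        )

    def test_full_plate_mask_rejected(self):
        with pytest.raises(ValueError, match="background"):
            sample_background_regions(np.ones((64, 64), dtype=bool), seed=0)


class TestMaskAgreementUnderNoise:
    def test_iou_nonincreasing_with_noise(self, small_layout):
        lay = PlateLayout(**small_layout)
        ious = []
        for sigma in (0.0, 60.0, 200.0):
            raw, dark, white, truth = generate_plate(
                lay, SpectralModel(noise_sigma=sigma), seed=6
            )
            refl = calibrate_reflectance(raw, dark, white, clip_policy=None)
            m = otsu_mask(refl).data
            ious.append((m & truth.mask).sum() / (m | truth.mask).sum())
        assert ious[0] == pytest.approx(1.0, abs=1e-12) or ious[0] > 0.95
        assert ious[0] >= ious[1] - 0.02 >= ious[2] - 0.04
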