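"""Droplet ROI segmentation on a feature-band image or PCA score image.

Three mask routes are supported: global Otsu thresholding of an enhanced
8-bit band image, thresholding of the first principal-component score image,
and (in :mod:`hsiplate.unet`) a trained encoder-decoder network.  Masks are
cleaned, connected components are labeled as droplets, droplets are assigned
dilution classes from the known plate grid, and background sampling regions
are drawn away from the droplets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import unsharp_mask

from .io import Hypercube, Image2D

__all__ = [
    "otsu_mask",
    "MaskImage",
    "LabelMap",
    "otsu_threshold",
    "apply_threshold",
    "to_8bit",
    "enhance_band_image",
    "pca_mask",
    "label_droplets",
    "assign_classes",
    "sample_background_regions",
    "OTSU_PRESETS",
    "DEFAULT_FEATURE_BAND_NM",
]

#: fixed global thresholds reported for the two residue types (8-bit scale)
OTSU_PRESETS = {"spinach": 110, "potato": 98}

#: band used for mask building by default; a strong absorption feature of
#: vegetable residues (chlorophyll region)
DEFAULT_FEATURE_BAND_NM = 720.0


@dataclass
class MaskImage:
    """Binary droplet mask with provenance ('otsu', 'pca', 'unet', 'truth')."""

    data: np.ndarray
    provenance: str = "otsu"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelMap:
    """Integer droplet ids per pixel (0 = background) plus id->class map."""

    labels: np.ndarray
    id_to_class: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)

    @property
    def n_droplets(self) -> int:
        return int(self.labels.max())

    def centroids(self) -> np.ndarray:
        """(n, 2) array of droplet centroids (line, sample), id order."""
        n = self.n_droplets
        if n == 0:
            return np.empty((0, 2))
        return np.asarray(ndimage.center_of_mass(self.labels > 0, self.labels, np.arange(1, n + 1)))

    def to_table(self) -> pd.DataFrame:
        cents = self.centroids()
        return pd.DataFrame(
            {
                "droplet_id": np.arange(1, self.n_droplets + 1),
                "line": cents[:, 0] if len(cents) else [],
                "sample": cents[:, 1] if len(cents) else [],
                "class": [self.id_to_class.get(i) for i in range(1, self.n_droplets + 1)],
            }
        )


def otsu_threshold(image_8bit: np.ndarray) -> int:
    """Otsu's global threshold on a 256-gray-level image.

    Returns the integer level ``t`` maximizing the between-class variance
    ``omega0 * omega1 * (mu0 - mu1)**2`` of the histogram split
    ``{<= t} / {> t}``.  Ties resolve to the lowest level, so the result is
    deterministic.
    """
    img = np.asarray(image_8bit)
    hist = np.bincount(img.astype(np.int64).ravel(), minlength=256)[:256].astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: image has a single gray level")
    # cumulative class weight and mean for every candidate split
    omega0 = np.cumsum(hist) / total
    mu_cum = np.cumsum(hist * np.arange(256)) / total
    mu_total = mu_cum[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / omega0
        mu1 = (mu_total - mu_cum) / omega1
        sigma_b = omega0 * omega1 * (mu0 - mu1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))


def apply_threshold(image, t: float, polarity: str = "above") -> MaskImage:
    """Binarize ``image`` at threshold ``t``; polarity 'above' or 'below'."""
    img = image.data if isinstance(image, Image2D) else np.asarray(image)
    if polarity == "above":
        return MaskImage(img > t, provenance="otsu")
    if polarity == "below":
        return MaskImage(img <= t, provenance="otsu")
    raise ValueError(f"polarity must be 'above' or 'below', got {polarity!r}")


def to_8bit(image, p_low: float = 2.0, p_high: float = 98.0) -> np.ndarray:
    """Percentile-stretch an image to uint8 [0, 255].

    Clipping at the 2nd/98th percentiles suppresses specular outliers before
    histogram thresholding.
    """
    img = (image.data if isinstance(image, Image2D) else np.asarray(image)).astype(float)
    lo, hi = np.percentile(img, [p_low, p_high])
    if hi <= lo:
        lo, hi = img.min(), img.max()
        if hi <= lo:
            return np.zeros(img.shape, dtype=np.uint8)
    scaled = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    return np.round(scaled * 255).astype(np.uint8)


def enhance_band_image(image, median_size: int = 3, unsharp_radius: float = 1.0,
                       unsharp_amount: float = 1.0) -> Image2D:
    """Median-filter then unsharp-mask a band image (quality enhancement)."""
    img = image.data if isinstance(image, Image2D) else np.asarray(image)
    wavelength = image.wavelength_nm if isinstance(image, Image2D) else None
    med = ndimage.median_filter(img.astype(float), size=median_size, mode="reflect")
    sharp = unsharp_mask(med, radius=unsharp_radius, amount=unsharp_amount, preserve_range=True)
    return Image2D(sharp, wavelength_nm=wavelength)


def otsu_mask(cube: Hypercube, feature_band_nm: float = DEFAULT_FEATURE_BAND_NM,
              enhance: bool = True) -> MaskImage:
    """Full Otsu route: band image -> enhance -> 8-bit -> Otsu -> dark side.

    Residue droplets absorb at the feature band, so the mask takes the side
    of the threshold that is darker *and* smaller; on a plate the droplets
    are always the minority phase.
    """
    from .io import band_image

    img = band_image(cube, feature_band_nm)
    if enhance:
        img = enhance_band_image(img)
    img8 = to_8bit(img)
    t = otsu_threshold(img8)
    below = img8 <= t
    mask = below if below.sum() <= below.size / 2 else ~below
    return MaskImage(mask, provenance="otsu")


def pca_mask(cube: Hypercube, n_components: int = 1, score_threshold_rule: str = "otsu"
             ) -> MaskImage:
    """Mask from the first principal-component score image.

    The pixels-by-bands matrix is mean-centered and projected on PC1; the
    score image is Otsu-thresholded.  Polarity is chosen so the droplet
    (True) class is the minority, since droplets cover a small plate
    fraction.  The explained-variance ratios of the fitted components are
    attached to the returned mask as ``explained_variance_ratio``.
    """
    from sklearn.decomposition import PCA

    X = cube.data.reshape(-1, cube.bands).astype(np.float64)
    if np.allclose(X, X[0]):
        raise ValueError("constant cube: PCA scores undefined")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X - X.mean(axis=0))
    score_img = scores[:, 0].reshape(cube.data.shape[:2])
    if score_threshold_rule != "otsu":
        raise ValueError(f"unknown score_threshold_rule {score_threshold_rule!r}")
    t = otsu_threshold(to_8bit(score_img))
    below = to_8bit(score_img) <= t
    mask = below if below.sum() <= below.size / 2 else ~below
    out = MaskImage(mask, provenance="pca")
    out.explained_variance_ratio = pca.explained_variance_ratio_  # type: ignore[attr-defined]
    return out


def label_droplets(mask, min_area: int = 0) -> LabelMap:
    """8-connected components of area >= ``min_area``, ids 1..n in raster order.

    Raster order means components are numbered by the position of their
    first pixel in row-major scan, so labeling is independent of how the
    mask was produced.
    """
    m = mask.data if isinstance(mask, MaskImage) else np.asarray(mask, dtype=bool)
    lab = measure.label(m, connectivity=2)
    out = np.zeros_like(lab, dtype=np.int32)
    next_id = 1
    # scan ids by first-pixel raster position
    flat = lab.ravel()
    first_pos = {}
    for pos in np.flatnonzero(flat):
        lid = flat[pos]
        if lid not in first_pos:
            first_pos[lid] = pos
    for lid in sorted(first_pos, key=first_pos.get):
        comp = lab == lid
        if comp.sum() >= min_area:
            out[comp] = next_id
            next_id += 1
    return LabelMap(out)


def assign_classes(labelmap: LabelMap, layout, max_distance: float | None = None) -> LabelMap:
    """Map each droplet id to the dilution class of the nearest grid position.

    ``layout`` is a :class:`hsiplate.simulate.PlateLayout` (or anything with
    ``positions()`` returning (line, sample, class) tuples).  Droplets whose
    centroid lies farther than ``max_distance`` (default: half the smaller
    grid spacing) from every position are flagged unassigned (class None)
    with a warning.
    """
    positions = layout.positions()
    grid = np.array([[p[0], p[1]] for p in positions], dtype=float)
    classes = [p[2] for p in positions]
    if max_distance is None:
        max_distance = min(layout.row_spacing, layout.col_spacing) / 2.0
    cents = labelmap.centroids()
    id_to_class: dict[int, str | None] = {}
    for i, c in enumerate(cents, start=1):
        d = np.hypot(grid[:, 0] - c[0], grid[:, 1] - c[1])
        j = int(np.argmin(d))
        if d[j] > max_distance:
            warnings.warn(
                f"droplet {i} centroid {tuple(np.round(c, 1))} is {d[j]:.1f} px from the "
                "nearest grid position; left unassigned"
            )
            id_to_class[i] = None
        else:
            id_to_class[i] = classes[j]
    return LabelMap(labelmap.labels.copy(), id_to_class)


def sample_background_regions(
    mask,
    n_regions: int = 12,
    region_size: int = 10,
    seed: int = 0,
    dilate: int = 3,
    max_tries: int = 20000,
) -> list[tuple[int, int, int]]:
    """Seeded non-overlapping square background regions away from droplets.

    Returns ``n_regions`` tuples ``(line, sample, size)`` (top-left corners)
    whose squares are disjoint from the droplet mask dilated by ``dilate``
    pixels, and pairwise disjoint.  Raises if the background cannot host
    them.
    """
    m = mask.data if isinstance(mask, MaskImage) else np.asarray(mask, dtype=bool)
    forbidden = ndimage.binary_dilation(m, iterations=dilate) if dilate > 0 else m.copy()
    H, W = m.shape
    if H < region_size or W < region_size:
        raise ValueError("image smaller than requested region size")
    rng = np.random.default_rng(seed)
    taken = np.zeros_like(m, dtype=bool)
    regions: list[tuple[int, int, int]] = []
    for _ in range(max_tries):
        if len(regions) == n_regions:
            break
        r = int(rng.integers(0, H - region_size + 1))
        c = int(rng.integers(0, W - region_size + 1))
        sl = (slice(r, r + region_size), slice(c, c + region_size))
        if forbidden[sl].any() or taken[sl].any():
            continue
        taken[sl] = True
        regions.append((r, c, region_size))
    if len(regions) < n_regions:
        raise ValueError(
            f"could only place {len(regions)} of {n_regions} background regions; "
            "insufficient background area"
        )
    return regions


def regions_to_mask(regions, shape) -> np.ndarray:
    """Boolean mask covering a list of (line, sample, size) squares."""
    out = np.zeros(shape, dtype=bool)
    for r, c, s in regions:
        out[r : r + s, c : c + s] = True
    return out
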