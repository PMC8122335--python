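"""End-to-end pipeline: simulate -> calibrate -> segment -> extract ->
preprocess -> classify -> evaluate, driven by one seeded config.

Two classification routes mirror the study design: chemometric classifiers
scored by leave-one-out cross-validation, and the 1-D CNN scored on a
stratified calibration/validation split (accuracies Ac and Av).

Every run writes its artifacts plus a manifest (config, seed, package
versions) to the output directory; re-running the manifest reproduces the
report byte for byte.  Stage seeds are spawned deterministically from the
master seed so stages re-run in isolation match the full run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .chemometrics import CHEMOMETRIC_METHODS, ClassifierSpec, loo_cv
from .cnn1d import CNN1DClassifier, split_calibration_validation
from .evaluate import EvalReport, plot_confusion_matrix, report
from .io import calibrate_reflectance
from .preprocess import PREPROCESS_METHODS, preprocess
from .segment import (
    DEFAULT_FEATURE_BAND_NM,
    assign_classes,
    label_droplets,
    otsu_mask,
    pca_mask,
)
from .simulate import (
    GroundTruth,
    PlateLayout,
    SpectralModel,
    extract_labeled_spectra,
    generate_plate,
    generate_training_pairs,
)
from .spectra import LabeledSpectra

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

_SEGMENTERS = ("otsu", "pca", "unet", "truth")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    seed: int = 0
    outdir: str = "hsiplate_run"
    # simulation
    layout: dict = field(default_factory=dict)  # PlateLayout overrides
    model: dict = field(default_factory=dict)  # SpectralModel overrides
    # segmentation
    segmentation: str = "otsu"
    feature_band_nm: float = DEFAULT_FEATURE_BAND_NM
    unet_epochs: int = 15
    unet_pairs: int = 12
    # classification
    preprocessing: str = "NoP"
    aggregate: str = "pixel"  # 'pixel' spectra or per-'droplet' means
    classifier: str = "SVM"  # chemometric method name or 'cnn1d'
    cnn_epochs: int = 100
    split_fraction: float = 0.7
    max_spectra_per_class: int = 30

    def validate(self) -> None:
        if self.segmentation not in _SEGMENTERS:
            raise PipelineError("config", f"segmentation must be one of {_SEGMENTERS}")
        if self.preprocessing not in PREPROCESS_METHODS:
            raise PipelineError(
                "config", f"preprocessing must be one of {PREPROCESS_METHODS}"
            )
        if self.classifier != "cnn1d" and self.classifier not in CHEMOMETRIC_METHODS:
            raise PipelineError(
                "config",
                f"classifier must be 'cnn1d' or one of {CHEMOMETRIC_METHODS}",
            )
        if self.aggregate not in ("pixel", "droplet"):
            raise PipelineError("config", "aggregate must be 'pixel' or 'droplet'")
        if not 0 < self.split_fraction < 1:
            raise PipelineError("config", "split_fraction must be in (0, 1)")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self)))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed (< 2^31) from the master seed."""
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(ss.generate_state(1)[0] % (2**31))


def _segment(config: RunConfig, refl, truth: GroundTruth):
    if config.segmentation == "truth":
        from .segment import MaskImage

        return MaskImage(truth.mask.copy(), provenance="truth")
    if config.segmentation == "otsu":
        return otsu_mask(refl, config.feature_band_nm)
    if config.segmentation == "pca":
        return pca_mask(refl)
    # unet: train on randomized synthetic pairs, predict the plate band image
    from .io import band_image
    from .unet import UNetSegmenter

    seed = config.stage_seed("unet")
    pairs = generate_training_pairs(
        config.unet_pairs,
        layout=truth.layout,
        model=SpectralModel(**config.model),
        seed=seed,
    )
    seg = UNetSegmenter(epochs=config.unet_epochs, random_state=seed)
    seg.fit_pairs(pairs)
    img = band_image(refl, config.feature_band_nm).data
    H, W = img.shape
    f = 2**seg.depth
    Hp, Wp = -(-H // f) * f, -(-W // f) * f  # pad up to a multiple of 2^depth
    padded = np.pad(img, ((0, Hp - H), (0, Wp - W)), mode="reflect")
    pred = seg.predict(padded[None])[0][:H, :W]
    from .segment import MaskImage

    return MaskImage(pred, provenance="unet")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full flow; returns a dict of artifact paths and results."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"outdir": outdir}

    # --- simulate + calibrate -------------------------------------------
    try:
        layout = PlateLayout(**config.layout)
        model = SpectralModel(**config.model)
        raw, dark, white, truth = generate_plate(
            layout, model, seed=config.stage_seed("simulate")
        )
        refl = calibrate_reflectance(raw, dark, white)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", str(e)) from e

    # --- segment ---------------------------------------------------------
    try:
        mask = _segment(config, refl, truth)
        min_area = max(1, int(0.25 * layout.droplet_area))
        labelmap = assign_classes(label_droplets(mask, min_area=min_area), layout)
        labelmap.to_table().to_csv(outdir / "droplets.csv", index=False)
        artifacts["droplets"] = outdir / "droplets.csv"
        artifacts["n_droplets"] = labelmap.n_droplets
        artifacts["mask"] = _save_mask(mask, outdir / "mask.png")
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("segment", str(e)) from e

    # --- extract + subsample ---------------------------------------------
    try:
        if config.aggregate == "droplet":
            from .simulate import droplet_mean_spectra

            spectra = droplet_mean_spectra(refl, truth)
        else:
            spectra = extract_labeled_spectra(refl, truth)
            spectra = _subsample(
                spectra, config.max_spectra_per_class, config.stage_seed("extract")
            )
        spectra.to_csv(outdir / "spectra.csv")
        artifacts["spectra"] = outdir / "spectra.csv"
    except Exception as e:  # noqa: BLE001
        raise PipelineError("extract", str(e)) from e

    # --- preprocess -------------------------------------------------------
    try:
        pre = preprocess(spectra, config.preprocessing)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("preprocess", str(e)) from e

    # --- classify + evaluate ---------------------------------------------
    try:
        results = _classify(config, pre)
        df = report(results, outdir / "eval_report.csv")
        artifacts["report"] = outdir / "eval_report.csv"
        artifacts["results"] = results
        artifacts["report_frame"] = df
        for r in results:
            png = outdir / f"confusion_{r.method}_{r.split}.png"
            plot_confusion_matrix(r.cm, png, title=f"{r.method} ({r.split})")
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("classify", str(e)) from e

    manifest = {
        "config": dataclasses.asdict(config),
        "versions": _versions(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = outdir / "manifest.json"
    return artifacts


def _classify(config: RunConfig, pre: LabeledSpectra) -> list[EvalReport]:
    if config.classifier == "cnn1d":
        split = split_calibration_validation(
            pre, config.split_fraction, seed=config.stage_seed("split")
        )
        clf = CNN1DClassifier(
            epochs=config.cnn_epochs, random_state=config.stage_seed("cnn1d")
        )
        clf.fit(split.calibration.X, split.calibration.y)
        cm_c, _ = clf.evaluate(split.calibration.X, split.calibration.y)
        cm_v, _ = clf.evaluate(split.validation.X, split.validation.y)
        return [
            EvalReport(cm_c, "cnn1d", config.preprocessing, "synthetic", "calibration"),
            EvalReport(cm_v, "cnn1d", config.preprocessing, "synthetic", "validation"),
        ]
    spec = ClassifierSpec(method=config.classifier, seed=config.stage_seed("classify"))
    cm = loo_cv(spec, pre.X, pre.y)
    return [EvalReport(cm, config.classifier, config.preprocessing, "synthetic", "LOO")]


def _subsample(spectra: LabeledSpectra, per_class: int, seed: int) -> LabeledSpectra:
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for cls in np.unique(spectra.y):
        idx = np.flatnonzero(spectra.y == cls)
        if len(idx) > per_class:
            idx = rng.choice(idx, size=per_class, replace=False)
        keep.extend(idx.tolist())
    return spectra.subset(np.sort(keep))


def _save_mask(mask, path: Path) -> Path:
    from imageio.v3 import imwrite

    imwrite(path, (np.asarray(mask.data, dtype=np.uint8) * 255))
    return path


def _versions() -> dict:
    import sklearn
    import scipy

    return {
        "hsiplate": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }
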