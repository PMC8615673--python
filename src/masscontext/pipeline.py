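"""End-to-end orchestration: manifests, image I/O, train and eval runs.

A dataset is a CSV manifest with columns ``image_path, row_min, col_min,
row_max, col_max, label, density`` pointing at PNG or DICOM images, one
annotated mass per row.  ``run_train`` fits a
:class:`~masscontext.estimator.ContextEnsembleClassifier` and serializes
a bundle (backbone weights + graph sidecar + stacker + config);
``run_eval`` scores a test manifest and writes a metrics report plus
per-case and per-ROI audit files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd

from . import backbone as bb
from .datatypes import BoundingBox, Density, GrayImage, Label, MassRegion
from .enhancement import EnhancementConfig
from .augmentation import AugmentationPlan
from .estimator import ContextEnsembleClassifier
from .metrics import MetricsReport, compute_metrics, confusion_from_predictions, roc_auc
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger("masscontext")

MANIFEST_COLUMNS = (
    "image_path", "row_min", "col_min", "row_max", "col_max", "label", "density",
)

_LABELS = {"benign": Label.BENIGN, "malignant": Label.MALIGNANT}
_DENSITIES = {"I": Density.I, "II": Density.II, "III": Density.III, "IV": Density.IV}


class ManifestError(ValueError):
    """A manifest row or file violates the input contract."""


# ---------------------------------------------------------------------------
# image IO
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> GrayImage:
    """Read a grayscale PNG or DICOM image."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        pixels = ds.pixel_array
        if ds.get("PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
            pixels = pixels.max() - pixels
        depth = 16 if pixels.dtype.itemsize > 1 else 8
        return GrayImage(pixels, bit_depth=depth)
    import imageio.v3 as iio

    pixels = iio.imread(path)
    if pixels.ndim == 3:
        pixels = pixels[..., 0]
    depth = 16 if pixels.dtype.itemsize > 1 else 8
    return GrayImage(pixels, bit_depth=depth)


def write_image(path: str | Path, image: GrayImage) -> None:
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        _write_synthetic_dicom(path, image)
        return
    import imageio.v3 as iio

    iio.imwrite(path, image.pixels)


def _write_synthetic_dicom(path: Path, image: GrayImage) -> None:
    """Minimal synthetic secondary-capture DICOM writer (fixture/testing
    use only — carries pixel data and geometry, no clinical metadata)."""
    import pydicom
    from pydicom.dataset import FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[str(path)])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = pydicom.Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = image.shape
    ds.BitsAllocated = 16 if image.bit_depth == 16 else 8
    ds.BitsStored = image.bit_depth
    ds.HighBit = image.bit_depth - 1
    ds.PixelRepresentation = 0
    dtype = np.uint16 if image.bit_depth == 16 else np.uint8
    ds.PixelData = np.ascontiguousarray(image.pixels.astype(dtype)).tobytes()
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(
    regions: Sequence[MassRegion], out_dir: str | Path, image_format: str = "png"
) -> Path:
    """Write region images plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, region in enumerate(regions):
        name = region.region_id or f"region_{i:05d}"
        img_path = out_dir / f"{name}.{image_format}"
        write_image(img_path, region.image)
        rows.append(
            {
                "image_path": img_path.name,
                "row_min": region.bbox.row_min,
                "col_min": region.bbox.col_min,
                "row_max": region.bbox.row_max,
                "col_max": region.bbox.col_max,
                "label": region.label.name.lower() if region.label is not None else "",
                "density": region.density.name if region.density is not None else "",
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


def read_manifest(path: str | Path) -> list[MassRegion]:
    """Load and validate all regions of a manifest.

    Raises :class:`ManifestError` naming the offending row for missing
    columns, bad bounding boxes or unreadable images.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"label": str, "density": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ManifestError(f"manifest {path} lacks columns: {sorted(missing)}")
    regions = []
    for i, row in df.iterrows():
        img_path = Path(row["image_path"])
        if not img_path.is_absolute():
            img_path = path.parent / img_path
        try:
            image = read_image(img_path)
        except Exception as exc:  # noqa: BLE001 - rewrap with row context
            raise ManifestError(f"row {i}: cannot read image {img_path}: {exc}") from exc
        try:
            bbox = BoundingBox(
                int(row["row_min"]), int(row["col_min"]),
                int(row["row_max"]), int(row["col_max"]),
            )
        except ValueError as exc:
            raise ManifestError(f"row {i}: invalid bounding box: {exc}") from exc
        label = _LABELS.get(str(row["label"]).strip().lower())
        density = _DENSITIES.get(str(row["density"]).strip())
        try:
            regions.append(
                MassRegion(image, bbox, label=label, density=density,
                           region_id=img_path.stem)
            )
        except ValueError as exc:
            raise ManifestError(f"row {i}: {exc}") from exc
    return regions


def filter_by_density(
    regions: Sequence[MassRegion], density: Optional[str]
) -> list[MassRegion]:
    """Restrict to one BI-RADS class (density-specific protocol)."""
    if density is None:
        return list(regions)
    if density not in _DENSITIES:
        raise ValueError(f"unknown density class {density!r}")
    want = _DENSITIES[density]
    out = [r for r in regions if r.density == want]
    if not out:
        raise ValueError(f"no regions with density {density}")
    return out


# ---------------------------------------------------------------------------
# runs
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One training/evaluation run."""

    scheme: str = "MC2"
    variant: str = "tiny"
    fusion: str = "stack-rbf"
    enhancement_enabled: bool = False
    density_filter: Optional[str] = None
    epochs: int = 10
    batch_size: int = 64
    learning_rate: Optional[float] = None
    validation_fraction: float = 0.10
    augmentation: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def build_estimator(self) -> ContextEnsembleClassifier:
        enh = EnhancementConfig() if self.enhancement_enabled else None
        plan = AugmentationPlan(seed=self.seed, **self.augmentation)
        return ContextEnsembleClassifier(
            scheme=self.scheme, variant=self.variant, fusion=self.fusion,
            enhancement=enh, augmentation_plan=plan,
            learning_rate=self.learning_rate, epochs=self.epochs,
            batch_size=self.batch_size,
            validation_fraction=self.validation_fraction,
            random_state=self.seed,
        )


def run_train(
    config: RunConfig, train_manifest: str | Path, out_dir: str | Path
) -> ContextEnsembleClassifier:
    """Fit the estimator on a manifest and serialize the model bundle."""
    regions = filter_by_density(read_manifest(train_manifest), config.density_filter)
    logger.info("training on %d regions (%s/%s/%s)",
                len(regions), config.scheme, config.variant, config.fusion)
    clf = config.build_estimator()
    clf.fit(regions)
    save_bundle(out_dir, clf, config)
    return clf


def save_bundle(
    out_dir: str | Path, clf: ContextEnsembleClassifier, config: RunConfig
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bb.save_model(out / "backbone.npz", clf.backbone_)
    if clf.stacker_ is not None:
        joblib.dump(clf.stacker_, out / "stacker.joblib")
    (out / "run_config.json").write_text(json.dumps(asdict(config), indent=1))


def load_bundle(out_dir: str | Path) -> ContextEnsembleClassifier:
    out = Path(out_dir)
    config = RunConfig(**json.loads((out / "run_config.json").read_text()))
    clf = config.build_estimator()
    clf.backbone_ = bb.load_model(out / "backbone.npz")
    clf.arch_spec_ = clf.backbone_.spec
    clf.stacker_ = (
        joblib.load(out / "stacker.joblib")
        if (out / "stacker.joblib").exists()
        else None
    )
    clf.classes_ = np.array([0, 1])
    from .roi_context import n_rois

    clf.n_rois_ = n_rois(config.scheme)
    return clf


def run_eval(
    clf: ContextEnsembleClassifier,
    test_manifest: str | Path,
    out_dir: Optional[str | Path] = None,
    density_filter: Optional[str] = None,
) -> MetricsReport:
    """Score a test manifest; optionally write report + audit CSVs.

    The per-ROI probabilities of every case are retained so fused
    decisions can be re-derived offline under any fusion rule.
    """
    regions = filter_by_density(read_manifest(test_manifest), density_filter)
    if any(r.label is None for r in regions):
        raise ManifestError("evaluation requires labeled regions")
    y_true = np.array([int(r.label) for r in regions])

    roi_probs = clf.roi_probabilities(regions)
    y_pred = clf.predict(regions)
    scores = clf.predict_proba(regions)[:, 1]

    report = compute_metrics(confusion_from_predictions(y_true, y_pred))
    if np.unique(y_true).size == 2:
        report.auc = roc_auc(scores, y_true)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "region_id": [r.region_id for r in regions],
                "label": y_true,
                "prediction": y_pred,
                "malignant_score": scores,
            }
        ).to_csv(out / "predictions.csv", index=False)
        np.save(out / "roi_probabilities.npy", roi_probs)
        (out / "metrics.json").write_text(json.dumps(report.as_dict(), indent=1))
    return report


def make_synthetic_manifests(
    out_dir: str | Path,
    config: SyntheticConfig | None = None,
    image_format: str = "png",
) -> tuple[Path, Path]:
    """Generate a phantom dataset and write train/test manifests."""
    ds = generate_dataset(config)
    out = Path(out_dir)
    train = write_manifest(ds.train, out / "train", image_format)
    test = write_manifest(ds.test, out / "test", image_format)
    return train, test
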