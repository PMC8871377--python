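"""Dataset and artifact plumbing.

Datasets live in class-labeled folders (``root/NORMAL``, ``root/DRY_AMD``,
``root/WET_AMD`` — or ``root/AMD`` for pre-binarized data), mirroring how
the public OCT collections are distributed.  Everything on disk is plain
text or standard rasters: PNG/JPEG/TIFF images in, CSV manifests /
feature tables / score tables and JSON configs and reports out.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image, UnidentifiedImageError

from .data import BinaryLabel, ImageSet, Label, LabeledImage

log = logging.getLogger("octanomaly")

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}
_LABEL_FOLDERS = {
    "NORMAL": Label.NORMAL,
    "DRY_AMD": Label.DRY_AMD,
    "WET_AMD": Label.WET_AMD,
    "AMD": Label.AMD,  # pre-binarized folders: morphology unspecified
}


class DataError(RuntimeError):
    """Unreadable or malformed input data."""


@dataclass
class ManifestRecord:
    path: str
    label: str
    binary_label: str
    ok: bool = True
    error: str = ""


@dataclass
class DatasetManifest:
    root: str
    records: list[ManifestRecord] = field(default_factory=list)

    @property
    def classes(self) -> list[str]:
        return sorted({r.label for r in self.records})

    @property
    def valid_records(self) -> list[ManifestRecord]:
        return [r for r in self.records if r.ok]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([r.__dict__ for r in self.records]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, root: str = "") -> "DatasetManifest":
        df = pd.read_csv(path, keep_default_na=False)
        records = [
            ManifestRecord(
                path=str(row["path"]), label=str(row["label"]),
                binary_label=str(row["binary_label"]),
                ok=bool(row.get("ok", True)), error=str(row.get("error", "")),
            )
            for _, row in df.iterrows()
        ]
        return cls(root=root, records=records)


def scan_dataset(root: str | Path) -> DatasetManifest:
    """Deterministically enumerate a class-foldered image tree.

    Folders are visited in sorted order and so are files; unreadable
    images are listed with ``ok=False`` rather than dropped silently.
    """
    root = Path(root)
    if not root.is_dir():
        raise DataError(f"dataset root does not exist: {root}")
    records: list[ManifestRecord] = []
    for folder in sorted(p for p in root.iterdir() if p.is_dir()):
        label = _LABEL_FOLDERS.get(folder.name)
        if label is None:
            continue
        for f in sorted(folder.iterdir()):
            if f.suffix.lower() not in IMAGE_EXTENSIONS:
                continue
            rec = ManifestRecord(path=str(f), label=label.value,
                                 binary_label=label.binary.value)
            try:
                with Image.open(f) as img:
                    img.verify()
            except (UnidentifiedImageError, OSError) as exc:
                rec.ok = False
                rec.error = str(exc)
            records.append(rec)
    if not records:
        raise DataError(f"no class folders with images found under {root}")
    return DatasetManifest(root=str(root), records=records)


def load_image(
    path: str | Path,
    target_size: tuple[int, int] = (224, 224),
    channels: int = 3,
) -> np.ndarray:
    """Decode, bilinear-resize and scale an image to float [0, 1].

    Returns ``(H, W, channels)`` with grayscale inputs replicated across
    channels, or ``(H, W)`` when ``channels == 1``.
    """
    try:
        with Image.open(path) as img:
            gray = img.convert("L").resize(
                (target_size[1], target_size[0]), Image.Resampling.BILINEAR
            )
    except (UnidentifiedImageError, OSError) as exc:
        raise DataError(f"cannot decode image {path}: {exc}") from exc
    arr = np.asarray(gray, dtype=np.float64) / 255.0
    if channels == 1:
        return arr
    return np.repeat(arr[:, :, None], channels, axis=2)


def load_imageset(
    source: str | Path | DatasetManifest,
    target_size: tuple[int, int] = (224, 224),
) -> ImageSet:
    """Load all valid manifest records as grayscale images (network input layout)."""
    manifest = source if isinstance(source, DatasetManifest) else scan_dataset(source)
    images = []
    for rec in manifest.valid_records:
        px = load_image(rec.path, target_size=target_size, channels=1)
        images.append(LabeledImage(px, Label(rec.label), source=rec.path))
    return ImageSet(images)


def save_imageset(images: ImageSet, out_dir: str | Path, seed: Optional[int] = None) -> Path:
    """Write PNGs into ``out/<LABEL>/`` plus a CSV manifest."""
    out_dir = Path(out_dir)
    rows = []
    counters: dict[str, int] = {}
    for im in images:
        sub = out_dir / im.label.value
        sub.mkdir(parents=True, exist_ok=True)
        i = counters.get(im.label.value, 0)
        counters[im.label.value] = i + 1
        name = im.source or f"{im.label.value}_{i:05d}.png"
        path = sub / Path(name).name
        Image.fromarray(np.clip(im.pixels * 255.0, 0, 255).astype(np.uint8)).save(path)
        rows.append({"filename": str(path), "label": im.label.value,
                     "binary_label": im.binary_label.value, "seed": seed})
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path


# ---- feature / score tables ------------------------------------------------

def write_features_csv(features: np.ndarray, filenames: Sequence[str], path: str | Path) -> None:
    """One row per image: f0..f{d-1} columns, then the source filename."""
    features = np.atleast_2d(features)
    df = pd.DataFrame(features, columns=[f"f{i}" for i in range(features.shape[1])])
    df["filename"] = list(filenames)
    df.to_csv(path, index=False)


def read_features_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    if "filename" not in df.columns:
        raise DataError(f"feature table {path} lacks a filename column")
    names = df.pop("filename").astype(str).tolist()
    return df.to_numpy(dtype=np.float64), names


def write_scores_csv(path: str | Path, filenames: Sequence[str],
                     scores: Sequence[float], decisions: Sequence[str]) -> None:
    pd.DataFrame(
        {"filename": list(filenames), "lof_score": list(scores), "decision": list(decisions)}
    ).to_csv(path, index=False)


# ---- run config ------------------------------------------------------------

_RUNCONFIG_KEYS = {
    "seed", "alpha", "batch_size", "learning_rate", "epochs", "train_frac",
    "input_size", "backbone", "k", "threshold", "quantile", "metric",
}


def load_run_config(path: str | Path) -> dict:
    """Flat YAML/JSON config; unknown keys are rejected to catch typos."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise DataError(f"config {path} must be a mapping")
    unknown = set(cfg) - _RUNCONFIG_KEYS
    if unknown:
        raise DataError(f"unknown config keys in {path}: {sorted(unknown)}")
    return cfg


def build_pipeline_config(cfg: dict):
    from .embedding import BackboneSpec, TrainConfig
    from .lof import LOFParams
    from .pipeline import PipelineConfig

    seed = int(cfg.get("seed", 0))
    train_kwargs = {k: cfg[k] for k in
                    ("batch_size", "alpha", "learning_rate", "epochs", "train_frac")
                    if k in cfg}
    if "input_size" in cfg:
        train_kwargs["input_size"] = tuple(cfg["input_size"])
    lof_kwargs = {k: cfg[k] for k in ("k", "threshold", "quantile") if k in cfg}
    backbone = BackboneSpec(kind=cfg.get("backbone", "tiny_cnn"))
    return PipelineConfig(
        train=TrainConfig(seed=seed, **train_kwargs),
        lof=LOFParams(**lof_kwargs),
        backbone=backbone,
        seed=seed,
    )


# ---- run directory ---------------------------------------------------------

def save_run(run_dir: str | Path, fitted, filenames: Sequence[str]) -> None:
    """Persist a fitted pipeline: checkpoint, reference CSV, threshold + config JSON."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    fitted.model.save(run_dir / "model", train_config=fitted.config.train)
    write_features_csv(fitted.reference.points, filenames, run_dir / "reference_features.csv")
    run_meta = {
        "threshold": fitted.threshold,
        "lof": {"k": fitted.config.lof.k, "quantile": fitted.config.lof.quantile,
                "metric": fitted.reference.metric},
        "backbone": fitted.config.backbone.kind,
        "seed": fitted.config.seed,
    }
    (run_dir / "run.json").write_text(json.dumps(run_meta, indent=2))


def load_run(run_dir: str | Path):
    from .embedding import EmbeddingModel
    from .lof import LOFParams, ReferenceFeatureSet
    from .pipeline import FittedPipeline, PipelineConfig

    run_dir = Path(run_dir)
    meta = json.loads((run_dir / "run.json").read_text())
    model = EmbeddingModel.load(run_dir / "model")
    points, _ = read_features_csv(run_dir / "reference_features.csv")
    reference = ReferenceFeatureSet(points, metric=meta["lof"]["metric"])
    config = PipelineConfig(
        lof=LOFParams(k=meta["lof"]["k"], quantile=meta["lof"]["quantile"]),
        seed=meta["seed"],
    )
    return FittedPipeline(model=model, reference=reference,
                          threshold=meta["threshold"], config=config)


def setup_logging(level: str = "INFO", logfile: Optional[str | Path] = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )
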