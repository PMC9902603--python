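"""CSV manifests, run configuration, and image loading.

A manifest is a UTF-8, comma-delimited CSV with header
``path,label,cell_id,genotype``; ``label`` may be empty for prediction-only
manifests.  Validation errors cite 1-based file line numbers (the header is
line 1).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .backbones import BackboneSpec
from .classify import TrainHyperParams
from .preprocess import PreprocessConfig
from .protocol import SplitSpec
from .synthetic import LABELS, LabeledImage

__all__ = [
    "Manifest",
    "ManifestError",
    "read_manifest",
    "write_manifest",
    "load_images",
    "RunConfig",
    "setup_logging",
]

COLUMNS = ("path", "label", "cell_id", "genotype")


class ManifestError(ValueError):
    pass


@dataclass
class Manifest:
    rows: pd.DataFrame  # canonical column order, string dtype

    def __len__(self) -> int:
        return len(self.rows)


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame()
    for col in COLUMNS:
        out[col] = df[col].fillna("").astype(str) if col in df else ""
    return out


def read_manifest(path: str | Path) -> Manifest:
    """Read and validate a manifest CSV; errors cite line numbers."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "path" not in df.columns:
        raise ManifestError(f"{path}: missing required column 'path'")
    df = _canonical(df)
    seen: dict[str, int] = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if not row["path"]:
            raise ManifestError(f"{path}, line {line}: empty path")
        if row["path"] in seen:
            raise ManifestError(
                f"{path}, line {line}: duplicate path {row['path']!r} "
                f"(first seen on line {seen[row['path']]})"
            )
        seen[row["path"]] = line
        if row["label"] and row["label"] not in LABELS:
            raise ManifestError(
                f"{path}, line {line}: invalid label {row['label']!r} "
                f"(expected one of {LABELS} or empty)"
            )
    return Manifest(rows=df)


def write_manifest(manifest: Manifest | pd.DataFrame, path: str | Path) -> None:
    """Write the canonical comma-delimited UTF-8 form (stable byte output)."""
    df = manifest.rows if isinstance(manifest, Manifest) else _canonical(manifest)
    df = _canonical(df)
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def load_images(manifest: Manifest, root: str | Path) -> list[LabeledImage]:
    """Load the images a manifest points to (paths relative to ``root``)."""
    from PIL import Image

    root = Path(root)
    images = []
    for _, row in manifest.rows.iterrows():
        p = root / row["path"]
        if not p.exists():
            raise FileNotFoundError(f"image listed in manifest not found: {p}")
        arr = np.asarray(Image.open(p).convert("RGB"))
        images.append(
            LabeledImage(
                pixels=arr,
                label=row["label"] or "A",  # placeholder for unlabeled rows
                cell_id=row["cell_id"] or "unknown",
                genotype=row["genotype"] or "WT",
                path=row["path"],
            )
        )
        if not row["label"]:
            images[-1].label_missing = True
    return images


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; serializes losslessly to JSON."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    split: SplitSpec = field(default_factory=SplitSpec)
    hyper: TrainHyperParams = field(default_factory=TrainHyperParams)
    base_seed: int = 0
    output_dir: str = "runs"

    def to_json(self) -> str:
        def enc(obj):
            d = asdict(obj)
            return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

        return json.dumps(
            {
                "preprocess": enc(self.preprocess),
                "backbone": enc(self.backbone),
                "split": enc(self.split),
                "hyper": enc(self.hyper),
                "base_seed": self.base_seed,
                "output_dir": self.output_dir,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        pp = raw["preprocess"]
        pp["stage_order"] = tuple(pp["stage_order"])
        pp["white_value"] = tuple(pp["white_value"])
        return cls(
            preprocess=PreprocessConfig(**pp),
            backbone=BackboneSpec(**raw["backbone"]),
            split=SplitSpec(**raw["split"]),
            hyper=TrainHyperParams(**raw["hyper"]),
            base_seed=raw["base_seed"],
            output_dir=raw["output_dir"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


def setup_logging(logfile: str | Path | None = None, level=logging.INFO) -> logging.Logger:
    """Timestamped, level-tagged logging to console and optionally a file."""
    logger = logging.getLogger("chromotype")
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger
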