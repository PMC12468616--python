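"""Readers and writers for the pipeline's interchange formats.

Detections travel as CSV (``x,y,score`` header, comma-separated, UTF-8,
0-based pixel coordinates) or as a JSON list of objects; MIDOG-style
COCO-like annotation files are also accepted, with the mitotic-figure
category resolved from the file's own category table (never hard-coded
ids) and each detection taken as its bounding-box center.  Tissue/tumor
masks arrive as PNG/TIFF images at grid or pixel resolution; pixel
masks are pooled to the grid by a >= 50% coverage rule.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from pydantic import BaseModel, ConfigDict

from .density import Detection, PatchGrid

__all__ = [
    "read_detections_csv",
    "write_detections_csv",
    "read_detections_json",
    "write_detections_json",
    "read_midog_annotations",
    "read_image",
    "read_mask",
    "RunConfig",
    "load_run_config",
    "config_hash",
]

logger = logging.getLogger(__name__)


def read_detections_csv(path: str | Path) -> list[Detection]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"detection CSV {path} lacks columns {sorted(missing)}")
    scores = df["score"] if "score" in df.columns else np.ones(len(df))
    return [Detection(float(x), float(y), float(s)) for x, y, s in zip(df["x"], df["y"], scores)]


def write_detections_csv(dets: list[Detection], path: str | Path) -> None:
    pd.DataFrame(
        {"x": [d.x for d in dets], "y": [d.y for d in dets], "score": [d.score for d in dets]}
    ).to_csv(path, index=False, float_format="%.17g")  # exact float64 round-trip


def read_detections_json(path: str | Path) -> list[Detection]:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise ValueError(f"detection JSON {path} must hold a list")
    return [Detection(float(d["x"]), float(d["y"]), float(d.get("score", 1.0))) for d in data]


def write_detections_json(dets: list[Detection], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([{"x": d.x, "y": d.y, "score": d.score} for d in dets], fh)


def _is_mitotic_category(name: str) -> bool:
    lowered = name.lower()
    if any(neg in lowered for neg in ("non", "not ", "impostor", "imposter", "hard")):
        return False
    return "mitotic" in lowered or "mitosis" in lowered


def read_midog_annotations(
    path: str | Path, bbox_format: str = "corners"
) -> dict[int, list[Detection]]:
    """Parse a MIDOG-style (COCO-like) annotation JSON.

    Only annotations of the mitotic-figure category (resolved from the
    file's category table by name) are returned, keyed by ``image_id``,
    with each detection at the bounding-box center.  ``bbox_format`` is
    ``"corners"`` ([xmin, ymin, xmax, ymax], the MIDOG convention) or
    ``"xywh"`` (COCO [x, y, w, h]).
    """
    if bbox_format not in ("corners", "xywh"):
        raise ValueError("bbox_format must be 'corners' or 'xywh'")
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if "categories" not in data or "annotations" not in data:
        raise ValueError(f"{path} is not a MIDOG-style annotation file")
    mitotic_ids = {c["id"] for c in data["categories"] if _is_mitotic_category(str(c["name"]))}
    if not mitotic_ids:
        raise ValueError(f"{path}: no mitotic-figure category found in the category table")
    out: dict[int, list[Detection]] = {}
    n = 0
    for ann in data["annotations"]:
        if ann.get("category_id") not in mitotic_ids:
            continue
        x0, y0, a, b = ann["bbox"]
        if bbox_format == "corners":
            cx, cy = (x0 + a) / 2.0, (y0 + b) / 2.0
        else:
            cx, cy = x0 + a / 2.0, y0 + b / 2.0
        out.setdefault(int(ann["image_id"]), []).append(
            Detection(cx, cy, float(ann.get("score", 1.0)))
        )
        n += 1
    logger.info("read %d mitotic-figure annotations across %d images from %s", n, len(out), path)
    return out


def read_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF image as a numpy array (RGB or grayscale)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    return np.asarray(Image.open(path))


def read_mask(path: str | Path, grid: PatchGrid) -> np.ndarray:
    """Load a binary tumor/tissue mask and pool it onto the patch grid.

    A mask already at grid resolution passes through; a pixel-resolution
    mask whose dimensions are integer multiples of the grid is pooled by
    block-mean coverage >= 50%.
    """
    arr = read_image(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    mask = arr.astype(float) > (127 if arr.dtype == np.uint8 else 0)
    if mask.shape == grid.shape:
        return mask
    if mask.shape[0] % grid.n_rows == 0 and mask.shape[1] % grid.n_cols == 0:
        br = mask.shape[0] // grid.n_rows
        bc = mask.shape[1] // grid.n_cols
        pooled = mask.reshape(grid.n_rows, br, grid.n_cols, bc).mean(axis=(1, 3))
        return pooled >= 0.5
    raise ValueError(
        f"mask shape {mask.shape} is incompatible with grid {grid.shape}"
    )


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class Ki67Section(_StrictModel):
    patch_size_px: int = 1536
    min_cells: int = 500
    expansion_radius_px: int = 5
    min_radius_px: int = 8
    max_radius_px: int = 24
    radius_step_px: int = 2
    min_center_distance_px: int = 16
    accumulator_threshold: float = 0.3
    min_stain_od: float = 0.1


class DensitySection(_StrictModel):
    patch_size_px: int = 512
    mpp: float = 0.2525
    window_area_mm2: float = 2.0
    score_threshold: float = 0.5
    border_mode: str = "same"
    tumor_coverage_min: float = 0.5


class HistogramSection(_StrictModel):
    mitotic_support_max: int = 48
    ki67_support_max: int = 100


class ClassifierSection(_StrictModel):
    model: str = "mlp"
    hidden_units: int = 64
    learning_rate: float = 1e-3
    max_epochs: int = 500
    class_weighting: str = "inverse_frequency"
    folds: int = 3


class RunConfig(_StrictModel):
    """Schema-validated nested configuration; unknown keys rejected."""

    seed: int = 0
    ki67: Ki67Section = Ki67Section()
    density: DensitySection = DensitySection()
    histogram: HistogramSection = HistogramSection()
    classifier: ClassifierSection = ClassifierSection()


def load_run_config(path: str | Path | None = None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of a config, logged with every artifact."""
    payload = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
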