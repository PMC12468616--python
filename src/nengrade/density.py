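"""Slide-level density maps of proliferative activity.

Mitotic-figure detections (point coordinates from an upstream object
detector) are quantized onto the slide's patch grid and summed with a
sliding window covering 2 mm^2 of tissue — the area over which the WHO
mitotic count is defined.  Ki-67 density maps hold the per-patch Ki-67
index directly (window of one patch).  Missing values (non-tumor or
unqualified patches) are NaN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import convolve2d

from .ki67 import CellCounts

__all__ = [
    "Detection",
    "PatchGrid",
    "DensityMap",
    "window_patches_for_area",
    "quantize_detections",
    "sliding_sum",
    "hotspot",
    "ki67_index_map",
    "render_heatmap",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Detection:
    """One candidate mitotic figure: level-0 pixel coordinates (0-based,
    x = column axis) and a detector confidence in [0, 1]."""

    x: float
    y: float
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("detection coordinates must be >= 0")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be in [0, 1]")


@dataclass(frozen=True)
class PatchGrid:
    """The fixed non-overlapping patch grid of one slide."""

    n_rows: int
    n_cols: int
    patch_size_px: int = 512
    mpp: float = 0.2525
    tumor_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.patch_size_px <= 0 or self.mpp <= 0:
            raise ValueError("patch_size_px and mpp must be positive")
        if self.tumor_mask is not None:
            mask = np.asarray(self.tumor_mask, dtype=bool)
            if mask.shape != (self.n_rows, self.n_cols):
                raise ValueError("tumor_mask shape must match the grid")
            object.__setattr__(self, "tumor_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


@dataclass(frozen=True)
class DensityMap:
    """2D array of local proliferation values over grid positions.

    ``kind`` is ``"mitotic_2mm2"`` (window-summed mitotic counts) or
    ``"ki67_index"`` (per-patch indices in [0, 100]); NaN marks missing.
    """

    values: np.ndarray
    kind: str
    window_patches: int = 1

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be 2D")
        if self.kind not in ("mitotic_2mm2", "ki67_index"):
            raise ValueError(f"unknown density map kind {self.kind!r}")
        object.__setattr__(self, "values", values)


def window_patches_for_area(area_mm2: float, mpp: float, patch_px: int) -> int:
    """Side length, in patches, of a square window covering ``area_mm2``.

    round(sqrt(area)*1000 / (mpp*patch)); 2 mm^2 at 0.2525 um/px and
    512-px patches gives the canonical 11-patch (5632 px) window.
    """
    if area_mm2 <= 0 or mpp <= 0 or patch_px <= 0:
        raise ValueError("area_mm2, mpp and patch_px must all be positive")
    side = math.floor(math.sqrt(area_mm2) * 1000.0 / (mpp * patch_px) + 0.5)
    if side < 1:
        raise ValueError("window smaller than one patch; use a larger area or smaller patches")
    return side


def quantize_detections(
    dets: Iterable[Detection | Sequence[float]],
    grid: PatchGrid,
    score_threshold: float = 0.5,
) -> np.ndarray:
    """Count score-passing detections per grid cell.

    Cell (r, c) covers the half-open pixel box [c*P, (c+1)*P) x
    [r*P, (r+1)*P).  Out-of-bounds detections are dropped with a warning.
    """
    counts = np.zeros(grid.shape, dtype=np.int64)
    p = grid.patch_size_px
    width = grid.n_cols * p
    height = grid.n_rows * p
    n_dropped = 0
    for det in dets:
        if not isinstance(det, Detection):
            det = Detection(*det)
        if det.score < score_threshold:
            continue
        if not (0 <= det.x < width and 0 <= det.y < height):
            n_dropped += 1
            continue
        counts[int(det.y // p), int(det.x // p)] += 1
    if n_dropped:
        logger.warning("dropped %d out-of-bounds detections", n_dropped)
    return counts


def sliding_sum(
    counts: np.ndarray,
    window: int,
    mode: str = "same",
    mask: np.ndarray | None = None,
) -> DensityMap:
    """Sum ``counts`` over every window x window neighborhood (stride 1).

    ``"same"`` zero-pads the borders and keeps the grid shape (window
    must be odd so the window is centered); ``"valid"`` returns only
    fully covered positions.  With a tumor mask, non-tumor cells
    contribute zero and receive NaN in the output.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be 2D")
    if window < 1:
        raise ValueError("window must be >= 1")
    if mode not in ("same", "valid"):
        raise ValueError("mode must be 'same' or 'valid'")
    if mode == "same" and window % 2 == 0:
        raise ValueError("'same' mode requires an odd window for centering")
    if mode == "valid" and (window > counts.shape[0] or window > counts.shape[1]):
        raise ValueError("window larger than the grid in 'valid' mode")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != counts.shape:
            raise ValueError("mask shape must match counts")
        counts = np.where(mask, counts, 0.0)
    kernel = np.ones((window, window))
    values = convolve2d(counts, kernel, mode=mode)
    if mask is not None:
        if mode == "same":
            values[~mask] = np.nan
        else:
            m = window // 2
            inner = mask[m : mask.shape[0] - m, m : mask.shape[1] - m]
            values[~inner] = np.nan
    return DensityMap(values=values, kind="mitotic_2mm2", window_patches=window)


def hotspot(dmap: DensityMap) -> tuple[float, int, int]:
    """Maximum density value and its first (row-major) position.

    Ties break toward the smallest row, then the smallest column.
    """
    values = dmap.values
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("density map has no non-missing values")
    vmax = np.nanmax(values)
    row, col = np.argwhere(values == vmax)[0]
    return float(vmax), int(row), int(col)


def ki67_index_map(
    per_patch: Iterable[tuple[int, int, CellCounts]],
    grid: PatchGrid,
) -> DensityMap:
    """Place qualifying per-patch Ki-67 indices on the grid (NaN elsewhere)."""
    values = np.full(grid.shape, np.nan)
    seen: set[tuple[int, int]] = set()
    for row, col, cells in per_patch:
        if not (0 <= row < grid.n_rows and 0 <= col < grid.n_cols):
            raise ValueError(f"grid coordinate ({row}, {col}) outside grid {grid.shape}")
        if (row, col) in seen:
            raise ValueError(f"duplicate grid coordinate ({row}, {col})")
        seen.add((row, col))
        if cells.qualifies:
            values[row, col] = cells.index_pct
    return DensityMap(values=values, kind="ki67_index", window_patches=1)


def render_heatmap(dmap: DensityMap, path: str, cmap: str = "inferno") -> None:
    """Write a PNG heatmap of a density map for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(dmap.values, cmap=cmap, interpolation="nearest")
    ax.set_title(dmap.kind)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
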