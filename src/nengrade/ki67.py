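"""Classical Ki-67 proliferation-index quantification for IHC patches.

The Ki-67 index of a patch is the fraction of tumor nuclei that stain
positive for the Ki-67 antigen (brown DAB chromogen) among all nuclei
(blue hematoxylin counterstain).  The pipeline here is fully classical:

1. optical-density color deconvolution into hematoxylin (H) and DAB (D)
   concentration planes,
2. Otsu thresholding of each plane into a binary nucleus mask,
3. morphological expansion of the masks,
4. circular Hough transform to count nucleus-like circles per channel,
5. index = 100 * |D circles| / |H circles|.

Patches with fewer than ``min_cells`` detected nuclei do not qualify for
slide-level aggregation, mirroring clinical practice of assessing the
index over at least 500 cells.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion
from skimage.filters import threshold_otsu
from skimage.morphology import isotropic_dilation
from skimage.transform import hough_circle, hough_circle_peaks

__all__ = [
    "HoughParams",
    "Ki67Config",
    "StainChannels",
    "CellCounts",
    "HDAB_STAIN_MATRIX",
    "separate_stains",
    "binarize_channel",
    "expand_mask",
    "detect_circles",
    "ki67_patch_index",
]


def _unit_rows(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    norms = np.linalg.norm(matrix, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("stain matrix has a zero row")
    return matrix / norms


#: Ruifrok–Johnston optical-density vectors for hematoxylin, eosin and DAB
#: (rows normalized to unit length).  Eosin is carried only to make the
#: deconvolution matrix invertible; the pipeline uses H and D.
HDAB_STAIN_MATRIX: np.ndarray = _unit_rows(
    np.array(
        [
            [0.650, 0.704, 0.286],  # hematoxylin
            [0.072, 0.990, 0.105],  # eosin
            [0.268, 0.570, 0.776],  # DAB
        ]
    )
)


@dataclass(frozen=True)
class HoughParams:
    """Circular Hough search parameters, in pixels at level 0.

    The radius range should bracket the expected nucleus radius *after*
    mask expansion (nuclei are ~5–10 µm across; at 0.2525 µm/px and a
    5 px dilation that is roughly 8–24 px).
    """

    min_radius_px: int = 8
    max_radius_px: int = 24
    radius_step_px: int = 2
    min_center_distance_px: int = 16
    accumulator_threshold: float = 0.3

    def __post_init__(self) -> None:
        if not self.min_radius_px < self.max_radius_px:
            raise ValueError("min_radius_px must be < max_radius_px")
        if self.radius_step_px < 1:
            raise ValueError("radius_step_px must be >= 1")
        if self.min_center_distance_px < 1:
            raise ValueError("min_center_distance_px must be >= 1")

    @property
    def radii(self) -> np.ndarray:
        return np.arange(self.min_radius_px, self.max_radius_px + 1, self.radius_step_px)


@dataclass(frozen=True)
class Ki67Config:
    """Configuration of the patch-level Ki-67 algorithm.

    ``min_stain_od`` is a physical noise floor on the per-stain optical
    density: Otsu foreground additionally requires a concentration above
    it, so a channel whose stain is simply absent (e.g. the DAB plane of
    a wholly negative patch) yields an empty mask instead of thresholded
    sensor noise.
    """

    patch_size_px: int = 1536
    min_cells: int = 500
    expansion_radius_px: int = 5
    hough: HoughParams = field(default_factory=HoughParams)
    stain_matrix: np.ndarray = field(default_factory=lambda: HDAB_STAIN_MATRIX.copy())
    min_stain_od: float = 0.1

    def __post_init__(self) -> None:
        if self.patch_size_px <= 0:
            raise ValueError("patch_size_px must be positive")
        if self.min_cells < 0:
            raise ValueError("min_cells must be >= 0")
        if self.expansion_radius_px < 0:
            raise ValueError("expansion_radius_px must be >= 0")
        matrix = np.asarray(self.stain_matrix, dtype=float)
        if matrix.shape != (3, 3):
            raise ValueError("stain_matrix must be 3x3")
        if not np.allclose(np.linalg.norm(matrix, axis=1), 1.0, atol=1e-6):
            raise ValueError("stain_matrix rows must be unit vectors")
        object.__setattr__(self, "stain_matrix", matrix)

    def replace(self, **kwargs) -> "Ki67Config":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class StainChannels:
    """Hematoxylin and DAB concentration planes of one RGB patch."""

    hematoxylin: np.ndarray
    dab: np.ndarray


@dataclass(frozen=True)
class CellCounts:
    """Per-patch circle counts and the resulting Ki-67 index.

    ``index_pct`` is NaN when no nuclei were detected in the H channel;
    such patches never qualify and must not be aggregated.
    """

    n_total: int
    n_positive: int
    index_pct: float
    qualifies: bool


def separate_stains(patch: np.ndarray, matrix: np.ndarray | None = None) -> StainChannels:
    """Color-deconvolve an 8-bit RGB patch into H and DAB planes.

    Optical density ``OD = -log10(I/255)`` is projected onto the inverse
    of the stain matrix, giving per-stain concentrations; negatives are
    clipped to zero.  White background maps to ~zero in every channel.
    """
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[-1] != 3 or patch.size == 0:
        raise ValueError("patch must be a non-empty RGB image (H, W, 3)")
    matrix = HDAB_STAIN_MATRIX if matrix is None else _unit_rows(matrix)
    rgb = np.clip(patch.astype(float), 1.0, 255.0)
    od = -np.log10(rgb / 255.0)
    conc = od @ np.linalg.inv(matrix)
    conc = np.clip(conc, 0.0, None)
    return StainChannels(hematoxylin=conc[..., 0], dab=conc[..., 2])


def binarize_channel(channel: np.ndarray, min_signal: float = 0.0) -> np.ndarray:
    """Otsu-threshold a concentration plane into a nucleus mask.

    Foreground is the high-concentration side.  Constant images yield an
    all-background mask; ``min_signal`` raises the threshold floor.
    """
    channel = np.asarray(channel, dtype=float)
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite values")
    if channel.size == 0 or np.ptp(channel) == 0:
        return np.zeros(channel.shape, dtype=bool)
    thresh = max(float(threshold_otsu(channel)), float(min_signal))
    return channel > thresh


def expand_mask(mask: np.ndarray, radius: int) -> np.ndarray:
    """Dilate a binary mask by a disk of the given radius (0 = identity)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    return isotropic_dilation(mask, radius)


def detect_circles(mask: np.ndarray, params: HoughParams | None = None) -> np.ndarray:
    """Detect circles in a binary mask with a circular Hough transform.

    The transform is applied to the mask boundary.  Returns an
    ``(n, 3)`` float array of ``(center_x, center_y, radius)`` rows;
    accepted centers are at least ``min_center_distance_px`` apart.
    """
    params = params or HoughParams()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.empty((0, 3), dtype=float)
    edges = mask & ~binary_erosion(mask)
    radii = params.radii
    spaces = hough_circle(edges, radii)
    _, cx, cy, found_r = hough_circle_peaks(
        spaces,
        radii,
        min_xdistance=params.min_center_distance_px,
        min_ydistance=params.min_center_distance_px,
        threshold=params.accumulator_threshold,
    )
    return np.column_stack([cx, cy, found_r]).astype(float)


def _channel_circles(channel: np.ndarray, config: Ki67Config) -> np.ndarray:
    mask = binarize_channel(channel, min_signal=config.min_stain_od)
    mask = expand_mask(mask, config.expansion_radius_px)
    return detect_circles(mask, config.hough)


def ki67_patch_index(patch: np.ndarray, config: Ki67Config | None = None) -> CellCounts:
    """Compute the Ki-67 index of one IHC patch.

    Runs the full chain independently on the H and D planes and divides
    the D-circle count (positive cells) by the H-circle count (all
    cells).  A patch qualifies only with >= ``min_cells`` H circles.
    """
    config = config or Ki67Config()
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[0] != config.patch_size_px or patch.shape[1] != config.patch_size_px:
        raise ValueError(
            f"patch must be {config.patch_size_px}x{config.patch_size_px} RGB, got {patch.shape}"
        )
    channels = separate_stains(patch, config.stain_matrix)
    n_total = len(_channel_circles(channels.hematoxylin, config))
    n_positive = len(_channel_circles(channels.dab, config))
    if n_total > 0:
        index_pct = 100.0 * n_positive / n_total
        qualifies = n_total >= config.min_cells
    else:
        index_pct = float("nan")
        qualifies = False
    return CellCounts(n_total=n_total, n_positive=n_positive, index_pct=index_pct, qualifies=qualifies)
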