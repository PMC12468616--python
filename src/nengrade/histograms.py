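"""Slide-level histogram representations of density maps.

A slide is summarized by the normalized frequency histogram of its
density-map values: 49 unit-width bins (0..48, values clipped at 48,
well above the G3 threshold of 20) for mitotic activity, and 101 bins
(0..100) for the Ki-67 index.  These vectors — optionally concatenated
across stains — are the features fed to the grade classifiers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .density import DensityMap

__all__ = [
    "HistogramConfig",
    "SlideHistogram",
    "FeatureVector",
    "mitotic_histogram_config",
    "ki67_histogram_config",
    "build_histogram",
    "pool_map_values",
    "concat_features",
    "majority_vote",
]


@dataclass(frozen=True)
class HistogramConfig:
    kind: str  # "mitotic" | "ki67"
    support_min: int
    support_max: int
    clip: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("mitotic", "ki67"):
            raise ValueError(f"unknown histogram kind {self.kind!r}")
        if self.support_min >= self.support_max:
            raise ValueError("support_min must be < support_max")

    @property
    def n_bins(self) -> int:
        return self.support_max - self.support_min + 1


def mitotic_histogram_config() -> HistogramConfig:
    """49 bins over clipped mitotic window counts 0..48."""
    return HistogramConfig(kind="mitotic", support_min=0, support_max=48)


def ki67_histogram_config() -> HistogramConfig:
    """101 bins over integer Ki-67 indices 0..100."""
    return HistogramConfig(kind="ki67", support_min=0, support_max=100)


@dataclass(frozen=True)
class SlideHistogram:
    frequencies: np.ndarray
    kind: str
    n_values: int

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequencies, dtype=float)
        if freq.ndim != 1 or np.any(freq < 0):
            raise ValueError("frequencies must be a non-negative vector")
        object.__setattr__(self, "frequencies", freq)


@dataclass(frozen=True)
class FeatureVector:
    """Concatenated [mitotic 49 | ki67 101] slide feature (length 150)."""

    values: np.ndarray
    provenance: tuple[str, ...] = ()


def _map_values(dmap: DensityMap | np.ndarray) -> np.ndarray:
    values = dmap.values if isinstance(dmap, DensityMap) else np.asarray(dmap, dtype=float)
    return values[np.isfinite(values)].ravel()


def pool_map_values(maps: Iterable[DensityMap | np.ndarray]) -> np.ndarray:
    """Pool the non-missing values of several same-stain maps (e.g. all
    slides of one patient) into one array, ready for ``build_histogram``."""
    pooled = [_map_values(m) for m in maps]
    return np.concatenate(pooled) if pooled else np.empty(0)


def build_histogram(dmap: DensityMap | np.ndarray, config: HistogramConfig) -> SlideHistogram:
    """Histogram the non-missing map values into unit-width integer bins.

    Values are rounded half-up, clipped into the support, counted and
    normalized to sum 1.  An all-missing map is unrepresentable.
    """
    values = _map_values(dmap)
    if values.size == 0:
        raise ValueError("cannot build a histogram from an empty/all-missing map")
    ints = np.floor(values + 0.5).astype(int)
    if config.clip:
        ints = np.clip(ints, config.support_min, config.support_max)
    elif ints.min() < config.support_min or ints.max() > config.support_max:
        raise ValueError("values outside histogram support with clip=False")
    counts = np.bincount(ints - config.support_min, minlength=config.n_bins)
    return SlideHistogram(
        frequencies=counts / counts.sum(), kind=config.kind, n_values=int(values.size)
    )


def concat_features(mitotic: SlideHistogram, ki67: SlideHistogram, provenance: Sequence[str] = ()) -> FeatureVector:
    """Order-stable [mitotic | ki67] concatenation (length 49 + 101)."""
    if mitotic is None or ki67 is None:
        raise ValueError("both stains are required; fall back to a single-stain model")
    if mitotic.kind != "mitotic" or ki67.kind != "ki67":
        raise ValueError("histogram kinds must be (mitotic, ki67)")
    values = np.concatenate([mitotic.frequencies, ki67.frequencies])
    return FeatureVector(values=values, provenance=tuple(provenance))


def majority_vote(patch_grades: Sequence[int]) -> int:
    """Modal grade of a list of patch predictions; ties break toward the
    higher grade (highest grade takes precedence)."""
    if len(patch_grades) == 0:
        raise ValueError("cannot vote on an empty list")
    counts = Counter(int(g) for g in patch_grades)
    best = max(counts.values())
    return max(g for g, c in counts.items() if c == best)
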