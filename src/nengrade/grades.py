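"""WHO grade-rule primitives (2019 scheme, grades 1–3).

Boundary semantics: the G2 ranges "2–20" (mitoses per 2 mm^2) and
"3–20" (Ki-67 %) are inclusive at both ends, so counts of exactly 2 or
20 and indices of exactly 3% or 20% are G2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "GradeThresholds",
    "who_grade_mitotic",
    "who_grade_ki67",
    "combined_grade",
    "patient_grade",
]


@dataclass(frozen=True)
class GradeThresholds:
    mitotic_g1_max_exclusive: float = 2.0
    mitotic_g2_max_inclusive: float = 20.0
    ki67_g1_max_exclusive: float = 3.0
    ki67_g2_max_inclusive: float = 20.0

    def __post_init__(self) -> None:
        if not self.mitotic_g1_max_exclusive < self.mitotic_g2_max_inclusive:
            raise ValueError("mitotic G1 bound must be < G2 bound")
        if not self.ki67_g1_max_exclusive < self.ki67_g2_max_inclusive:
            raise ValueError("ki67 G1 bound must be < G2 bound")


def who_grade_mitotic(count: float, thresholds: GradeThresholds | None = None) -> int:
    """Grade from the mitotic count per 2 mm^2: <2 G1, 2–20 G2, >20 G3."""
    thresholds = thresholds or GradeThresholds()
    if count < 0:
        raise ValueError("mitotic count must be >= 0")
    if count < thresholds.mitotic_g1_max_exclusive:
        return 1
    if count <= thresholds.mitotic_g2_max_inclusive:
        return 2
    return 3


def who_grade_ki67(index_pct: float, thresholds: GradeThresholds | None = None) -> int:
    """Grade from the Ki-67 index in percent: <3 G1, 3–20 G2, >20 G3."""
    thresholds = thresholds or GradeThresholds()
    if not 0 <= index_pct <= 100:
        raise ValueError("Ki-67 index must be in [0, 100] percent")
    if index_pct < thresholds.ki67_g1_max_exclusive:
        return 1
    if index_pct <= thresholds.ki67_g2_max_inclusive:
        return 2
    return 3


def _max_grade(grades: Sequence[int], what: str) -> int:
    grades = [int(g) for g in grades]
    if not grades:
        raise ValueError(f"cannot combine an empty list of {what}")
    if any(g not in (1, 2, 3) for g in grades):
        raise ValueError("grades must be in {1, 2, 3}")
    return max(grades)


def combined_grade(grades: Sequence[int]) -> int:
    """Highest grade takes precedence when measures disagree."""
    return _max_grade(grades, "grades")


def patient_grade(slide_grades: Sequence[int]) -> int:
    """A patient with several slides receives the highest slide grade."""
    return _max_grade(slide_grades, "slide grades")
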