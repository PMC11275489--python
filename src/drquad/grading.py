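"""Rule-based diabetic-retinopathy severity grading (MESSIDOR scale).

The MESSIDOR scale grades a fundus photograph from whole-image lesion
counts: the number of microaneurysms (muA), the number of hemorrhages (H)
and a binary neovascularization flag (NV).

    level 0, NoDR:     muA = 0           and H = 0
    level 1, Mild:     0 < muA <= 5      and H = 0
    level 2, Moderate: (5 < muA < 15 or 0 < H < 5) and NV = 0
    level 3, Severe:   muA >= 15 or H >= 5 or NV = 1

The clauses overlap at their boundaries, so they are evaluated most-severe
first; this makes the classifier total and monotone (raising either count,
or setting NV, never lowers the level).  Macular edema is outside this scale
as used here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .geometry import EtdrsGrid, FundusFrame, Region, assign_regions
from .lesions import LesionMark, LesionType, coerce_lesion_type

GRADE_LABELS = {0: "NoDR", 1: "Mild", 2: "Moderate", 3: "Severe"}
LABEL_LEVELS = {v: k for k, v in GRADE_LABELS.items()}


@dataclass(frozen=True)
class GradeRuleSet:
    """Thresholds of the grading rules.

    ``mild_ma_max``: largest microaneurysm count still mild (muA <= 5).
    ``moderate_ma_max``: muA at or above this is severe (muA >= 15).
    ``moderate_hem_max``: H at or above this is severe (H >= 5).
    """

    mild_ma_max: int = 5
    moderate_ma_max: int = 15
    moderate_hem_max: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.mild_ma_max < self.moderate_ma_max:
            raise ValueError(
                f"need 0 < mild_ma_max < moderate_ma_max, got {self.mild_ma_max}, {self.moderate_ma_max}"
            )
        if self.moderate_hem_max <= 0:
            raise ValueError("moderate_hem_max must be positive")


DEFAULT_RULES = GradeRuleSet()


@dataclass(frozen=True)
class DRGrade:
    """A severity grade together with the counts that produced it."""

    level: int
    label: str
    mu_a: int
    h: int
    nv: int

    def __post_init__(self) -> None:
        if self.level not in GRADE_LABELS:
            raise ValueError(f"level must be 0..3, got {self.level}")


def grade_from_counts(
    mu_a: int, h: int, nv: int = 0, rules: GradeRuleSet = DEFAULT_RULES
) -> DRGrade:
    """Grade from whole-image lesion counts; total over non-negative inputs."""
    mu_a, h, nv = int(mu_a), int(h), int(nv)
    if mu_a < 0 or h < 0:
        raise ValueError(f"lesion counts must be non-negative, got muA={mu_a}, H={h}")
    if nv not in (0, 1):
        raise ValueError(f"nv must be 0 or 1, got {nv}")
    if mu_a >= rules.moderate_ma_max or h >= rules.moderate_hem_max or nv == 1:
        level = 3
    elif (rules.mild_ma_max < mu_a < rules.moderate_ma_max) or (0 < h < rules.moderate_hem_max):
        level = 2
    elif 0 < mu_a <= rules.mild_ma_max and h == 0:
        level = 1
    else:
        level = 0
    return DRGrade(level=level, label=GRADE_LABELS[level], mu_a=mu_a, h=h, nv=nv)


def grade_image(
    marks: Iterable[LesionMark],
    nv: int = 0,
    rules: GradeRuleSet = DEFAULT_RULES,
    frame: FundusFrame | None = None,
    grid: EtdrsGrid | None = None,
) -> DRGrade:
    """Grade one image from its lesion marks.

    Counts are whole-image totals.  When a ``frame`` is supplied, marks
    falling outside the 45 degree field are excluded first (they are not
    retinal findings of this photograph); central-ring marks, should any
    exist, still count.
    """
    marks = list(marks)
    if frame is not None and marks:
        regions = assign_regions(
            [m.x_px for m in marks], [m.y_px for m in marks], frame, grid
        )
        marks = [m for m, r in zip(marks, regions) if r is not Region.OUTSIDE_FIELD]
    mu_a = sum(1 for m in marks if coerce_lesion_type(m.lesion_type) is LesionType.MA)
    h = sum(1 for m in marks if coerce_lesion_type(m.lesion_type) is LesionType.HEM)
    return grade_from_counts(mu_a, h, nv, rules)
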