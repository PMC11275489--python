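"""Modified ETDRS grid: quadrant geometry, laterality and region assignment.

The standard ETDRS macular grid (central ring plus two concentric rings cut
by diagonals) is here reduced to its central 1500 um ring and its four
diagonal quadrants, with the quadrants extended to the periphery of the 45
degree field of view.  Every retinal point therefore receives exactly one of
six labels: ``central_ring``, the four quadrants, or ``outside_field``.

Conventions
-----------
* Pixel coordinates are 0-based, x rightward, y downward (image convention);
  "superior" is smaller y.
* Quadrant boundaries are the diagonal rays at 45, 135, 225 and 315 degrees
  from the horizontal through the fovea (the classic ETDRS "X" division).
  A point exactly on a boundary ray belongs to the counter-clockwise wedge
  (measuring angles counter-clockwise with "up" positive), so the wedges are
  the half-open intervals [45, 135), [135, 225), [225, 315), [315, 45).
* The photograph is assumed macula-centered and non-mirrored, so the optic
  disc lies nasal to the fovea: a right eye shows the disc on the image
  right.  The horizontal wedges are labeled temporal/nasal accordingly
  (temporal = side opposite the disc).
* The 45 degree field is modeled as the circle inscribed in the image
  rectangle, centered at the image center; points beyond it are
  ``outside_field`` and never enter quadrant totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .lesions import LesionMark, LesionType, coerce_lesion_type

#: Conversion used to give the 45 degree field a physical scale: one degree of
#: visual angle covers roughly 288 um on the retina of an emmetropic adult eye.
DEFAULT_RETINA_UM_PER_DEG = 288.0

#: Diameter of the foveal central ring of the ETDRS grid, in micrometres.
CENTRAL_RING_DIAMETER_UM = 1500.0


class Laterality(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    UNKNOWN = "unknown"


class Region(str, Enum):
    """Exhaustive, mutually exclusive region labels of the modified grid."""

    SUPERIOR = "superior"
    TEMPORAL = "temporal"
    NASAL = "nasal"
    INFERIOR = "inferior"
    CENTRAL_RING = "central_ring"
    OUTSIDE_FIELD = "outside_field"


#: The four quadrants, in the fixed reporting order used throughout.
QUADRANTS: tuple[Region, ...] = (
    Region.SUPERIOR,
    Region.TEMPORAL,
    Region.NASAL,
    Region.INFERIOR,
)


class DegenerateLandmarkError(ValueError):
    """Fovea and disc centers do not determine laterality (same x)."""


def um_per_px_from_fov(
    width_px: float,
    fov_deg: float = 45.0,
    retina_um_per_deg: float = DEFAULT_RETINA_UM_PER_DEG,
) -> float:
    """Micrometres of retina per pixel for a fundus photo spanning ``fov_deg``.

    The horizontal image width is assumed to span the stated field of view,
    so the scale is ``fov_deg * retina_um_per_deg / width_px``.

    >>> um_per_px_from_fov(1440, 45.0)
    9.0
    """
    if width_px <= 0 or fov_deg <= 0 or retina_um_per_deg <= 0:
        raise ValueError(
            "width_px, fov_deg and retina_um_per_deg must all be positive; got "
            f"{width_px}, {fov_deg}, {retina_um_per_deg}"
        )
    return fov_deg * retina_um_per_deg / width_px


@dataclass
class FundusFrame:
    """Geometry and landmarks of one macula-centered fundus photograph."""

    image_id: str
    width_px: int
    height_px: int
    fovea_x: float
    fovea_y: float
    disc_x: float
    disc_y: float
    fov_deg: float = 45.0
    um_per_px: float | None = None
    laterality: Laterality = Laterality.UNKNOWN
    retina_um_per_deg: float = DEFAULT_RETINA_UM_PER_DEG

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError(f"image dimensions must be positive: {self.width_px}x{self.height_px}")
        for name, x, y in (("fovea", self.fovea_x, self.fovea_y), ("disc", self.disc_x, self.disc_y)):
            if not (0 <= x < self.width_px and 0 <= y < self.height_px):
                raise ValueError(f"{name} center ({x}, {y}) lies outside the {self.width_px}x{self.height_px} image")
        if self.um_per_px is None:
            self.um_per_px = um_per_px_from_fov(self.width_px, self.fov_deg, self.retina_um_per_deg)
        if self.um_per_px <= 0:
            raise ValueError(f"um_per_px must be positive, got {self.um_per_px}")
        self.laterality = Laterality(self.laterality)
        if self.laterality is Laterality.UNKNOWN:
            self.laterality = infer_laterality(self)

    def mirrored_x(self) -> "FundusFrame":
        """The same photograph flipped left-right (landmarks included)."""
        return replace(
            self,
            fovea_x=self.width_px - 1 - self.fovea_x,
            disc_x=self.width_px - 1 - self.disc_x,
            laterality=Laterality.UNKNOWN,
        )


def infer_laterality(frame: FundusFrame) -> Laterality:
    """Decide left vs right eye from the disc position relative to the fovea.

    On a non-mirrored macula-centered photograph the optic disc is nasal to
    the fovea, so a disc on the image right means a right eye.  Raises
    :class:`DegenerateLandmarkError` when ``disc_x == fovea_x``.
    """
    if frame.disc_x == frame.fovea_x:
        raise DegenerateLandmarkError(
            f"disc and fovea share x={frame.disc_x}: laterality is undecidable"
        )
    return Laterality.RIGHT if frame.disc_x > frame.fovea_x else Laterality.LEFT


@dataclass(frozen=True)
class EtdrsGrid:
    """The modified ETDRS grid attached to one frame.

    ``center_*`` is the fovea (grid center); the field circle is centered at
    ``field_center_*`` with radius ``field_radius_px``.
    """

    center_x: float
    center_y: float
    um_per_px: float
    central_ring_radius_um: float = CENTRAL_RING_DIAMETER_UM / 2
    field_center_x: float = 0.0
    field_center_y: float = 0.0
    field_radius_px: float = 0.0

    def __post_init__(self) -> None:
        if self.central_ring_radius_um <= 0 or self.um_per_px <= 0:
            raise ValueError("central_ring_radius_um and um_per_px must be positive")
        if self.field_radius_px <= 0:
            raise ValueError("field_radius_px must be positive")

    @classmethod
    def for_frame(
        cls,
        frame: FundusFrame,
        central_ring_radius_um: float = CENTRAL_RING_DIAMETER_UM / 2,
        field_radius_px: float | None = None,
    ) -> "EtdrsGrid":
        """Grid centered on the frame's fovea, field = inscribed image circle."""
        if field_radius_px is None:
            field_radius_px = min(frame.width_px, frame.height_px) / 2
        return cls(
            center_x=frame.fovea_x,
            center_y=frame.fovea_y,
            um_per_px=frame.um_per_px,
            central_ring_radius_um=central_ring_radius_um,
            field_center_x=(frame.width_px - 1) / 2,
            field_center_y=(frame.height_px - 1) / 2,
            field_radius_px=field_radius_px,
        )

    @property
    def central_ring_radius_px(self) -> float:
        return self.central_ring_radius_um / self.um_per_px


def _horizontal_wedge_labels(laterality: Laterality) -> tuple[Region, Region]:
    """(image-left wedge, image-right wedge) labels for the given eye."""
    if laterality is Laterality.RIGHT:
        return Region.TEMPORAL, Region.NASAL
    if laterality is Laterality.LEFT:
        return Region.NASAL, Region.TEMPORAL
    raise ValueError("cannot label temporal/nasal wedges with unknown laterality")


def assign_region(
    x_px: float,
    y_px: float,
    frame: FundusFrame,
    grid: EtdrsGrid | None = None,
) -> Region:
    """Label one retinal point with its modified-ETDRS region.

    Total over the plane: every point gets exactly one label.  Precedence is
    central ring (distance from fovea < ring radius), then field membership,
    then the diagonal wedge containing the point's angle from the fovea.
    """
    if grid is None:
        grid = EtdrsGrid.for_frame(frame)
    dx = x_px - grid.center_x
    dy_up = grid.center_y - y_px  # positive when the point is superior
    if math.hypot(dx, dy_up) < grid.central_ring_radius_px:
        return Region.CENTRAL_RING
    if math.hypot(x_px - grid.field_center_x, y_px - grid.field_center_y) > grid.field_radius_px:
        return Region.OUTSIDE_FIELD
    angle = math.degrees(math.atan2(dy_up, dx)) % 360.0
    wedge = int((angle - 45.0) % 360.0 // 90.0)  # 0=sup, 1=img-left, 2=inf, 3=img-right
    left_label, right_label = _horizontal_wedge_labels(frame.laterality)
    return (Region.SUPERIOR, left_label, Region.INFERIOR, right_label)[wedge]


def assign_regions(
    xs: Sequence[float] | np.ndarray,
    ys: Sequence[float] | np.ndarray,
    frame: FundusFrame,
    grid: EtdrsGrid | None = None,
) -> list[Region]:
    """Vectorized :func:`assign_region` over parallel coordinate arrays."""
    if grid is None:
        grid = EtdrsGrid.for_frame(frame)
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    dx = xs - grid.center_x
    dy_up = grid.center_y - ys
    r_fovea = np.hypot(dx, dy_up)
    r_field = np.hypot(xs - grid.field_center_x, ys - grid.field_center_y)
    angle = np.degrees(np.arctan2(dy_up, dx)) % 360.0
    wedge = ((angle - 45.0) % 360.0 // 90.0).astype(int)
    left_label, right_label = _horizontal_wedge_labels(frame.laterality)
    wedge_labels = np.array(
        [Region.SUPERIOR, left_label, Region.INFERIOR, right_label], dtype=object
    )
    out = wedge_labels[wedge]
    out[r_field > grid.field_radius_px] = Region.OUTSIDE_FIELD
    out[r_fovea < grid.central_ring_radius_px] = Region.CENTRAL_RING
    return list(out)


@dataclass
class QuadrantCounts:
    """Per-region, per-type lesion counts for one image."""

    image_id: str
    counts: dict[tuple[Region, LesionType], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {(r, t): 0 for r in Region for t in LesionType}
        full.update({(Region(r), LesionType(t)): int(v) for (r, t), v in self.counts.items()})
        self.counts = full

    def n(self, region: Region, lesion_type: LesionType | str) -> int:
        return self.counts[(Region(region), coerce_lesion_type(lesion_type))]

    def total(self, lesion_type: LesionType | str | None = None) -> int:
        if lesion_type is None:
            return sum(self.counts.values())
        t = coerce_lesion_type(lesion_type)
        return sum(v for (_, lt), v in self.counts.items() if lt is t)

    def in_field_total(self, lesion_type: LesionType | str) -> int:
        """Count inside the 45 degree field (quadrants + central ring)."""
        t = coerce_lesion_type(lesion_type)
        return sum(
            v
            for (r, lt), v in self.counts.items()
            if lt is t and r is not Region.OUTSIDE_FIELD
        )

    def to_rows(self) -> list[dict]:
        """Long-format rows (image_id, region, n_MA, n_HEM)."""
        return [
            {
                "image_id": self.image_id,
                "region": r.value,
                "n_MA": self.counts[(r, LesionType.MA)],
                "n_HEM": self.counts[(r, LesionType.HEM)],
            }
            for r in Region
        ]


def count_by_region(
    marks: Iterable[LesionMark],
    frame: FundusFrame,
    grid: EtdrsGrid | None = None,
) -> QuadrantCounts:
    """Count MA and HEM marks per region of the modified grid.

    The six labels partition the plane, so the per-region counts always sum
    to the number of marks.
    """
    if grid is None:
        grid = EtdrsGrid.for_frame(frame)
    out = QuadrantCounts(image_id=frame.image_id)
    marks = list(marks)
    if not marks:
        return out
    regions = assign_regions(
        [m.x_px for m in marks], [m.y_px for m in marks], frame, grid
    )
    for mark, region in zip(marks, regions):
        out.counts[(region, coerce_lesion_type(mark.lesion_type))] += 1
    return out
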