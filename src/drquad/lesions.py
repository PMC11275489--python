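"""Lesion records shared by the detector, the simulator and the grid counter."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class LesionType(str, Enum):
    """Red-lesion classes counted by the pipeline.

    MA: microaneurysm — small saccular capillary outpouching, the earliest
    visible diabetic-retinopathy lesion; appears as a small red dot of
    roughly 30-125 um.
    HEM: retinal hemorrhage — blood leaked from a ruptured capillary;
    larger and darker red than a microaneurysm.
    """

    MA = "MA"
    HEM = "HEM"


def coerce_lesion_type(value: "LesionType | str") -> LesionType:
    """Normalize a lesion-type token, raising ``ValueError`` for unknown ones."""
    if isinstance(value, LesionType):
        return value
    try:
        return LesionType(str(value).strip().upper())
    except ValueError:
        raise ValueError(f"unknown lesion type: {value!r} (expected MA or HEM)") from None


@dataclass(frozen=True)
class LesionMark:
    """One detected or annotated lesion.

    Parameters
    ----------
    lesion_type:
        ``LesionType.MA`` or ``LesionType.HEM``.
    x_px, y_px:
        Centroid in 0-based image pixel coordinates (x rightward, y downward).
    diameter_um:
        Equivalent-circle diameter in micrometres of retina; must be positive.
    mean_intensity:
        Optional normalized darkness score in [0, 1] (contrast of the blob
        against the local background); ``None`` for annotation-only marks.
    """

    lesion_type: LesionType
    x_px: float
    y_px: float
    diameter_um: float
    mean_intensity: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lesion_type", coerce_lesion_type(self.lesion_type))
        if not self.diameter_um > 0:
            raise ValueError(f"diameter_um must be positive, got {self.diameter_um}")
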