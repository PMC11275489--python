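"""Synthetic lesion-map cohorts calibrated to published quadrant statistics.

The generator emulates the structure of two screening cohorts of
macula-centered 45-degree fundus photographs: per-grade stratum sizes, and
per-quadrant microaneurysm/hemorrhage count distributions specified by their
(mean, SD).  Counts are drawn from a negative binomial with moment-matched
mean and variance when the cell is overdispersed (SD^2 > mean), which every
severe-DR cell is, and from a Poisson otherwise; the Poisson branch matches
the mean but cannot reproduce an underdispersed SD.  Lesions are then placed
uniformly at random inside their target quadrant wedge — outside the 750 um
foveal central ring, inside the 45-degree field, clear of the optic disc —
so that grid counting recovers the drawn counts exactly (geometric closure).

Two consistency modes exist because table-calibrated mild/moderate strata
need not satisfy the grading rules that define them (e.g. a "mild" image may
carry hemorrhages):

* ``table_calibrated`` (default) — draw counts exactly as calibrated; the
  declared stratum grade is bookkeeping and may disagree with rule-based
  regrading of the image.
* ``rule_consistent`` — deterministically adjust each image's drawn counts
  into the declared grade's feasible region (drop excess lesions from the
  fullest quadrants, add needed ones temporally), trading calibration
  fidelity for grading consistency.

An optional renderer turns a lesion map into a simple synthetic RGB fundus
image (bright disc, darker macula, dark-red lesion blobs) for exercising the
classical detector; it is a schematic stand-in, not a photorealistic model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .geometry import (
    QUADRANTS,
    EtdrsGrid,
    FundusFrame,
    Laterality,
    Region,
    assign_region,
)
from .grading import DEFAULT_RULES, GRADE_LABELS, GradeRuleSet
from .lesions import LesionMark, LesionType

DEFAULT_MA_DIAMETER_UM = (30.0, 110.0)
DEFAULT_HEM_DIAMETER_UM = (150.0, 800.0)

RateTable = Mapping[tuple[LesionType, Region], tuple[float, float]]


class PlacementError(RuntimeError):
    """No room to place a lesion under the geometric constraints."""


# ---------------------------------------------------------------------------
# Count law
# ---------------------------------------------------------------------------


def _nb_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    r = mean * mean / (var - mean)
    return r, r / (r + mean)


def sample_count(mean: float, sd: float, rng: np.random.Generator) -> int:
    """One non-negative lesion count with (approximately) the given moments.

    Negative binomial with matched mean and variance when ``sd^2 > mean``
    (dispersion size ``r = mean^2 / (sd^2 - mean)``), Poisson(mean) when
    ``sd^2 <= mean``, and identically zero when ``mean == 0``.
    """
    return int(sample_counts(mean, sd, 1, rng)[0])


def sample_counts(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized :func:`sample_count` (shape ``(size,)`` int array)."""
    if mean < 0 or sd < 0:
        raise ValueError(f"mean and sd must be non-negative, got {mean}, {sd}")
    if mean == 0:
        return np.zeros(size, dtype=int)
    if sd * sd > mean:
        r, p = _nb_params(mean, sd)
        return rng.negative_binomial(r, p, size=size).astype(int)
    return rng.poisson(mean, size=size).astype(int)


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuadrantRates:
    """(mean, SD) of the per-image lesion count, per lesion type and quadrant."""

    rates: RateTable

    def __post_init__(self) -> None:
        table: dict[tuple[LesionType, Region], tuple[float, float]] = {}
        for (lt, q), (mean, sd) in self.rates.items():
            lt, q = LesionType(lt), Region(q)
            if q not in QUADRANTS:
                raise ValueError(f"rates must be keyed by quadrants, got {q}")
            if mean < 0 or sd < 0:
                raise ValueError(f"negative rate for ({lt}, {q}): {mean} +/- {sd}")
            table[(lt, q)] = (float(mean), float(sd))
        for lt in LesionType:
            for q in QUADRANTS:
                table.setdefault((lt, q), (0.0, 0.0))
        object.__setattr__(self, "rates", table)

    def __getitem__(self, key: tuple[LesionType, Region]) -> tuple[float, float]:
        return self.rates[(LesionType(key[0]), Region(key[1]))]

    @classmethod
    def from_nested(cls, nested: Mapping[str, Mapping[str, Sequence[float]]]) -> "QuadrantRates":
        """From ``{lesion: {quadrant: [mean, sd]}}`` (the YAML preset layout)."""
        flat = {
            (LesionType(lt), Region(q)): (float(ms[0]), float(ms[1]))
            for lt, per_q in nested.items()
            for q, ms in per_q.items()
        }
        return cls(flat)


@dataclass(frozen=True)
class GradeStratum:
    label: str
    level: int
    n: int
    rates: QuadrantRates

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"stratum {self.label!r} needs n >= 2, got {self.n}")
        if GRADE_LABELS.get(self.level) is None:
            raise ValueError(f"level must be 0..3, got {self.level}")


@dataclass(frozen=True)
class FrameGeometry:
    """Camera/eye geometry template for generated frames.

    Defaults model a 45-degree non-mydriatic camera at 1440x960 px (9 um/px
    with the 288 um/degree retina scale), fovea near the image center with a
    small jitter, and the optic disc ~4500 um nasal and slightly superior.
    """

    width_px: int = 1440
    height_px: int = 960
    fov_deg: float = 45.0
    retina_um_per_deg: float = 288.0
    fovea_jitter_px: float = 12.0
    disc_offset_um: float = 4500.0
    disc_elevation_um: float = 270.0

    def make_frame(
        self, image_id: str, laterality: Laterality, rng: np.random.Generator
    ) -> FundusFrame:
        um_per_px = self.fov_deg * self.retina_um_per_deg / self.width_px
        fx = self.width_px / 2 + rng.uniform(-self.fovea_jitter_px, self.fovea_jitter_px)
        fy = self.height_px / 2 + rng.uniform(-self.fovea_jitter_px, self.fovea_jitter_px)
        sign = 1.0 if laterality is Laterality.RIGHT else -1.0
        dx = fx + sign * self.disc_offset_um / um_per_px
        dy = fy - self.disc_elevation_um / um_per_px
        return FundusFrame(
            image_id=image_id,
            width_px=self.width_px,
            height_px=self.height_px,
            fovea_x=fx,
            fovea_y=fy,
            disc_x=dx,
            disc_y=dy,
            fov_deg=self.fov_deg,
            retina_um_per_deg=self.retina_um_per_deg,
        )


@dataclass(frozen=True)
class CohortSpec:
    name: str
    strata: tuple[GradeStratum, ...]
    laterality_mix: float = 0.5  # fraction of right eyes
    seed: int | None = None
    mode: str = "table_calibrated"  # or "rule_consistent"
    geometry: FrameGeometry = field(default_factory=FrameGeometry)
    rules: GradeRuleSet = DEFAULT_RULES

    def __post_init__(self) -> None:
        if not 0.0 <= self.laterality_mix <= 1.0:
            raise ValueError("laterality_mix must be in [0, 1]")
        if self.mode not in ("table_calibrated", "rule_consistent"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.strata:
            raise ValueError("cohort needs at least one stratum")


def _load_preset(resource: str) -> dict:
    with resources.files("drquad.data").joinpath(resource).open("r") as fh:
        return yaml.safe_load(fh)


def load_preset(
    name: str,
    seed: int | None = None,
    strata: Sequence[str] | None = None,
    mode: str = "table_calibrated",
    laterality_mix: float = 0.5,
    geometry: FrameGeometry | None = None,
) -> CohortSpec:
    """Load a shipped cohort preset (``messidor`` or ``miradataset``).

    ``strata`` optionally restricts the cohort to a subset of grade labels
    (case-insensitive), e.g. ``["Severe"]`` for the severe stratum alone.
    """
    raw = _load_preset(f"{name.lower()}.yaml")
    wanted = None if strata is None else {s.lower() for s in strata}
    chosen = []
    for label, entry in raw["strata"].items():
        if wanted is not None and label.lower() not in wanted:
            continue
        chosen.append(
            GradeStratum(
                label=label,
                level=int(entry["level"]),
                n=int(entry["n"]),
                rates=QuadrantRates.from_nested(entry["rates"]),
            )
        )
    if wanted is not None and len(chosen) != len(wanted):
        raise ValueError(f"unknown strata {wanted - {s.label.lower() for s in chosen}} for preset {name}")
    return CohortSpec(
        name=raw["name"],
        strata=tuple(chosen),
        seed=seed,
        mode=mode,
        laterality_mix=laterality_mix,
        geometry=geometry or FrameGeometry(),
    )


def messidor_preset(**kwargs) -> CohortSpec:
    return load_preset("messidor", **kwargs)


def miradataset_preset(**kwargs) -> CohortSpec:
    return load_preset("miradataset", **kwargs)


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

_WEDGE_INTERVALS = {
    "superior": (45.0, 135.0),
    "image_left": (135.0, 225.0),
    "inferior": (225.0, 315.0),
    "image_right": (315.0, 405.0),
}


def _wedge_interval(region: Region, laterality: Laterality) -> tuple[float, float]:
    if region is Region.SUPERIOR:
        return _WEDGE_INTERVALS["superior"]
    if region is Region.INFERIOR:
        return _WEDGE_INTERVALS["inferior"]
    disc_right = laterality is Laterality.RIGHT
    if region is Region.NASAL:
        return _WEDGE_INTERVALS["image_right" if disc_right else "image_left"]
    if region is Region.TEMPORAL:
        return _WEDGE_INTERVALS["image_left" if disc_right else "image_right"]
    raise ValueError(f"cannot place lesions in region {region}")


def place_lesions(
    counts: Mapping[tuple[LesionType, Region], int],
    frame: FundusFrame,
    grid: EtdrsGrid | None = None,
    rng: np.random.Generator | None = None,
    ma_diameter_um: tuple[float, float] = DEFAULT_MA_DIAMETER_UM,
    hem_diameter_um: tuple[float, float] = DEFAULT_HEM_DIAMETER_UM,
    min_gap_um: float = 150.0,
    disc_clear_um: float = 2000.0,
    max_tries: int = 400,
) -> list[LesionMark]:
    """Place the requested number of lesions uniformly inside each quadrant.

    Rejection sampling guarantees that every placed mark satisfies
    ``assign_region(mark) == target quadrant``: outside the central ring,
    inside the field circle, within the target wedge, and at least
    ``disc_clear_um`` from the disc center.  ``min_gap_um`` is the minimum
    surface-to-surface distance between lesions; if a dense image cannot
    satisfy it within ``max_tries`` draws the gap constraint (only) is
    relaxed for that lesion, keeping counts exact.
    """
    if grid is None:
        grid = EtdrsGrid.for_frame(frame)
    if rng is None:
        rng = np.random.default_rng()
    upp = frame.um_per_px
    r_min = grid.central_ring_radius_px * (1 + 1e-9)
    fovea_off = math.hypot(
        grid.center_x - grid.field_center_x, grid.center_y - grid.field_center_y
    )
    r_max = grid.field_radius_px - fovea_off - 1.0
    if r_min >= r_max:
        raise PlacementError(
            f"central ring ({r_min:.0f} px) reaches the usable field radius ({r_max:.0f} px)"
        )
    ranges = {LesionType.MA: ma_diameter_um, LesionType.HEM: hem_diameter_um}
    placed: list[LesionMark] = []

    def try_place(lesion: LesionType, region: Region, enforce_gap: bool) -> LesionMark | None:
        lo, hi = _wedge_interval(region, frame.laterality)
        d_um = rng.uniform(*ranges[lesion])
        radius_px = d_um / 2.0 / upp
        for _ in range(max_tries):
            r = math.sqrt(rng.uniform(r_min**2, r_max**2))
            theta = math.radians(rng.uniform(lo, hi))
            x = grid.center_x + r * math.cos(theta)
            y = grid.center_y - r * math.sin(theta)  # image y grows downward
            if not (radius_px <= x < frame.width_px - radius_px and radius_px <= y < frame.height_px - radius_px):
                continue
            if math.hypot(x - frame.disc_x, y - frame.disc_y) < disc_clear_um / upp:
                continue
            if assign_region(x, y, frame, grid) is not region:
                continue
            if enforce_gap and any(
                math.hypot(x - m.x_px, y - m.y_px) * upp < (d_um + m.diameter_um) / 2 + min_gap_um
                for m in placed
            ):
                continue
            return LesionMark(lesion_type=lesion, x_px=x, y_px=y, diameter_um=d_um)
        return None

    for (lesion, region), k in counts.items():
        lesion, region = LesionType(lesion), Region(region)
        for _ in range(int(k)):
            mark = try_place(lesion, region, enforce_gap=min_gap_um > 0)
            if mark is None and min_gap_um > 0:
                mark = try_place(lesion, region, enforce_gap=False)
            if mark is None:
                raise PlacementError(f"could not place a {lesion.value} in {region.value}")
            placed.append(mark)
    return placed


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedImage:
    """One generated lesion map with its ground truth."""

    frame: FundusFrame
    marks: list[LesionMark]
    level: int
    label: str
    nv: int
    target_counts: dict[tuple[LesionType, Region], int]


def _draw_quadrant_counts(
    rates: QuadrantRates, rng: np.random.Generator
) -> dict[tuple[LesionType, Region], int]:
    return {
        (lt, q): sample_count(*rates[(lt, q)], rng)
        for lt in LesionType
        for q in QUADRANTS
    }


def _remove_excess(
    counts: dict[tuple[LesionType, Region], int], lesion: LesionType, excess: int
) -> None:
    # peel one at a time from the currently fullest quadrant (stable tie-break)
    for _ in range(excess):
        q = max(QUADRANTS, key=lambda q: (counts[(lesion, q)], -QUADRANTS.index(q)))
        if counts[(lesion, q)] == 0:
            break
        counts[(lesion, q)] -= 1


def enforce_grade_rules(
    counts: dict[tuple[LesionType, Region], int],
    level: int,
    rules: GradeRuleSet = DEFAULT_RULES,
) -> dict[tuple[LesionType, Region], int]:
    """Minimal deterministic adjustment of drawn counts to satisfy a grade.

    Used by the ``rule_consistent`` simulation mode: excess lesions are
    removed from the fullest quadrants, missing ones added to the temporal
    quadrant (the highest-load quadrant in the calibration tables).
    """
    c = dict(counts)
    ma = sum(v for (lt, _), v in c.items() if lt is LesionType.MA)
    hem = sum(v for (lt, _), v in c.items() if lt is LesionType.HEM)
    if level == 0:
        return {k: 0 for k in c}
    if level == 1:
        for q in QUADRANTS:
            c[(LesionType.HEM, q)] = 0
        if ma > rules.mild_ma_max:
            _remove_excess(c, LesionType.MA, ma - rules.mild_ma_max)
        elif ma == 0:
            c[(LesionType.MA, Region.TEMPORAL)] = 1
        return c
    if level == 2:
        if ma >= rules.moderate_ma_max:
            _remove_excess(c, LesionType.MA, ma - rules.moderate_ma_max + 1)
        if hem >= rules.moderate_hem_max:
            _remove_excess(c, LesionType.HEM, hem - rules.moderate_hem_max + 1)
        ma = sum(v for (lt, _), v in c.items() if lt is LesionType.MA)
        hem = sum(v for (lt, _), v in c.items() if lt is LesionType.HEM)
        if not (ma > rules.mild_ma_max or hem > 0):
            c[(LesionType.HEM, Region.TEMPORAL)] += 1
        return c
    if level == 3:
        if ma < rules.moderate_ma_max and hem < rules.moderate_hem_max:
            c[(LesionType.MA, Region.TEMPORAL)] += rules.moderate_ma_max - ma
        return c
    raise ValueError(f"level must be 0..3, got {level}")


def simulate_cohort(spec: CohortSpec, rng: np.random.Generator | None = None) -> list[SimulatedImage]:
    """Generate the full cohort of lesion maps described by ``spec``.

    Reproducible: a given ``spec.seed`` always yields the identical cohort.
    Per-grade image counts are exactly as specified; per-image quadrant
    counts follow the stratum's calibrated distributions.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    images: list[SimulatedImage] = []
    for stratum in spec.strata:
        for i in range(stratum.n):
            image_id = f"{spec.name}-{stratum.label.lower()}-{i:04d}"
            laterality = (
                Laterality.RIGHT if rng.random() < spec.laterality_mix else Laterality.LEFT
            )
            frame = spec.geometry.make_frame(image_id, laterality, rng)
            counts = _draw_quadrant_counts(stratum.rates, rng)
            if spec.mode == "rule_consistent":
                counts = enforce_grade_rules(counts, stratum.level, spec.rules)
            marks = place_lesions(counts, frame, rng=rng)
            images.append(
                SimulatedImage(
                    frame=frame,
                    marks=marks,
                    level=stratum.level,
                    label=stratum.label,
                    nv=0,
                    target_counts=counts,
                )
            )
    return images


def cohort_grades(images: Iterable[SimulatedImage]) -> dict[str, int]:
    """``image_id -> declared grade level`` mapping for a simulated cohort."""
    return {img.frame.image_id: img.level for img in images}


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RenderSpec:
    """Appearance parameters of the schematic fundus renderer.

    Colors are RGB in [0, 1].  The green channel carries the red-lesion
    contrast (dark lesions on an orange background), as in real fundus
    photographs.  Hemorrhages are drawn as randomly oriented ellipses with
    the equivalent-circle area of their nominal diameter; microaneurysms as
    circles.  ``edge_feather_px`` soft-blends lesion boundaries so that a
    threshold at half contrast recovers the nominal diameter.
    """

    background_rgb: tuple[float, float, float] = (0.78, 0.43, 0.24)
    disc_rgb: tuple[float, float, float] = (0.96, 0.86, 0.55)
    disc_radius_um: float = 900.0
    disc_axis_ratio: float = 0.85  # vertical/horizontal
    macula_depth: float = 0.04
    macula_sigma_um: float = 600.0
    ma_rgb: tuple[float, float, float] = (0.45, 0.10, 0.08)
    hem_rgb: tuple[float, float, float] = (0.33, 0.07, 0.06)
    hem_axis_ratio_range: tuple[float, float] = (0.65, 1.0)
    edge_feather_px: float = 1.2
    noise_sigma: float = 0.008
    ma_diameter_um: tuple[float, float] = DEFAULT_MA_DIAMETER_UM
    hem_diameter_um: tuple[float, float] = DEFAULT_HEM_DIAMETER_UM


def render_fundus(
    frame: FundusFrame,
    marks: Sequence[LesionMark],
    spec: RenderSpec = RenderSpec(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a lesion map as an 8-bit RGB fundus-like image.

    ``rng`` drives hemorrhage ellipse shapes and pixel noise; pass a seeded
    generator for reproducible renders.  Marks must lie inside the image.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    h, w = frame.height_px, frame.width_px
    upp = frame.um_per_px
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.background_rgb
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    # darker macula (gentle Gaussian dip in the green channel)
    sig = spec.macula_sigma_um / upp
    r2 = (xx - frame.fovea_x) ** 2 + (yy - frame.fovea_y) ** 2
    img[..., 1] -= spec.macula_depth * np.exp(-r2 / (2 * sig * sig))

    # bright optic disc (soft-edged ellipse)
    a = spec.disc_radius_um / upp
    b = a * spec.disc_axis_ratio
    rho = np.sqrt(((xx - frame.disc_x) / a) ** 2 + ((yy - frame.disc_y) / b) ** 2)
    alpha = np.clip(0.5 + (1.0 - rho) * math.sqrt(a * b) / spec.edge_feather_px, 0.0, 1.0)
    img = img * (1 - alpha[..., None]) + np.asarray(spec.disc_rgb) * alpha[..., None]

    for mark in marks:
        if not (0 <= mark.x_px < w and 0 <= mark.y_px < h):
            raise ValueError(f"mark at ({mark.x_px:.0f}, {mark.y_px:.0f}) outside the {w}x{h} image")
        r_px = mark.diameter_um / 2.0 / upp
        if mark.lesion_type is LesionType.HEM:
            q = rng.uniform(*spec.hem_axis_ratio_range)
            theta = rng.uniform(0, math.pi)
            color = spec.hem_rgb
        else:
            q, theta, color = 1.0, 0.0, spec.ma_rgb
        ae, be = r_px / math.sqrt(q), r_px * math.sqrt(q)
        pad = int(math.ceil(max(ae, be) + 3 * spec.edge_feather_px)) + 1
        x0, x1 = max(0, int(mark.x_px) - pad), min(w, int(mark.x_px) + pad + 1)
        y0, y1 = max(0, int(mark.y_px) - pad), min(h, int(mark.y_px) + pad + 1)
        ys, xs = np.mgrid[y0:y1, x0:x1].astype(np.float64)
        u = xs - mark.x_px
        v = ys - mark.y_px
        ur = u * math.cos(theta) + v * math.sin(theta)
        vr = -u * math.sin(theta) + v * math.cos(theta)
        rho = np.sqrt((ur / ae) ** 2 + (vr / be) ** 2)
        alpha = np.clip(0.5 + (1.0 - rho) * r_px / spec.edge_feather_px, 0.0, 1.0)
        img[y0:y1, x0:x1] = (
            img[y0:y1, x0:x1] * (1 - alpha[..., None]) + np.asarray(color) * alpha[..., None]
        )

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)
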