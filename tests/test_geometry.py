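"""Grid geometry: laterality, scaling, region assignment and counting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drquad import (
    DegenerateLandmarkError,
    EtdrsGrid,
    FundusFrame,
    Laterality,
    LesionMark,
    LesionType,
    Region,
    assign_region,
    assign_regions,
    count_by_region,
    infer_laterality,
    um_per_px_from_fov,
)


def oracle_region(x: float, y: float, frame: FundusFrame) -> Region:
    """Independent per-point assignment via atan2 and explicit angle intervals."""
    dx = x - frame.fovea_x
    dy_up = frame.fovea_y - y
    if math.hypot(dx, dy_up) * frame.um_per_px < 750.0:
        return Region.CENTRAL_RING
    cx, cy = (frame.width_px - 1) / 2, (frame.height_px - 1) / 2
    if math.hypot(x - cx, y - cy) > min(frame.width_px, frame.height_px) / 2:
        return Region.OUTSIDE_FIELD
    ang = math.degrees(math.atan2(dy_up, dx)) % 360.0
    if 45.0 <= ang < 135.0:
        return Region.SUPERIOR
    if 225.0 <= ang < 315.0:
        return Region.INFERIOR
    on_image_left = 135.0 <= ang < 225.0
    right_eye = frame.disc_x > frame.fovea_x
    if right_eye:
        return Region.TEMPORAL if on_image_left else Region.NASAL
    return Region.NASAL if on_image_left else Region.TEMPORAL


class TestLaterality:
    def test_disc_right_of_fovea_is_right_eye(self):
        frame = FundusFrame("a", 1440, 960, 720, 480, 1050, 470)
        assert infer_laterality(frame) is Laterality.RIGHT

    def test_disc_left_of_fovea_is_left_eye(self):
        frame = FundusFrame("b", 1440, 960, 720, 480, 390, 470)
        assert infer_laterality(frame) is Laterality.LEFT

    def test_vertically_aligned_landmarks_are_degenerate(self):
        with pytest.raises(DegenerateLandmarkError):
            FundusFrame("c", 1440, 960, 720, 480, 720, 300)


class TestScale:
    @pytest.mark.parametrize(
        "width,expected", [(1440, 9.0), (2880, 4.5)], ids=["messidor-small", "doubled"]
    )
    def test_um_per_px_from_45_degree_field(self, width, expected):
        assert um_per_px_from_fov(width, 45.0, 288.0) == pytest.approx(expected)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            um_per_px_from_fov(0, 45.0)


class TestAssignRegion:
    def test_point_above_fovea_is_superior(self, right_frame):
        y = right_frame.fovea_y - 2000 / right_frame.um_per_px
        assert assign_region(right_frame.fovea_x, y, right_frame) is Region.SUPERIOR

    def test_fovea_itself_is_central_ring(self, right_frame):
        assert assign_region(right_frame.fovea_x, right_frame.fovea_y, right_frame) is Region.CENTRAL_RING

    def test_central_ring_boundary(self, right_frame):
        for d_um, expected in [(749, Region.CENTRAL_RING), (751, Region.SUPERIOR)]:
            y = right_frame.fovea_y - d_um / right_frame.um_per_px
            assert assign_region(right_frame.fovea_x, y, right_frame) is expected

    def test_temporal_nasal_depend_on_laterality(self, right_frame, left_frame):
        dx = 2000 / right_frame.um_per_px
        x = right_frame.fovea_x - dx  # image-left of the fovea
        assert assign_region(x, right_frame.fovea_y, right_frame) is Region.TEMPORAL
        assert assign_region(x, left_frame.fovea_y, left_frame) is Region.NASAL

    def test_boundary_ray_goes_to_counterclockwise_wedge(self, right_frame):
        # exactly on the 45-degree ray: superior wedge (the CCW neighbour)
        d = 150.0
        x = right_frame.fovea_x + d
        y = right_frame.fovea_y - d
        assert assign_region(x, y, right_frame) is Region.SUPERIOR
        # exactly on the 135-degree ray: image-left wedge (temporal, right eye)
        assert assign_region(right_frame.fovea_x - d, y, right_frame) is Region.TEMPORAL

    def test_far_corner_is_outside_field(self, right_frame):
        assert assign_region(0, 0, right_frame) is Region.OUTSIDE_FIELD

    @pytest.mark.parametrize("eye", ["right", "left"])
    def test_agrees_with_atan2_interval_oracle(self, eye, right_frame, left_frame, rng):
        frame = right_frame if eye == "right" else left_frame
        xs = rng.uniform(0, frame.width_px, 4000)
        ys = rng.uniform(0, frame.height_px, 4000)
        got = assign_regions(xs, ys, frame)
        expected = [oracle_region(x, y, frame) for x, y in zip(xs, ys)]
        assert got == expected


class TestMirrorSymmetry:
    def test_point_mirror_about_fovea_swaps_temporal_nasal(self, right_frame, rng):
        """Reflecting positions across the vertical axis through the fovea
        exchanges the horizontal wedges and fixes the vertical ones."""
        swap = {
            Region.TEMPORAL: Region.NASAL,
            Region.NASAL: Region.TEMPORAL,
            Region.SUPERIOR: Region.SUPERIOR,
            Region.INFERIOR: Region.INFERIOR,
            Region.CENTRAL_RING: Region.CENTRAL_RING,
            Region.OUTSIDE_FIELD: Region.OUTSIDE_FIELD,
        }
        xs = rng.uniform(0, right_frame.width_px, 2000)
        ys = rng.uniform(0, right_frame.height_px, 2000)
        direct = assign_regions(xs, ys, right_frame)
        mirrored = assign_regions(2 * right_frame.fovea_x - xs, ys, right_frame)
        assert mirrored == [swap[r] for r in direct]

    def test_full_frame_mirror_preserves_all_labels(self, right_frame, rng):
        """Mirroring frame landmarks *and* points flips laterality but keeps
        every anatomical label (a left eye seen in a mirror)."""
        mirrored_frame = right_frame.mirrored_x()
        assert mirrored_frame.laterality is Laterality.LEFT
        xs = rng.uniform(0, right_frame.width_px, 2000)
        ys = rng.uniform(0, right_frame.height_px, 2000)
        direct = assign_regions(xs, ys, right_frame)
        mirrored = assign_regions(right_frame.width_px - 1 - xs, ys, mirrored_frame)
        assert mirrored == direct


class TestCountByRegion:
    def test_empty_marks_all_zero(self, right_frame):
        qc = count_by_region([], right_frame)
        assert qc.total() == 0

    def test_constructed_placement(self, right_frame):
        upp = right_frame.um_per_px
        marks = [
            LesionMark(LesionType.MA, right_frame.fovea_x, right_frame.fovea_y - 2000 / upp, 60)
            for _ in range(3)
        ] + [LesionMark(LesionType.HEM, right_frame.fovea_x, right_frame.fovea_y + 2000 / upp, 300)]
        qc = count_by_region(marks, right_frame)
        assert qc.n(Region.SUPERIOR, "MA") == 3
        assert qc.n(Region.INFERIOR, "HEM") == 1
        assert qc.total() == 4

    def test_counts_match_per_point_oracle_and_sum_to_total(self, right_frame, rng):
        xs = rng.uniform(0, right_frame.width_px, 500)
        ys = rng.uniform(0, right_frame.height_px, 500)
        marks = [LesionMark(LesionType.MA, x, y, 60) for x, y in zip(xs, ys)]
        qc = count_by_region(marks, right_frame)
        expected = {r: 0 for r in Region}
        for x, y in zip(xs, ys):
            expected[oracle_region(x, y, right_frame)] += 1
        assert {r: qc.n(r, "MA") for r in Region} == expected
        assert qc.total() == 500

    def test_unknown_lesion_type_rejected(self):
        with pytest.raises(ValueError, match="unknown lesion type"):
            LesionMark("exudate", 10, 10, 60)


@given(
    x=st.floats(min_value=0, max_value=1439),
    y=st.floats(min_value=0, max_value=959),
)
def test_every_point_gets_exactly_one_label(x, y):
    frame = FundusFrame("h", 1440, 960, 719.5, 479.5, 1219.5, 449.5)
    assert assign_region(x, y, frame) in Region


def test_grid_rejects_nonpositive_ring():
    with pytest.raises(ValueError):
        EtdrsGrid(center_x=0, center_y=0, um_per_px=9.0, central_ring_radius_um=0, field_radius_px=480)
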