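"""Equal-volume radii, voxel partitioning, and the brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from defectvol.geometry import (
    CONTROL,
    INNER,
    MIDDLE,
    OUTER,
    OUTSIDE,
    DefectROI,
    detect_defect_center,
    equal_volume_radii,
    estimate_z_extent,
    load_defect_config,
    partition_volume,
    validate_no_overlap,
)
from defectvol.io import LabelVolume, VoxelVolume

from conftest import make_plate_labels


def brute_force_partition(grid, roi):
    """Independent per-voxel classification by explicit python loops."""
    out = np.empty(grid.shape, dtype=np.uint8)
    cx, cy = roi.center_xy
    z_lo, z_hi = roi.z_range
    s = grid.spacing
    for k in range(grid.shape[0]):
        z = grid.origin[0] + (k + 0.5) * s
        in_z = z_lo <= z <= z_hi
        for j in range(grid.shape[1]):
            y = grid.origin[1] + (j + 0.5) * s
            for i in range(grid.shape[2]):
                x = grid.origin[2] + (i + 0.5) * s
                if not in_z:
                    out[k, j, i] = OUTSIDE
                    continue
                d = math.hypot(x - cx, y - cy)
                if d <= roi.r1:
                    out[k, j, i] = INNER
                elif d <= roi.r2:
                    out[k, j, i] = MIDDLE
                elif d <= roi.radius:
                    out[k, j, i] = OUTER
                elif d <= roi.control_radius:
                    out[k, j, i] = CONTROL
                else:
                    out[k, j, i] = OUTSIDE
    return out


class TestEqualVolumeRadii:
    def test_closed_forms_at_study_radius(self):
        r1, r2, rc = equal_volume_radii(4.0)
        assert r1 == pytest.approx(4.0 / math.sqrt(3.0), abs=1e-9)
        assert r2 == pytest.approx(4.0 * math.sqrt(2.0 / 3.0), abs=1e-9)
        assert rc == pytest.approx(8.0 / math.sqrt(3.0), abs=1e-9)
        assert (r1, r2, rc) == pytest.approx((2.309401, 3.265986, 4.618802), abs=1e-6)

    def test_scale_invariance(self):
        assert equal_volume_radii(1.0) == pytest.approx(
            (0.577350, 0.816497, 1.154701), abs=1e-6
        )
        four = np.array(equal_volume_radii(4.0))
        one = np.array(equal_volume_radii(1.0))
        np.testing.assert_allclose(four, 4 * one, rtol=1e-14)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=200, deadline=None)
    def test_equal_area_identity(self, R):
        r1, r2, rc = equal_volume_radii(R)
        areas = np.array(
            [r1**2, r2**2 - r1**2, R**2 - r2**2, rc**2 - R**2]
        ) * math.pi
        np.testing.assert_allclose(areas, areas[0], rtol=1e-12)
        assert 0 < r1 < r2 < R < rc

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("inf")])
    def test_invalid_radius(self, bad):
        with pytest.raises(ValueError):
            equal_volume_radii(bad)


class TestPartition:
    def test_matches_brute_force_on_coarse_grid(self):
        # spacing 1 mm, R = 2 mm: every voxel checked against the python loop
        grid = VoxelVolume(data=np.zeros((6, 12, 12)), spacing=1.0)
        roi = DefectROI(center_xy=(6.0, 6.0), radius=2.0, z_range=(1.0, 5.0))
        part = partition_volume(grid, roi)
        expected = brute_force_partition(grid, roi)
        np.testing.assert_array_equal(part.region_map, expected)

    def test_matches_brute_force_on_64cubed_offcenter(self):
        grid = VoxelVolume(data=np.zeros((20, 64, 64)), spacing=0.2)
        roi = DefectROI(center_xy=(6.53, 5.97), radius=2.3, z_range=(0.7, 3.1))
        part = partition_volume(grid, roi)
        np.testing.assert_array_equal(part.region_map, brute_force_partition(grid, roi))
        for region, code in (("inner", INNER), ("middle", MIDDLE),
                             ("outer", OUTER), ("control", CONTROL)):
            assert part.voxel_counts[region] == int((part.region_map == code).sum())

    def test_axis_voxel_is_inner(self):
        grid = VoxelVolume(data=np.zeros((3, 11, 11)), spacing=1.0)
        roi = DefectROI(center_xy=(5.5, 5.5), radius=3.0, z_range=(0.0, 3.0))
        part = partition_volume(grid, roi)
        assert part.region_map[1, 5, 5] == INNER  # voxel center on the axis, d = 0

    def test_regions_disjoint_and_fill_defect_cylinder(self):
        grid = VoxelVolume(data=np.zeros((10, 50, 50)), spacing=0.2)
        roi = DefectROI(center_xy=(5.0, 5.0), radius=2.0, z_range=(0.4, 1.6))
        part = partition_volume(grid, roi)
        inside = brute_force_partition(grid, roi)
        defect = np.isin(inside, (INNER, MIDDLE, OUTER))
        assert np.array_equal(np.isin(part.region_map, (INNER, MIDDLE, OUTER)), defect)

    def test_pairwise_counts_converge_with_resolution(self):
        mismatches = {}
        for spacing in (0.4, 0.2, 0.1, 0.046):
            n = int(10 / spacing)
            grid = VoxelVolume(data=np.zeros((4, n, n)), spacing=spacing)
            roi = DefectROI(center_xy=(5.0, 5.0), radius=4.0,
                            z_range=(0.0, 4 * spacing))
            mismatches[spacing] = partition_volume(grid, roi).pairwise_count_mismatch()
        assert mismatches[0.046] < mismatches[0.1] < mismatches[0.4]
        assert mismatches[0.046] < 0.005  # study resolution: well under 0.5%

    def test_counts_approach_analytic_volume(self):
        # |count - V/s^3| / (V/s^3) shrinks with spacing, per region
        for spacing, bound in ((0.2, 0.03), (0.046, 0.002)):
            n = int(10 / spacing)
            grid = VoxelVolume(data=np.zeros((4, n, n)), spacing=spacing)
            roi = DefectROI(center_xy=(5.0, 5.0), radius=4.0,
                            z_range=(0.0, 4 * spacing))
            part = partition_volume(grid, roi)
            analytic = roi.region_area_mm2() * 4 * spacing / spacing**3
            for region in ("inner", "middle", "outer", "control"):
                rel = abs(part.voxel_counts[region] - analytic) / analytic
                assert rel < bound, (spacing, region, rel)

    def test_rotation_invariance_90deg(self):
        spacing, n = 0.25, 48
        side = n * spacing
        grid = VoxelVolume(data=np.zeros((6, n, n)), spacing=spacing)
        cx, cy = 5.3, 6.1
        roi = DefectROI(center_xy=(cx, cy), radius=2.2, z_range=(0.25, 1.25))
        counts = partition_volume(grid, roi).voxel_counts
        # rotating the grid 90 deg in-plane about its middle maps the defect
        # center to (cy, side - cx); counts must be identical
        roi_rot = DefectROI(center_xy=(cy, side - cx), radius=2.2, z_range=(0.25, 1.25))
        assert partition_volume(grid, roi_rot).voxel_counts == counts

    def test_control_beyond_grid_is_an_error(self):
        grid = VoxelVolume(data=np.zeros((4, 20, 20)), spacing=0.2)
        roi = DefectROI(center_xy=(2.0, 2.0), radius=2.0, z_range=(0.0, 0.8))
        with pytest.raises(ValueError, match="control cylinder"):
            partition_volume(grid, roi)

    def test_region_volume_is_count_times_spacing_cubed(self):
        grid = VoxelVolume(data=np.zeros((6, 30, 30)), spacing=0.3)
        roi = DefectROI(center_xy=(4.5, 4.5), radius=1.5, z_range=(0.3, 1.5))
        part = partition_volume(grid, roi)
        for region, count in part.voxel_counts.items():
            assert part.region_volumes_mm3[region] == pytest.approx(count * 0.3**3, rel=1e-12)


class TestZExtent:
    def test_plate_extent_recovered_within_one_voxel(self):
        labels = make_plate_labels(shape=(40, 60, 60), spacing=0.1, z_plate=(1.0, 3.0))
        roi = DefectROI(center_xy=(3.0, 3.0), radius=1.0)
        z_lo, z_hi = estimate_z_extent(labels, roi)
        assert z_lo == pytest.approx(1.0 - labels.spacing, abs=labels.spacing)
        assert z_hi == pytest.approx(3.0 + labels.spacing, abs=labels.spacing)

    def test_explicit_z_range_bypasses_estimation(self):
        labels = make_plate_labels()
        roi = DefectROI(center_xy=(2.0, 2.0), radius=1.0, z_range=(0.5, 2.5))
        assert estimate_z_extent(labels, roi) == (0.5, 2.5)

    def test_empty_control_annulus_is_an_error(self):
        labels = LabelVolume(data=np.zeros((10, 30, 30), dtype=np.int16), spacing=0.1)
        roi = DefectROI(center_xy=(1.5, 1.5), radius=0.5)
        with pytest.raises(ValueError, match="z_range"):
            estimate_z_extent(labels, roi)


class TestConfig:
    def test_load_and_overlap_validation(self, tmp_path):
        cfg = {
            "defects": [
                {"id": "a", "group": "PCM", "center_xy_mm": [5.0, 5.0]},
                {"id": "b", "group": "blood", "center_xy_mm": [15.0, 5.0],
                 "radius_mm": 4.0, "z_range_mm": [0.5, 2.5]},
            ]
        }
        rois = load_defect_config(cfg)
        assert rois[0].radius == 4.0 and rois[0].z_range is None
        assert rois[1].z_range == (0.5, 2.5) and rois[1].group == "blood"

    def test_overlapping_controls_error_names_both_defects(self):
        rois = [
            DefectROI(center_xy=(5.0, 5.0), radius=4.0, defect_id="a"),
            DefectROI(center_xy=(10.0, 5.0), radius=4.0, defect_id="b"),
        ]
        with pytest.raises(ValueError, match="'a' and 'b'"):
            validate_no_overlap(rois)


def test_detect_defect_center_finds_the_hole():
    labels = make_plate_labels(shape=(20, 80, 80), spacing=0.1, z_plate=(0.5, 1.5))
    # punch a 2 mm-radius hole at (3.1, 4.2) mm
    yc = (np.arange(80) + 0.5) * 0.1
    xc = (np.arange(80) + 0.5) * 0.1
    hole = (yc[:, None] - 4.2) ** 2 + (xc[None, :] - 3.1) ** 2 <= 2.0**2
    labels.labels[:, hole] = 0
    cx, cy = detect_defect_center(labels)
    assert cx == pytest.approx(3.1, abs=0.1)
    assert cy == pytest.approx(4.2, abs=0.1)
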