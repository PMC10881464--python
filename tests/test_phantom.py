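"""Phantom generator: determinism, ground-truth conservation, cohorts."""

import numpy as np
import pytest

from defectvol.geometry import estimate_z_extent, partition_volume
from defectvol.io import BONE, GRAFT
from defectvol.phantom import (
    GroupEffect,
    PhantomDefect,
    PhantomSpec,
    cohort,
    cohort_fills,
    generate_phantom,
)
from defectvol.quantify import classify_corticality, quantify_defect
from defectvol.stats import anova_oneway, paired_t


def small_spec(**defect_kwargs):
    defaults = dict(
        defect_id="d", group="PCM", center_xy=(5.0, 5.0),
        bone_fill=(0.3, 0.5, 0.7), graft_fill=(0.08, 0.0, 0.0),
    )
    defaults.update(defect_kwargs)
    return PhantomSpec(
        plate_size_mm=(10.0, 10.0), spacing=0.1,
        defects=(PhantomDefect(**defaults),), seed=5,
    )


class TestGeneratePhantom:
    def test_same_spec_and_seed_bit_identical(self):
        spec = small_spec()
        g1, l1, _ = generate_phantom(spec)
        g2, l2, _ = generate_phantom(spec)
        assert np.array_equal(l1.labels, l2.labels)
        assert np.array_equal(g1.data, g2.data)

    def test_different_seed_differs(self):
        spec = small_spec()
        g1, _, _ = generate_phantom(spec)
        g2, _, _ = generate_phantom(
            PhantomSpec(**{**spec.__dict__, "seed": 6})
        )
        assert not np.array_equal(g1.data, g2.data)

    def test_ground_truth_conservation(self, coarse_phantom):
        # recorded per-region bone voxels must sum to the bone inside the
        # full defect cylinder, exactly
        (gray, labels, gt), spec = coarse_phantom
        d = spec.defects[0]
        s = labels.spacing
        yc = xc = (np.arange(labels.shape[1]) + 0.5) * s
        d2 = (yc[:, None] - d.center_xy[1]) ** 2 + (xc[None, :] - d.center_xy[0]) ** 2
        in_defect = d2 <= d.radius**2
        zc = (np.arange(labels.shape[0]) + 0.5) * s
        slab = (zc >= gt.plate_z_range[0]) & (zc <= gt.plate_z_range[1])
        cyl = slab[:, None, None] & in_defect[None, :, :]
        for material, code in (("bone_mm3", BONE), ("graft_mm3", GRAFT)):
            region_sum = sum(
                gt.per_region["c1"][r][material] for r in ("inner", "middle", "outer")
            )
            direct = int((labels.labels[cyl] == code).sum()) * labels.voxel_volume_mm3
            assert region_sum == pytest.approx(direct, rel=1e-12)

    def test_ground_truth_matches_label_recount(self, coarse_phantom):
        (gray, labels, gt), spec = coarse_phantom
        d = spec.defects[0]
        roi = d.roi().with_z_range(estimate_z_extent(labels, d.roi()))
        part = partition_volume(labels, roi)
        quant = quantify_defect(labels, part)
        expected = gt.expected_regeneration_pct("c1")
        for region in ("inner", "middle", "outer"):
            assert quant.regeneration_pct[region] == pytest.approx(expected[region], abs=1e-9)

    def test_unicortical_flag_yields_unicortical_classification(self):
        spec = small_spec(bi_cortical=False, graft_fill=(0.0, 0.0, 0.0))
        _, labels, gt = generate_phantom(spec)
        d = spec.defects[0]
        roi = d.roi().with_z_range(estimate_z_extent(labels, d.roi()))
        rep = classify_corticality(labels, roi)
        assert gt.corticality["d"] == "uni-cortical"
        assert rep.classification == "uni-cortical"

    def test_bicortical_flag_yields_bicortical_classification(self, coarse_phantom):
        (gray, labels, gt), spec = coarse_phantom
        d = spec.defects[0]
        roi = d.roi().with_z_range(estimate_z_extent(labels, d.roi()))
        assert classify_corticality(labels, roi).classification == "bi-cortical"

    def test_infeasible_fill_rejected(self):
        with pytest.raises(ValueError, match="<= 1"):
            PhantomDefect(defect_id="x", bone_fill=(0.8, 0.5, 0.5), graft_fill=(0.3, 0.0, 0.0))

    def test_overlapping_defects_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PhantomSpec(
                plate_size_mm=(20.0, 20.0),
                defects=(
                    PhantomDefect(defect_id="a", center_xy=(8.0, 10.0)),
                    PhantomDefect(defect_id="b", center_xy=(12.0, 10.0)),
                ),
            )

    def test_defect_outside_plate_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            small_spec(center_xy=(1.0, 5.0))

    def test_graft_shortfall_is_recorded(self):
        # outer region at bone fill 0.8 leaves a ring too thin for 0.25 mm
        # particles: placement must stop and record the shortfall
        spec = small_spec(graft_fill=(0.0, 0.0, 0.1))
        _, _, gt = generate_phantom(spec)
        assert "graft_outer" in gt.shortfalls["d"]

    def test_islet_mode_reaches_target_fill(self):
        spec = small_spec(bone_mode="islets", bone_fill=(0.3, 0.3, 0.3),
                          graft_fill=(0.0, 0.0, 0.0))
        _, labels, gt = generate_phantom(spec)
        regen = gt.expected_regeneration_pct("d")
        for region in ("inner", "middle", "outer"):
            assert regen[region] == pytest.approx(30.0, abs=3.0)

    def test_particle_diameters_within_requested_range(self, coarse_phantom):
        (gray, labels, gt), spec = coarse_phantom
        for region, dia in gt.particles["c1"]:
            dmin, dmax = spec.defects[0].particle_diameter_range
            assert dmin <= dia <= dmax


class TestCohort:
    GROUPS = [
        GroupEffect("blood", bone_fill_mean=(0.24, 0.45, 0.77), bone_fill_sd=(0.18, 0.18, 0.14)),
        GroupEffect("DBBMc", bone_fill_mean=(0.53, 0.66, 0.90), bone_fill_sd=(0.21, 0.16, 0.08),
                    graft_fill_mean=(0.10, 0.08, 0.05), graft_fill_sd=(0.03, 0.03, 0.02)),
    ]

    def test_fills_table_shape_and_bounds(self):
        fills = cohort_fills(self.GROUPS, n_subjects=8, seed=1)
        assert len(fills) == 8 * 2 * 3
        assert fills.bone_fill.between(0, 1).all()
        assert (fills.bone_fill + fills.graft_fill <= 1 + 1e-12).all()

    def test_single_subject_is_an_error(self):
        with pytest.raises(ValueError, match="2 subjects"):
            cohort_fills(self.GROUPS, n_subjects=1, seed=0)

    def test_negative_sd_is_an_error(self):
        with pytest.raises(ValueError, match="sd"):
            GroupEffect("x", bone_fill_mean=(0.5, 0.5, 0.5), bone_fill_sd=(-0.1, 0.1, 0.1))

    def test_stated_effect_detected_by_anova_on_fills(self):
        # the between-group gap in the inner region mirrors the study's
        # strongest contrast; at n = 8 the ANOVA should reject for this seed
        fills = cohort_fills(self.GROUPS, n_subjects=8, seed=11)
        inner = fills[fills.region == "inner"]
        groups = [inner[inner.group == g.group].bone_fill.tolist() for g in self.GROUPS]
        assert anova_oneway(groups).p < 0.05

    def test_inward_gradient_detected_by_paired_t(self):
        fills = cohort_fills(self.GROUPS, n_subjects=8, seed=2)
        blood = fills[fills.group == "blood"]
        inner = blood[blood.region == "inner"].bone_fill.to_numpy()
        outer = blood[blood.region == "outer"].bone_fill.to_numpy()
        assert paired_t(inner, outer).p < 0.05

    def test_null_cohorts_reject_at_about_alpha(self):
        null_groups = [
            GroupEffect(g, bone_fill_mean=(0.4, 0.5, 0.6), bone_fill_sd=(0.15, 0.15, 0.15))
            for g in ("a", "b", "c", "d")
        ]
        hits = 0
        reps = 200
        for rep in range(reps):
            fills = cohort_fills(null_groups, n_subjects=8, seed=10_000 + rep)
            inner = fills[fills.region == "inner"]
            groups = [inner[inner.group == g.group].bone_fill.tolist() for g in null_groups]
            if anova_oneway(groups).p < 0.05:
                hits += 1
        assert hits / reps < 0.11  # ~alpha, generous band at 200 reps

    def test_rasterized_cohort_recovers_fills_end_to_end(self):
        phantoms, fills = cohort(self.GROUPS, n_subjects=2, seed=4, spacing=0.15)
        assert len(phantoms) == 2
        gray, labels, gt, spec = phantoms[0]
        for d in spec.defects:
            roi = d.roi().with_z_range(estimate_z_extent(labels, d.roi()))
            part = partition_volume(labels, roi)
            quant = quantify_defect(labels, part)
            expected = gt.expected_regeneration_pct(d.defect_id)
            for region in ("inner", "middle", "outer"):
                assert quant.regeneration_pct[region] == pytest.approx(
                    expected[region], abs=1e-9
                )
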