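"""Synthetic calvarial-defect phantoms with exact voxel-level ground truth.

The phantom emulates the study system: a flat calvarial plate (~2 mm thick)
carrying circular critical-size defects of 8 mm diameter, each surrounded by
intact pristine bone. Healing inside a defect is laid down as new bone
growing inward from the margin (optionally as scattered central "bony
islets"), with residual graft present as non-overlapping mineralized
spherical particles of 0.25-1 mm diameter. A defect is either bi-cortical
(a through hole) or uni-cortical (the inferior cortical plate left intact).

Ground truth (per-region bone/graft voxel volumes, particle inventory,
corticality) is recorded from the final rasterized label volume, so pipeline
recovery can be checked against exact values. Generation is deterministic:
the same spec and seed reproduce the volumes bit for bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    CONTROL,
    DEFECT_REGIONS,
    INNER,
    MIDDLE,
    OUTER,
    OUTSIDE,
    REGION_CODES,
    DefectROI,
    validate_no_overlap,
)
from .io import BACKGROUND, BONE, GRAFT, LabelVolume, VoxelVolume

__all__ = ["PhantomDefect", "PhantomSpec", "PhantomGroundTruth", "generate_phantom",
           "GroupEffect", "cohort", "cohort_fills"]

log = logging.getLogger(__name__)

_MAX_CONSECUTIVE_REJECTIONS = 10_000


@dataclass(frozen=True)
class PhantomDefect:
    """One simulated defect: geometry, healing state and graft load.

    ``bone_fill`` / ``graft_fill`` give the target volume fractions of each
    defect region (inner, middle, outer) occupied by new bone / residual
    graft, relative to the region's cleared volume (the pristine plate is
    fully dense, so a bone fill of 0.2 yields ~20% regeneration against the
    control annulus).
    """

    defect_id: str
    group: str = "blood"
    center_xy: tuple[float, float] = (0.0, 0.0)
    radius: float = 4.0
    bone_fill: tuple[float, float, float] = (0.2, 0.45, 0.8)  # inner, middle, outer
    graft_fill: tuple[float, float, float] = (0.0, 0.0, 0.0)
    particle_diameter_range: tuple[float, float] = (0.25, 1.0)
    bi_cortical: bool = True
    bone_mode: str = "annular"  # "annular" margins-inward fronts | "islets" scattered spheres
    islet_diameter_mm: float = 0.25

    def __post_init__(self):
        for name, fills in (("bone_fill", self.bone_fill), ("graft_fill", self.graft_fill)):
            if len(fills) != 3 or any(not 0 <= f <= 1 for f in fills):
                raise ValueError(f"{name} must be three fractions in [0, 1], got {fills}")
        for fb, fg in zip(self.bone_fill, self.graft_fill):
            if fb + fg > 1:
                raise ValueError(
                    f"bone_fill + graft_fill must be <= 1 per region, got {fb}+{fg}"
                )
        dmin, dmax = self.particle_diameter_range
        if not 0 < dmin <= dmax <= self.radius:
            raise ValueError(
                f"particle diameters must satisfy 0 < dmin <= dmax <= R, "
                f"got {self.particle_diameter_range} with R={self.radius}"
            )
        if self.bone_mode not in ("annular", "islets"):
            raise ValueError(f"bone_mode must be 'annular' or 'islets', got {self.bone_mode}")

    def roi(self) -> DefectROI:
        return DefectROI(center_xy=self.center_xy, radius=self.radius,
                         defect_id=self.defect_id, group=self.group)


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description: plate, defects, imaging model, seed."""

    plate_size_mm: tuple[float, float] = (11.0, 11.0)  # (x, y)
    thickness_mm: float = 2.0
    spacing: float = 0.046
    z_margin_mm: float = 0.25
    defects: tuple[PhantomDefect, ...] = ()
    gray_means: tuple[float, float, float] = (0.0, 100.0, 200.0)  # background, bone, graft
    noise_sd: float = 5.0
    inferior_plate_fraction: float = 0.25  # uni-cortical: intact inferior band, as fraction of thickness
    seed: int = 0

    def __post_init__(self):
        if self.thickness_mm <= 0 or self.spacing <= 0 or self.z_margin_mm < 0:
            raise ValueError("thickness and spacing must be positive, z margin non-negative")
        rois = [d.roi() for d in self.defects]
        validate_no_overlap(rois)
        for roi in rois:
            cx, cy = roi.center_xy
            rc = roi.control_radius
            if (cx - rc < 0 or cx + rc > self.plate_size_mm[0]
                    or cy - rc < 0 or cy + rc > self.plate_size_mm[1]):
                raise ValueError(
                    f"defect {roi.defect_id!r} with control radius {rc:.3f} mm does "
                    f"not fit inside the {self.plate_size_mm} mm plate"
                )


@dataclass
class PhantomGroundTruth:
    """Exact voxel-level ground truth recorded at generation time.

    ``per_region[defect_id][region]`` holds ``bone_mm3``, ``graft_mm3``,
    ``region_mm3`` (voxel) and ``region_mm3_analytic``; ``particles`` lists
    (region, diameter_mm) per placed sphere; ``plate_z_range`` is the axial
    slab of the pristine plate.
    """

    per_region: dict[str, dict[str, dict[str, float]]]
    particles: dict[str, list[tuple[str, float]]]
    corticality: dict[str, str]
    plate_z_range: tuple[float, float]
    spacing: float
    shortfalls: dict[str, dict[str, float]] = field(default_factory=dict)

    def expected_regeneration_pct(self, defect_id: str) -> dict[str, float]:
        control_bone = self.per_region[defect_id]["control"]["bone_mm3"]
        return {
            r: 100.0 * self.per_region[defect_id][r]["bone_mm3"] / control_bone
            for r in DEFECT_REGIONS
        }

    def expected_graft_fraction_pct(self, defect_id: str) -> dict[str, float]:
        out = {}
        for r in DEFECT_REGIONS:
            reg = self.per_region[defect_id][r]
            tot = reg["bone_mm3"] + reg["graft_mm3"]
            out[r] = 100.0 * reg["graft_mm3"] / tot if tot else math.nan
        return out

    def n_particles(self, defect_id: str) -> int:
        return len(self.particles[defect_id])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for did, regions in self.per_region.items():
            for region, vals in regions.items():
                rows.append({"defect_id": did, "region": region, **vals})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rasterization helpers
# ---------------------------------------------------------------------------


def _region_bounds(roi: DefectROI) -> dict[str, tuple[float, float]]:
    return {
        "inner": (0.0, roi.r1),
        "middle": (roi.r1, roi.r2),
        "outer": (roi.r2, roi.radius),
    }


def _rasterize_sphere(labels, center_zyx, radius, spacing, value,
                      only_empty=True, clearance=0.0):
    """Set voxels whose centers lie within the sphere; returns (placed_count,
    had_collision). With only_empty, any nonzero voxel within
    radius + clearance of the center aborts placement — a clearance of
    sqrt(3) * spacing guarantees the placed voxels are not even
    26-adjacent to previously placed material, so non-overlapping graft
    spheres stay distinct connected components."""
    cz, cy, cx = center_zyx
    reach = radius + clearance
    lo = [max(0, int((c - reach) / spacing - 1)) for c in center_zyx]
    hi = [min(n, int((c + reach) / spacing + 2)) for c, n in zip(center_zyx, labels.shape)]
    if any(l >= h for l, h in zip(lo, hi)):
        return 0, False
    zc = (np.arange(lo[0], hi[0]) + 0.5) * spacing
    yc = (np.arange(lo[1], hi[1]) + 0.5) * spacing
    xc = (np.arange(lo[2], hi[2]) + 0.5) * spacing
    d2 = ((zc - cz)[:, None, None] ** 2 + (yc - cy)[None, :, None] ** 2
          + (xc - cx)[None, None, :] ** 2)
    mask = d2 <= radius**2
    sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    if only_empty and (sub[d2 <= reach**2] != BACKGROUND).any():
        return 0, True
    if only_empty:
        sub[mask] = value
        return int(mask.sum()), False
    newly = mask & (sub == BACKGROUND)
    sub[newly] = value
    return int(newly.sum()), False


def generate_phantom(spec: PhantomSpec):
    """Rasterize a phantom: returns ``(gray, labels, ground_truth)``.

    The plate is laid down as solid bone, defect interiors cleared (leaving
    the inferior cortical band for uni-cortical defects), then refilled with
    new bone per region and non-overlapping graft spheres (rejection
    sampling; a run of 10^4 consecutive rejections stops placement with a
    logged shortfall). The gray volume is class means plus Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.spacing
    nx = int(round(spec.plate_size_mm[0] / s))
    ny = int(round(spec.plate_size_mm[1] / s))
    nz = int(round((spec.thickness_mm + 2 * spec.z_margin_mm) / s))
    labels = np.zeros((nz, ny, nx), dtype=np.int16)

    z0 = spec.z_margin_mm
    z1 = z0 + spec.thickness_mm
    zc = (np.arange(nz) + 0.5) * s
    plate_slab = (zc >= z0) & (zc <= z1)
    labels[plate_slab] = BONE

    yc = (np.arange(ny) + 0.5) * s
    xc = (np.arange(nx) + 0.5) * s

    per_region: dict[str, dict] = {}
    particles: dict[str, list] = {}
    corticality: dict[str, str] = {}
    shortfalls: dict[str, dict] = {}

    for d in spec.defects:
        roi = d.roi()
        cx, cy = roi.center_xy
        d2 = (yc[:, None] - cy) ** 2 + (xc[None, :] - cx) ** 2
        in_defect = d2 <= roi.radius**2

        # clear the defect, keeping the inferior band for uni-cortical defects
        inf_th = spec.inferior_plate_fraction * spec.thickness_mm
        fill_z_lo = z0 if d.bi_cortical else z0 + inf_th
        cleared_slab = plate_slab & (zc >= fill_z_lo)
        labels[cleared_slab[:, None, None] & in_defect[None, :, :]] = BACKGROUND
        corticality[d.defect_id] = "bi-cortical" if d.bi_cortical else "uni-cortical"

        bounds = _region_bounds(roi)
        n_cleared_z = int(cleared_slab.sum())
        shortfalls[d.defect_id] = {}

        # --- new bone ---
        for region, f in zip(DEFECT_REGIONS, d.bone_fill):
            if f <= 0:
                continue
            a, b = bounds[region]
            if d.bone_mode == "annular":
                # ingrowth front from the region's outer margin inward:
                # annulus (r_fill, b] has area fraction f of the region
                r_fill = math.sqrt(b**2 - f * (b**2 - a**2))
                ring = (d2 > r_fill**2) & (d2 <= b**2) & (d2 > a**2 if a > 0 else True)
                labels[cleared_slab[:, None, None] & ring[None, :, :]] = BONE
            else:
                # scattered bony islets until the target voxel count is met
                region_mask = (d2 > a**2 if a > 0 else np.ones_like(d2, bool)) & (d2 <= b**2)
                region_voxels = int(region_mask.sum()) * n_cleared_z
                target = int(round(f * region_voxels))
                placed = 0
                rad = d.islet_diameter_mm / 2.0
                attempts = 0
                while placed < target and attempts < 100_000:
                    attempts += 1
                    r_lo, r_hi = max(a, 0.0) + rad, b - rad
                    if r_hi <= r_lo:
                        break
                    r = math.sqrt(rng.uniform(r_lo**2, r_hi**2))
                    th = rng.uniform(0, 2 * math.pi)
                    czp = rng.uniform(fill_z_lo + rad, z1 - rad)
                    n_set, _ = _rasterize_sphere(
                        labels, (czp, cy + r * math.sin(th), cx + r * math.cos(th)),
                        rad, s, BONE, only_empty=False)
                    placed += n_set
                if placed < target:
                    shortfalls[d.defect_id][f"bone_{region}"] = (target - placed) * s**3
                    log.warning("defect %s: bone islet shortfall in %s region",
                                d.defect_id, region)

        # --- residual graft particles (non-overlapping spheres) ---
        particles[d.defect_id] = []
        clearance = math.sqrt(3.0) * s  # keeps particles 26-disconnected
        for region, (g, f) in zip(DEFECT_REGIONS, zip(d.graft_fill, d.bone_fill)):
            if g <= 0:
                continue
            a, b = bounds[region]
            # stay clear of the annular bone front occupying (r_front, b]
            if d.bone_mode == "annular" and f > 0:
                r_front = math.sqrt(b**2 - f * (b**2 - a**2))
            else:
                r_front = b
            region_mask = (d2 > a**2 if a > 0 else np.ones_like(d2, bool)) & (d2 <= b**2)
            region_voxels = int(region_mask.sum()) * n_cleared_z
            target = int(round(g * region_voxels))
            placed = 0
            rejections = 0
            dmin, dmax = d.particle_diameter_range
            while placed < target and rejections < _MAX_CONSECUTIVE_REJECTIONS:
                dia = rng.uniform(dmin, dmax)
                rad = dia / 2.0
                r_lo, r_hi = max(a, 0.0) + rad, r_front - rad - clearance
                z_lo_c, z_hi_c = fill_z_lo + rad, z1 - rad
                if r_hi <= r_lo or z_hi_c <= z_lo_c:
                    rejections += 1
                    continue
                r = math.sqrt(rng.uniform(r_lo**2, r_hi**2))
                th = rng.uniform(0, 2 * math.pi)
                czp = rng.uniform(z_lo_c, z_hi_c)
                n_set, collided = _rasterize_sphere(
                    labels, (czp, cy + r * math.sin(th), cx + r * math.cos(th)),
                    rad, s, GRAFT, only_empty=True, clearance=clearance)
                if collided or n_set == 0:
                    rejections += 1
                    continue
                rejections = 0
                placed += n_set
                particles[d.defect_id].append((region, dia))
            if placed < target:
                shortfalls[d.defect_id][f"graft_{region}"] = (target - placed) * s**3
                log.warning("defect %s: graft shortfall in %s region (%d of %d voxels)",
                            d.defect_id, region, placed, target)

    # --- ground truth from the final voxel counts, plate slab only ---
    vv = s**3
    for d in spec.defects:
        roi = d.roi()
        cx, cy = roi.center_xy
        d2 = (yc[:, None] - cy) ** 2 + (xc[None, :] - cx) ** 2
        plane = np.full(d2.shape, OUTSIDE, dtype=np.uint8)
        plane[d2 <= roi.control_radius**2] = CONTROL
        plane[d2 <= roi.radius**2] = OUTER
        plane[d2 <= roi.r2**2] = MIDDLE
        plane[d2 <= roi.r1**2] = INNER
        sub = labels[plate_slab]
        per_region[d.defect_id] = {}
        h = spec.thickness_mm
        for region, code in REGION_CODES.items():
            mask = plane == code
            nvox = int(mask.sum()) * int(plate_slab.sum())
            bone_n = int(np.count_nonzero(sub[:, mask] == BONE))
            graft_n = int(np.count_nonzero(sub[:, mask] == GRAFT))
            if region == "control":
                area = math.pi * (roi.control_radius**2 - roi.radius**2)
            else:
                area = roi.region_area_mm2()
            per_region[d.defect_id][region] = {
                "bone_mm3": bone_n * vv,
                "graft_mm3": graft_n * vv,
                "region_mm3": nvox * vv,
                "region_mm3_analytic": area * h,
            }
        particles.setdefault(d.defect_id, [])

    gt = PhantomGroundTruth(
        per_region=per_region,
        particles=particles,
        corticality=corticality,
        plate_z_range=(z0, z1),
        spacing=s,
        shortfalls=shortfalls,
    )

    means = np.asarray(spec.gray_means, dtype=np.float32)
    gray = means[labels]
    if spec.noise_sd > 0:
        gray = gray + rng.normal(0.0, spec.noise_sd, size=gray.shape).astype(np.float32)

    gray_vol = VoxelVolume(data=gray, spacing=s)
    label_vol = LabelVolume(data=labels, spacing=s)
    return gray_vol, label_vol, gt


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupEffect:
    """Between-subject distribution of fills for one treatment group.

    Per-subject region fills are drawn Normal(mean, sd) independently per
    region and truncated to [0, 1] (values outside the unit interval are
    clipped). Tuples are ordered (inner, middle, outer).
    """

    group: str
    bone_fill_mean: tuple[float, float, float]
    bone_fill_sd: tuple[float, float, float]
    graft_fill_mean: tuple[float, float, float] = (0.0, 0.0, 0.0)
    graft_fill_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        for sd in (*self.bone_fill_sd, *self.graft_fill_sd):
            if sd < 0:
                raise ValueError(f"group {self.group!r}: sd must be >= 0, got {sd}")


def cohort_fills(groups: list[GroupEffect], n_subjects: int, seed: int) -> pd.DataFrame:
    """Simulate per-subject ground-truth fills for a cohort (no voxels).

    Emulates the study design — each subject carries one defect per
    treatment group — and returns a tidy table (subject, group, region,
    bone_fill, graft_fill) shaped for the stats module.
    """
    if n_subjects < 2:
        raise ValueError(f"need at least 2 subjects, got {n_subjects}")
    rng = np.random.default_rng(seed)
    rows = []
    for subj in range(n_subjects):
        for g in groups:
            for i, region in enumerate(DEFECT_REGIONS):
                bf = float(np.clip(rng.normal(g.bone_fill_mean[i], g.bone_fill_sd[i]), 0, 1))
                gf = float(np.clip(rng.normal(g.graft_fill_mean[i], g.graft_fill_sd[i]), 0, 1))
                if bf + gf > 1:
                    gf = 1.0 - bf
                rows.append({"subject": f"s{subj + 1}", "group": g.group,
                             "region": region, "bone_fill": bf, "graft_fill": gf})
    return pd.DataFrame(rows)


def cohort(
    groups: list[GroupEffect],
    n_subjects: int,
    seed: int,
    spacing: float = 0.092,
    rasterize: bool = True,
    **spec_kwargs,
):
    """Generate a cohort of phantoms, one defect per group per subject.

    Returns ``(phantoms, fills)`` where ``phantoms`` is a list of
    ``(gray, labels, ground_truth, spec)`` per subject (empty when
    ``rasterize=False``) and ``fills`` the tidy ground-truth fill table.
    Defects are laid out on a square grid on each subject's plate.
    """
    fills = cohort_fills(groups, n_subjects, seed)
    phantoms = []
    if not rasterize:
        return phantoms, fills

    k = len(groups)
    ncol = math.ceil(math.sqrt(k))
    nrow = math.ceil(k / ncol)
    rc = 2 * 4.0 / math.sqrt(3.0)
    cell = 2 * rc + 0.6
    plate = (ncol * cell, nrow * cell)

    for subj in range(n_subjects):
        sub = fills[fills.subject == f"s{subj + 1}"]
        defects = []
        for gi, g in enumerate(groups):
            rows = sub[sub.group == g.group].set_index("region")
            col, row = gi % ncol, gi // ncol
            defects.append(
                PhantomDefect(
                    defect_id=f"s{subj + 1}_{g.group}",
                    group=g.group,
                    center_xy=((col + 0.5) * cell, (row + 0.5) * cell),
                    bone_fill=tuple(rows.loc[r, "bone_fill"] for r in DEFECT_REGIONS),
                    graft_fill=tuple(rows.loc[r, "graft_fill"] for r in DEFECT_REGIONS),
                )
            )
        spec = PhantomSpec(
            plate_size_mm=plate,
            spacing=spacing,
            defects=tuple(defects),
            seed=seed + 1000 + subj,
            **spec_kwargs,
        )
        phantoms.append((*generate_phantom(spec), spec))
    return phantoms, fills
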