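"""2D zonal histomorphometry of defect cross-sections.

A stained mid-defect section is consumed as an already-labeled image
(background / bone / connective tissue / graft). The defect profile between
its two surgical edges is divided into three zones — outer, middle, inner —
progressing from the edges toward the center, using the same radii as the
3D analysis projected onto the section axis: with center c and half-width
R, the inner zone is |x - c| <= R/sqrt(3), the middle extends to
R*sqrt(2/3) and the outer to R. (An alternative zoning with equal 2D areas
per zone is available behind ``equal_area_2d=True``.)

Area percentages follow the histometric formulas:
bone% = bone / (bone + connective tissue), connective% is its complement,
and graft% = graft / (bone + connective tissue) — so bone% + ct% = 100
exactly wherever defined, and graft% may exceed 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import equal_volume_radii

__all__ = [
    "SECTION_BACKGROUND",
    "SECTION_BONE",
    "SECTION_CONNECTIVE",
    "SECTION_GRAFT",
    "SectionImage",
    "ZonalAreas",
    "zones_from_edges",
    "zonal_areas",
    "section_from_labels",
]

SECTION_BACKGROUND = 0
SECTION_BONE = 1
SECTION_CONNECTIVE = 2
SECTION_GRAFT = 3

_ZONES = ("inner", "middle", "outer")


@dataclass(frozen=True)
class SectionImage:
    """A labeled histological section.

    ``labels`` is a 2D array (rows = depth, columns = the section axis along
    the defect diameter) with the SECTION_* class codes; ``left_mm`` and
    ``right_mm`` mark the defect edges on the column axis (world mm, column
    center of pixel j at (j + 0.5) * pixel_size_mm).
    """

    labels: np.ndarray
    pixel_size_mm: float
    left_mm: float
    right_mm: float

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError(f"section image must be 2D, got ndim={lab.ndim}")
        if not self.pixel_size_mm > 0:
            raise ValueError(f"pixel size must be positive, got {self.pixel_size_mm}")
        if not self.right_mm > self.left_mm:
            raise ValueError(
                f"defect edges must satisfy right > left, got [{self.left_mm}, {self.right_mm}]"
            )
        object.__setattr__(self, "labels", lab)

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_size_mm**2


@dataclass
class ZonalAreas:
    """Per-zone class areas (mm2) and the derived percentages.

    Percentages are NaN (undefined) in a zone with no bone and no
    connective tissue.
    """

    areas_mm2: dict[str, dict[str, float]]  # zone -> class name -> mm2
    bone_pct: dict[str, float]
    ct_pct: dict[str, float]
    graft_pct: dict[str, float]


def zones_from_edges(
    left_mm: float, right_mm: float, equal_area_2d: bool = False
) -> dict[str, tuple[float, float]]:
    """Zone boundaries as half-distance bands |x - c| in (lo, hi].

    Default bands mirror the 3D region radii (R/sqrt(3), R*sqrt(2/3), R);
    with ``equal_area_2d`` the bands instead split the 1D profile into three
    equal widths (equal areas in the planar section).
    """
    if not right_mm > left_mm:
        raise ValueError(f"degenerate defect width: left={left_mm}, right={right_mm}")
    R = (right_mm - left_mm) / 2.0
    if equal_area_2d:
        b1, b2 = R / 3.0, 2.0 * R / 3.0
    else:
        b1, b2, _ = equal_volume_radii(R)
    return {"inner": (0.0, b1), "middle": (b1, b2), "outer": (b2, R)}


def zonal_areas(
    section: SectionImage, zones: dict[str, tuple[float, float]] | None = None
) -> ZonalAreas:
    """Class areas and histometric percentages per zone.

    Pixels are assigned to zones by the half-distance of their column
    centers from the defect center, ties inward (|x - c| <= bound), matching
    the 3D voxel-center rule. Pixels beyond the defect edges are ignored.
    """
    if zones is None:
        zones = zones_from_edges(section.left_mm, section.right_mm)
    c = (section.left_mm + section.right_mm) / 2.0
    ncols = section.labels.shape[1]
    xc = (np.arange(ncols) + 0.5) * section.pixel_size_mm
    dist = np.abs(xc - c)

    pa = section.pixel_area_mm2
    areas: dict[str, dict[str, float]] = {}
    bone_pct, ct_pct, graft_pct = {}, {}, {}
    class_names = {
        SECTION_BONE: "bone",
        SECTION_CONNECTIVE: "connective_tissue",
        SECTION_GRAFT: "graft",
    }
    for zone in _ZONES:
        lo, hi = zones[zone]
        cols = (dist > lo) & (dist <= hi) if lo > 0 else dist <= hi
        sub = section.labels[:, cols]
        counts = np.bincount(sub.ravel(), minlength=4)
        areas[zone] = {name: float(counts[code]) * pa for code, name in class_names.items()}
        bone = areas[zone]["bone"]
        ct = areas[zone]["connective_tissue"]
        graft = areas[zone]["graft"]
        denom = bone + ct
        if denom == 0:
            bone_pct[zone] = ct_pct[zone] = graft_pct[zone] = math.nan
        else:
            bone_pct[zone] = 100.0 * bone / denom
            ct_pct[zone] = 100.0 - bone_pct[zone]  # complement: sums to 100 exactly
            graft_pct[zone] = 100.0 * graft / denom
    return ZonalAreas(areas_mm2=areas, bone_pct=bone_pct, ct_pct=ct_pct, graft_pct=graft_pct)


def section_from_labels(labels_3d, roi, plate_z_range: tuple[float, float]) -> SectionImage:
    """Render a synthetic mid-defect section from a 3D label volume.

    Takes the coronal plane through the defect center; voxels inside the
    plate slab that are neither bone nor graft become connective tissue
    (in vivo, unmineralized defect space is connective tissue, which CT
    cannot separate from background but histology can).
    """
    from .io import BONE as B3, GRAFT as G3

    cy = roi.center_xy[1]
    j = int(cy / labels_3d.spacing)  # row whose center is nearest the axis
    plane = labels_3d.labels[:, j, :]
    zc = labels_3d.axis_centers(0)
    in_plate = (zc >= plate_z_range[0]) & (zc <= plate_z_range[1])

    out = np.full(plane.shape, SECTION_BACKGROUND, dtype=np.int16)
    out[plane == B3] = SECTION_BONE
    out[plane == G3] = SECTION_GRAFT
    soft = (plane == 0) & in_plate[:, None]
    out[soft] = SECTION_CONNECTIVE
    out = out[in_plate, :]
    return SectionImage(
        labels=out,
        pixel_size_mm=labels_3d.spacing,
        left_mm=roi.center_xy[0] - roi.radius,
        right_mm=roi.center_xy[0] + roi.radius,
    )
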