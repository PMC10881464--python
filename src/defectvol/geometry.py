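"""Defect ROI geometry: equal-volume coaxial cylindrical regions.

An 8 mm circular calvarial defect (radius ``R``) is partitioned into three
coaxial regions of equal volume — a central cylinder (*inner*) and two tubes
(*middle*, *outer*) — plus a fourth concentric annulus of the same volume
around the defect (*control*) representing the surrounding pristine bone.
Because all four share the same axial extent, equal volume reduces to equal
cross-section area, giving the closed-form radii

    r1 = R / sqrt(3),   r2 = R * sqrt(2/3),   Rc = 2R / sqrt(3)

so that pi*r1^2 = pi*(r2^2 - r1^2) = pi*(R^2 - r2^2) = pi*(Rc^2 - R^2).

Voxels are assigned to regions by the position of their *centers*, with
half-open boundaries (ties at a radius go inward): inner for d <= r1,
middle for r1 < d <= r2, outer for r2 < d <= R, control for R < d <= Rc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .io import BONE, LabelVolume, VoxelVolume

__all__ = [
    "OUTSIDE",
    "INNER",
    "MIDDLE",
    "OUTER",
    "CONTROL",
    "REGION_CODES",
    "REGION_NAMES",
    "DEFECT_REGIONS",
    "DefectROI",
    "RegionPartition",
    "equal_volume_radii",
    "estimate_z_extent",
    "partition_volume",
    "validate_no_overlap",
    "detect_defect_center",
    "load_defect_config",
]

OUTSIDE, INNER, MIDDLE, OUTER, CONTROL = 0, 1, 2, 3, 4
REGION_CODES = {"inner": INNER, "middle": MIDDLE, "outer": OUTER, "control": CONTROL}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}
#: the three regions inside the defect proper, ordered center -> margin
DEFECT_REGIONS = ("inner", "middle", "outer")

#: relative tolerance of the equal-area invariant check
_AREA_RTOL = 1e-12


def equal_volume_radii(radius: float) -> tuple[float, float, float]:
    """Radii ``(r1, r2, Rc)`` splitting a defect of radius ``radius`` into
    four equal-volume concentric regions (three inside + control annulus).

    >>> equal_volume_radii(4.0)  # doctest: +ELLIPSIS
    (2.3094..., 3.2659..., 4.6188...)
    """
    R = float(radius)
    if not (R > 0 and math.isfinite(R)):
        raise ValueError(f"defect radius must be positive and finite, got {radius}")
    return R / math.sqrt(3.0), R * math.sqrt(2.0 / 3.0), 2.0 * R / math.sqrt(3.0)


@dataclass(frozen=True)
class DefectROI:
    """A circular defect and its equal-volume region radii.

    Parameters
    ----------
    center_xy:
        World coordinates (mm) of the cylinder axis, ordered ``(x, y)``.
    radius:
        Defect radius R in mm (8 mm diameter defects give R = 4).
    z_range:
        ``(z_low, z_high)`` in mm spanned by all four cylinders, or ``None``
        until estimated from the data (see :func:`estimate_z_extent`).
    """

    center_xy: tuple[float, float]
    radius: float = 4.0
    z_range: tuple[float, float] | None = None
    defect_id: str = "defect"
    group: str | None = None

    def __post_init__(self):
        r1, r2, rc = equal_volume_radii(self.radius)
        areas = [
            math.pi * r1**2,
            math.pi * (r2**2 - r1**2),
            math.pi * (self.radius**2 - r2**2),
            math.pi * (rc**2 - self.radius**2),
        ]
        ref = areas[0]
        if any(abs(a - ref) > _AREA_RTOL * ref for a in areas):  # pragma: no cover
            raise AssertionError("equal-area invariant violated")
        if self.z_range is not None:
            lo, hi = self.z_range
            if not hi > lo:
                raise ValueError(f"z_range must satisfy z_high > z_low, got {self.z_range}")
            object.__setattr__(self, "z_range", (float(lo), float(hi)))
        object.__setattr__(self, "center_xy", tuple(float(v) for v in self.center_xy))

    @property
    def r1(self) -> float:
        return self.radius / math.sqrt(3.0)

    @property
    def r2(self) -> float:
        return self.radius * math.sqrt(2.0 / 3.0)

    @property
    def control_radius(self) -> float:
        return 2.0 * self.radius / math.sqrt(3.0)

    def with_z_range(self, z_range: tuple[float, float]) -> "DefectROI":
        return replace(self, z_range=z_range)

    def region_area_mm2(self) -> float:
        """Analytic cross-section area (mm2), identical for all four regions."""
        return math.pi * self.r1**2

    def region_volume_mm3(self) -> float:
        """Analytic region volume (mm3); requires an established z_range."""
        if self.z_range is None:
            raise ValueError("z_range not established; call estimate_z_extent first")
        return self.region_area_mm2() * (self.z_range[1] - self.z_range[0])


@dataclass
class RegionPartition:
    """Voxel-to-region assignment for one defect ROI.

    ``region_map`` holds the codes OUTSIDE/INNER/MIDDLE/OUTER/CONTROL over
    the full grid; counts and mm3 volumes are per region name.
    """

    region_map: np.ndarray
    voxel_counts: dict[str, int]
    region_volumes_mm3: dict[str, float]
    roi: DefectROI
    spacing: float

    def mask(self, region: str) -> np.ndarray:
        return self.region_map == REGION_CODES[region]

    def pairwise_count_mismatch(self) -> float:
        """Largest pairwise relative difference between the four region
        voxel counts (voxelization error; -> 0 as spacing -> 0)."""
        counts = [self.voxel_counts[r] for r in ("inner", "middle", "outer", "control")]
        lo, hi = min(counts), max(counts)
        return (hi - lo) / lo if lo else math.inf


def _radial_distance_sq(grid: VoxelVolume, roi: DefectROI) -> np.ndarray:
    """Squared in-plane distance (mm2) of every voxel center from the axis,
    shaped (ny, nx)."""
    ycent = grid.axis_centers(1)
    xcent = grid.axis_centers(2)
    cx, cy = roi.center_xy
    return (ycent[:, None] - cy) ** 2 + (xcent[None, :] - cx) ** 2


def estimate_z_extent(labels: LabelVolume, roi: DefectROI) -> tuple[float, float]:
    """Axial extent of the cylinders from the pristine bone around the defect.

    If ``roi.z_range`` is already set it is returned unchanged. Otherwise the
    range is the [min, max] z of bone voxel *centers* inside the control
    annulus (R < d <= Rc), expanded by one voxel spacing on each side — the
    control annulus is the study's reference for normal bone thickness, so
    the cylinder height follows the local plate.
    """
    if roi.z_range is not None:
        return roi.z_range
    d2 = _radial_distance_sq(labels, roi)
    in_annulus = (d2 > roi.radius**2) & (d2 <= roi.control_radius**2)
    bone_zyx = (labels.labels == BONE) & in_annulus[None, :, :]
    z_any = bone_zyx.any(axis=(1, 2))
    if not z_any.any():
        raise ValueError(
            f"defect {roi.defect_id!r}: no bone found in the control annulus; "
            "provide an explicit z_range in the defect configuration"
        )
    zc = labels.axis_centers(0)
    z_lo = float(zc[z_any.argmax()]) - labels.spacing
    z_hi = float(zc[len(z_any) - 1 - z_any[::-1].argmax()]) + labels.spacing
    return z_lo, z_hi


def partition_volume(grid: VoxelVolume, roi: DefectROI) -> RegionPartition:
    """Assign every voxel of ``grid`` to a region of ``roi`` by voxel center.

    Raises if the control cylinder extends beyond the lateral grid bounds
    (the control annulus would be truncated and its volume biased).
    """
    if roi.z_range is None:
        if isinstance(grid, LabelVolume):
            roi = roi.with_z_range(estimate_z_extent(grid, roi))
        else:
            raise ValueError("z_range not set; estimate it from a LabelVolume first")

    cx, cy = roi.center_xy
    rc = roi.control_radius
    x_lo, x_hi = grid.origin[2], grid.origin[2] + grid.shape[2] * grid.spacing
    y_lo, y_hi = grid.origin[1], grid.origin[1] + grid.shape[1] * grid.spacing
    if cx - rc < x_lo or cx + rc > x_hi or cy - rc < y_lo or cy + rc > y_hi:
        raise ValueError(
            f"defect {roi.defect_id!r}: control cylinder (radius {rc:.3f} mm at "
            f"({cx}, {cy})) extends beyond the grid bounds "
            f"x=[{x_lo}, {x_hi}], y=[{y_lo}, {y_hi}]"
        )

    d2 = _radial_distance_sq(grid, roi)
    plane = np.full(d2.shape, OUTSIDE, dtype=np.uint8)
    plane[d2 <= rc**2] = CONTROL
    plane[d2 <= roi.radius**2] = OUTER
    plane[d2 <= roi.r2**2] = MIDDLE
    plane[d2 <= roi.r1**2] = INNER

    zc = grid.axis_centers(0)
    z_lo, z_hi = roi.z_range
    in_z = (zc >= z_lo) & (zc <= z_hi)
    region_map = np.where(in_z[:, None, None], plane[None, :, :], OUTSIDE).astype(np.uint8)

    nz = int(in_z.sum())
    plane_counts = np.bincount(plane.ravel(), minlength=5)
    counts = {name: int(plane_counts[code]) * nz for name, code in REGION_CODES.items()}
    vv = grid.voxel_volume_mm3
    volumes = {name: n * vv for name, n in counts.items()}
    return RegionPartition(
        region_map=region_map,
        voxel_counts=counts,
        region_volumes_mm3=volumes,
        roi=roi,
        spacing=grid.spacing,
    )


def validate_no_overlap(rois: list[DefectROI]) -> None:
    """Raise if any two configured defects' region systems (including the
    control annuli) overlap — overlapping controls would double-count
    pristine bone."""
    for i in range(len(rois)):
        for j in range(i + 1, len(rois)):
            a, b = rois[i], rois[j]
            dist = math.hypot(a.center_xy[0] - b.center_xy[0], a.center_xy[1] - b.center_xy[1])
            if dist < a.control_radius + b.control_radius:
                raise ValueError(
                    f"defects {a.defect_id!r} and {b.defect_id!r} overlap: center "
                    f"distance {dist:.3f} mm < sum of control radii "
                    f"{a.control_radius + b.control_radius:.3f} mm"
                )


def detect_defect_center(
    labels: LabelVolume, expected_radius: float = 4.0
) -> tuple[float, float]:
    """Convenience circle fit to the bone-free area of a z-projection.

    Projects bone occupancy along z, takes the largest bone-free connected
    component surrounded by bone, and returns the centroid of that hole in
    world (x, y) mm. Never applied silently: callers must opt in; configured
    centers always win.
    """
    from scipy import ndimage

    bone_proj = (labels.labels == BONE).any(axis=0)
    holes = ~bone_proj
    # keep only holes not touching the projection border (the defect proper)
    lab, n = ndimage.label(holes)
    if n == 0:
        raise ValueError("no bone-free region found in the z-projection")
    border = np.unique(np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]]))
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    for b in border:
        if b > 0:
            sizes[b - 1] = 0
    if not sizes.any():
        raise ValueError("no interior bone-free region found (defect touches the border?)")
    best = int(np.argmax(sizes)) + 1
    cy_idx, cx_idx = ndimage.center_of_mass(lab == best)
    cx = labels.origin[2] + (cx_idx + 0.5) * labels.spacing
    cy = labels.origin[1] + (cy_idx + 0.5) * labels.spacing
    return float(cx), float(cy)


def load_defect_config(source) -> list[DefectROI]:
    """Parse the per-sample defect configuration.

    ``source`` is a YAML file path or an already-parsed mapping of the form::

        defects:
          - id: d1
            group: PCM            # blood | PCM | DBBMb | DBBMc
            center_xy_mm: [6.0, 6.0]
            radius_mm: 4.0        # default 4.0 (8 mm diameter)
            z_range_mm: auto      # or [z_low, z_high]
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = source
    if not isinstance(cfg, dict) or "defects" not in cfg:
        raise ValueError("defect configuration must contain a 'defects' list")
    rois = []
    for entry in cfg["defects"]:
        z = entry.get("z_range_mm", "auto")
        z_range = None if (z in (None, "auto")) else (float(z[0]), float(z[1]))
        rois.append(
            DefectROI(
                center_xy=tuple(entry["center_xy_mm"]),
                radius=float(entry.get("radius_mm", 4.0)),
                z_range=z_range,
                defect_id=str(entry.get("id", f"defect{len(rois) + 1}")),
                group=entry.get("group"),
            )
        )
    validate_no_overlap(rois)
    return rois
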