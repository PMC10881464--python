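"""Grayscale segmentation into bone / graft / background, and residual
graft-particle characterization.

Mineralized graft particles are denser than new bone on micro-CT, so the
default class ordering by gray value is background < bone < graft. Thresholds
are either explicit half-open gray intervals or derived automatically by a
three-class multi-Otsu histogram split; the cut points actually used are
always recorded so a run is reproducible without any interactive step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu

from .io import BACKGROUND, BONE, GRAFT, LabelVolume, VoxelVolume

__all__ = ["ThresholdSpec", "ParticleReport", "auto_thresholds", "threshold_segment",
           "particle_components"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdSpec:
    """Gray-level thresholds for the three-class segmentation.

    ``bone_range`` and ``graft_range`` are half-open intervals ``[lo, hi)``;
    ``hi`` may be ``None`` for an unbounded upper end. With ``auto=True`` the
    two cut points are derived from a 3-class Otsu split of the histogram and
    the intervals are ignored.
    """

    bone_range: tuple[float, float | None] | None = None
    graft_range: tuple[float, float | None] | None = None
    auto: bool = False

    def __post_init__(self):
        if self.auto:
            return
        if self.bone_range is None or self.graft_range is None:
            raise ValueError("provide bone_range and graft_range, or set auto=True")
        for name, (lo, hi) in (("bone", self.bone_range), ("graft", self.graft_range)):
            if hi is not None and not hi > lo:
                raise ValueError(f"{name}_range [{lo}, {hi}) is empty")
        b_lo, b_hi = self.bone_range
        g_lo, g_hi = self.graft_range
        b_hi = np.inf if b_hi is None else b_hi
        g_hi = np.inf if g_hi is None else g_hi
        if max(b_lo, g_lo) < min(b_hi, g_hi):
            raise ValueError(
                f"bone range [{b_lo}, {b_hi}) and graft range [{g_lo}, {g_hi}) overlap"
            )


@dataclass
class ParticleReport:
    """Connected-component summary of residual graft particles."""

    n_particles: int
    volumes_mm3: np.ndarray  # sorted descending
    equivalent_diameters_mm: np.ndarray  # sphere-equivalent, same order
    connectivity: int = 26

    def total_volume_mm3(self) -> float:
        return float(self.volumes_mm3.sum())


def auto_thresholds(gray: np.ndarray, max_iter: int = 50) -> tuple[float, float]:
    """Two cut points for a 3-class split of the gray histogram.

    Starts from a 3-class multi-Otsu split, then iterates Lloyd-style:
    recompute the three class means and move each cut to the midpoint of
    adjacent means, until stable. The refinement removes the tie ambiguity
    multi-Otsu has inside empty histogram valleys (any cut in a gap is
    equally optimal), pinning the cuts at the midpoints between the class
    gray levels instead.
    """
    flat = np.asarray(gray).ravel()
    t0, t1 = (float(t) for t in threshold_multiotsu(flat, classes=3))
    for _ in range(max_iter):
        lo = flat[flat < t0]
        mid = flat[(flat >= t0) & (flat < t1)]
        hi = flat[flat >= t1]
        if lo.size == 0 or mid.size == 0 or hi.size == 0:
            break
        new0 = (lo.mean() + mid.mean()) / 2.0
        new1 = (mid.mean() + hi.mean()) / 2.0
        if abs(new0 - t0) < 1e-9 and abs(new1 - t1) < 1e-9:
            break
        t0, t1 = float(new0), float(new1)
    return t0, t1


def threshold_segment(
    volume: VoxelVolume,
    spec: ThresholdSpec,
    graft_material: str | None = None,
) -> LabelVolume:
    """Classify each voxel as background, bone or graft by gray thresholds.

    Deterministic and idempotent for a fixed spec. In auto mode the derived
    cut points ``(t_bone, t_graft)`` are logged; bone is the middle gray
    class and graft the brightest.
    """
    gray = np.asarray(volume.data)
    if not np.isfinite(gray).all():
        raise ValueError("volume contains non-finite gray values")

    if spec.auto:
        t_bone, t_graft = auto_thresholds(gray)
        log.info("auto thresholds: bone >= %.4g, graft >= %.4g", t_bone, t_graft)
        bone_lo, bone_hi = t_bone, t_graft
        graft_lo, graft_hi = t_graft, np.inf
    else:
        bone_lo, bone_hi = spec.bone_range
        graft_lo, graft_hi = spec.graft_range
        bone_hi = np.inf if bone_hi is None else bone_hi
        graft_hi = np.inf if graft_hi is None else graft_hi

    labels = np.full(gray.shape, BACKGROUND, dtype=np.int16)
    labels[(gray >= bone_lo) & (gray < bone_hi)] = BONE
    labels[(gray >= graft_lo) & (gray < graft_hi)] = GRAFT
    return LabelVolume(
        data=labels,
        spacing=volume.spacing,
        origin=volume.origin,
        graft_material=graft_material,
    )


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def particle_components(labels: LabelVolume, connectivity: int = 26) -> ParticleReport:
    """Connected components of the graft class as individual particles.

    Components use 26-connectivity by default (voxels touching at faces,
    edges or corners join one particle), configurable to 6 or 18. Particle
    volumes are voxel counts times spacing^3, sorted descending; diameters
    are sphere-equivalent. The sum of particle volumes equals the total
    graft volume exactly (in voxel counts).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}, got {connectivity}")
    graft = labels.labels == GRAFT
    lab, n = ndimage.label(graft, structure=_STRUCTURES[connectivity])
    if n == 0:
        return ParticleReport(0, np.empty(0), np.empty(0), connectivity)
    counts = np.bincount(lab.ravel())[1:]
    volumes = np.sort(counts)[::-1].astype(float) * labels.voxel_volume_mm3
    diameters = (6.0 * volumes / np.pi) ** (1.0 / 3.0)
    return ParticleReport(int(n), volumes, diameters, connectivity)
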