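"""Shared fixtures: phantoms are generated once per session and reused."""

import numpy as np
import pytest

from defectvol.io import LabelVolume, VoxelVolume
from defectvol.phantom import PhantomDefect, PhantomSpec, generate_phantom

#: study-condition phantom: 8 mm defect, per-region bone fills declining
#: toward the center (outer 0.8 -> inner 0.2), residual graft particles in
#: the inner/middle regions, half-resolution grid (0.046 mm).
RECOVERY_SPEC = PhantomSpec(
    plate_size_mm=(11.0, 11.0),
    thickness_mm=2.0,
    spacing=0.046,
    defects=(
        PhantomDefect(
            defect_id="d1",
            group="DBBMb",
            center_xy=(5.5, 5.5),
            radius=4.0,
            bone_fill=(0.2, 0.45, 0.8),
            graft_fill=(0.10, 0.05, 0.0),
        ),
    ),
    gray_means=(0.0, 100.0, 200.0),
    noise_sd=5.0,
    seed=17,
)


@pytest.fixture(scope="session")
def recovery_phantom():
    """(gray, labels, ground_truth) for the standard recovery phantom."""
    return generate_phantom(RECOVERY_SPEC)


@pytest.fixture(scope="session")
def coarse_phantom():
    """A small, fast phantom (0.1 mm spacing) for plumbing-level tests."""
    spec = PhantomSpec(
        plate_size_mm=(10.0, 10.0),
        spacing=0.1,
        defects=(
            PhantomDefect(
                defect_id="c1",
                group="PCM",
                center_xy=(5.0, 5.0),
                bone_fill=(0.3, 0.5, 0.7),
                graft_fill=(0.08, 0.04, 0.0),
            ),
        ),
        seed=3,
    )
    return generate_phantom(spec), spec


def make_plate_labels(shape=(30, 40, 40), spacing=0.1, z_plate=(1.0, 2.0)):
    """Hand-built label volume: a solid bone plate in an axial slab."""
    labels = np.zeros(shape, dtype=np.int16)
    zc = (np.arange(shape[0]) + 0.5) * spacing
    slab = (zc >= z_plate[0]) & (zc <= z_plate[1])
    labels[slab] = 1
    return LabelVolume(data=labels, spacing=spacing)


@pytest.fixture
def plate_labels():
    return make_plate_labels()
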