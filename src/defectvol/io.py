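"""Volume and label-map I/O with voxel-size metadata.

All volumes use a fixed axis convention: array index order ``(z, y, x)``
with *z* normal to the calvarial plate, isotropic voxel spacing in mm, and
world coordinates in mm. Region membership everywhere downstream is
evaluated at voxel centers: the center of voxel ``(k, j, i)`` lies at
``origin + (index + 0.5) * spacing`` along each axis.

Supported formats: NIfTI-1 (``.nii`` / ``.nii.gz``), single- or multi-page
TIFF stacks with a YAML sidecar carrying the spacing, and raw binary with a
mandatory YAML sidecar declaring shape, dtype and spacing. Spacing is never
defaulted silently: a file without spacing metadata is a hard error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml

__all__ = [
    "VoxelVolume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "write_results_csv",
    "write_report_json",
    "BACKGROUND",
    "BONE",
    "GRAFT",
]

# label class codes shared by the whole pipeline
BACKGROUND = 0
BONE = 1
GRAFT = 2

#: relative tolerance used to decide whether header spacings are isotropic
_ISO_RTOL = 1e-4


def _check_spacing(spacing) -> float:
    """Validate an isotropic scalar spacing (mm), rejecting anisotropy."""
    arr = np.atleast_1d(np.asarray(spacing, dtype=float))
    if arr.size > 1:
        if not np.allclose(arr, arr[0], rtol=_ISO_RTOL, atol=0.0):
            pretty = ", ".join(f"{v:.6g}" for v in arr)
            raise ValueError(
                f"anisotropic voxel spacing ({pretty}) mm is not "
                "supported; resample to an isotropic grid first"
            )
        arr = arr[:1]
    s = float(arr[0])
    if not math.isfinite(s) or s <= 0:
        raise ValueError(f"voxel spacing must be a positive finite number, got {s}")
    return s


@dataclass
class VoxelVolume:
    """A 3D scalar micro-CT volume on an isotropic grid.

    Attributes
    ----------
    data:
        3D array of gray values, index order ``(z, y, x)``.
    spacing:
        Isotropic voxel edge length in mm.
    origin:
        World coordinate (mm) of the corner of voxel ``(0, 0, 0)``, ordered
        ``(z, y, x)`` to match the array axes.
    """

    data: np.ndarray
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm3 (= spacing**3); the single source of
        truth used by every downstream volume computation."""
        return self.spacing**3

    def axis_centers(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along ``axis`` (0=z,1=y,2=x)."""
        n = self.data.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing


@dataclass
class LabelVolume(VoxelVolume):
    """Per-voxel material classes on the same grid as a :class:`VoxelVolume`.

    Codes: 0 = background / soft tissue, 1 = bone, 2 = graft. The graft class
    of a given defect may additionally carry a material tag (PCM, DBBMb,
    DBBMc) in :attr:`graft_material`; the tag is bookkeeping only and does
    not alter geometry or volumes.
    """

    graft_material: str | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label volume must be integer-typed, got {self.data.dtype}")

    @property
    def labels(self) -> np.ndarray:
        return self.data


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def _load_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {sc}: spacing cannot be defaulted; "
            "provide a YAML sidecar with at least 'spacing_mm'"
        )
    with open(sc) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict) or "spacing_mm" not in meta:
        raise ValueError(f"sidecar {sc} must declare 'spacing_mm'")
    return meta


def _infer_format(path: Path, format_hint: str | None) -> str:
    if format_hint is not None:
        return format_hint
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        return "nifti"
    if suffixes.endswith((".tif", ".tiff")):
        return "tiff"
    if suffixes.endswith(".raw"):
        return "raw"
    if path.is_dir():
        return "tiff"
    raise ValueError(f"cannot infer volume format of {path}; pass format_hint")


def _read_array(path: str | Path, format_hint: str | None):
    path = Path(path)
    fmt = _infer_format(path, format_hint)
    if fmt == "nifti":
        img = nib.load(str(path))
        spacing = _check_spacing(img.header.get_zooms()[:3])
        data = np.asanyarray(img.dataobj)
        origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
        meta: dict = {}
    elif fmt == "tiff":
        if path.is_dir():
            slices = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
            if not slices:
                raise FileNotFoundError(f"no .tif/.tiff slices found in {path}")
            data = np.stack([tifffile.imread(str(p)) for p in slices], axis=0)
            meta = _load_sidecar(path / "stack")
        else:
            data = tifffile.imread(str(path))
            if data.ndim == 2:
                data = data[None]
            meta = _load_sidecar(path)
        spacing = _check_spacing(meta["spacing_mm"])
        origin = tuple(float(v) for v in meta.get("origin_mm", (0.0, 0.0, 0.0)))
    elif fmt == "raw":
        meta = _load_sidecar(path)
        for key in ("shape", "dtype"):
            if key not in meta:
                raise ValueError(f"raw sidecar for {path} must declare '{key}'")
        shape = tuple(int(v) for v in meta["shape"])
        data = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(shape)
        spacing = _check_spacing(meta["spacing_mm"])
        origin = tuple(float(v) for v in meta.get("origin_mm", (0.0, 0.0, 0.0)))
    else:
        raise ValueError(f"unknown format hint {fmt!r}")
    return data, spacing, origin, meta


def read_volume(path: str | Path, format_hint: str | None = None) -> VoxelVolume:
    """Read a 3D grayscale volume with spacing metadata.

    Parameters
    ----------
    path:
        NIfTI file, (multipage) TIFF file, directory of per-slice TIFFs, or
        raw binary file. TIFF and raw inputs require a YAML sidecar
        ``<file>.yaml`` (for a slice directory: ``stack.yaml``) with keys
        ``spacing_mm`` and, for raw, ``shape`` and ``dtype``.
    format_hint:
        One of ``"nifti"``, ``"tiff"``, ``"raw"``; inferred from the file
        suffix when omitted.
    """
    data, spacing, origin, _ = _read_array(path, format_hint)
    return VoxelVolume(data=data, spacing=spacing, origin=origin)


def read_labels(path: str | Path, format_hint: str | None = None) -> LabelVolume:
    """Read a label volume (integer classes) with spacing metadata."""
    data, spacing, origin, meta = _read_array(path, format_hint)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.array_equal(data, np.round(data)):
            raise ValueError(f"label file {path} contains non-integer values")
        data = data.astype(np.int16)
    return LabelVolume(
        data=data,
        spacing=spacing,
        origin=origin,
        graft_material=meta.get("graft_material"),
    )


def _write_array(vol: VoxelVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = _infer_format(path, None)
    if fmt == "nifti":
        affine = np.diag([vol.spacing] * 3 + [1.0]).astype(float)
        affine[:3, 3] = vol.origin[::-1]
        img = nib.Nifti1Image(vol.data, affine)
        img.header.set_zooms((vol.spacing,) * 3)
        nib.save(img, str(path))
    elif fmt == "tiff":
        tifffile.imwrite(str(path), vol.data)
        meta = {"spacing_mm": vol.spacing, "origin_mm": list(vol.origin),
                "shape": list(vol.data.shape), "dtype": str(vol.data.dtype)}
        if getattr(vol, "graft_material", None):
            meta["graft_material"] = vol.graft_material
        with open(_sidecar_path(path), "w") as fh:
            yaml.safe_dump(meta, fh)
    elif fmt == "raw":
        vol.data.tofile(path)
        meta = {"spacing_mm": vol.spacing, "origin_mm": list(vol.origin),
                "shape": list(vol.data.shape), "dtype": str(vol.data.dtype)}
        if getattr(vol, "graft_material", None):
            meta["graft_material"] = vol.graft_material
        with open(_sidecar_path(path), "w") as fh:
            yaml.safe_dump(meta, fh)
    else:  # pragma: no cover - _infer_format already raises
        raise ValueError(fmt)
    return path


def write_volume(vol: VoxelVolume, path: str | Path) -> Path:
    """Write a grayscale volume; format chosen from the file suffix."""
    return _write_array(vol, path)


def write_labels(labels: LabelVolume, path: str | Path) -> Path:
    """Write a label volume losslessly (round-trips bit-exactly)."""
    return _write_array(labels, path)


# ---------------------------------------------------------------------------
# tabular results
# ---------------------------------------------------------------------------


def write_results_csv(df, path: str | Path) -> Path:
    """Write a results table with stable row ordering (deterministic bytes)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.6f")
    return path


def write_report_json(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
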