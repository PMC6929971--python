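"""Reading and writing 3D attenuation volumes and binary masks.

Supported containers: NIfTI-1 (``.nii``/``.nii.gz``), multi-page TIFF with a
JSON sidecar carrying the voxel size, and MetaImage (``.mhd``/``.mha``).
Internally every grid is a ``numpy`` array in ``(z, y, x)`` axis order with
0-based indexing, and all physical quantities derive from a single isotropic
voxel size in micrometres.  Anisotropic volumes are rejected rather than
resampled: every distance and volume computation downstream assumes one
isotropic spacing.

Attenuation values are carried in scanner-native (arbitrary) units; the
calibration stage makes results unit-free, so the unit label is opaque.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import tifffile

from .errors import (
    AlignmentError,
    AnisotropyError,
    DimensionalityError,
    MetadataError,
    VolumeFormatError,
)

__all__ = [
    "VolumeMetadata",
    "AttenuationVolume",
    "TumorMask",
    "read_volume",
    "write_volume",
    "read_mask",
]

#: relative tolerance used when deciding whether a spacing triple is isotropic
_ISO_RTOL = 1e-4


@dataclass(frozen=True)
class VolumeMetadata:
    """Geometry metadata for a reconstructed volume.

    Parameters
    ----------
    voxel_size:
        Isotropic voxel edge length in micrometres (µm).
    dims:
        Grid dimensions as ``(z, y, x)`` voxel counts.
    attenuation_units:
        Free-text label for the attenuation scale (scanner-native or HU).
    origin:
        Optional physical origin in mm; carried through, never interpreted.
    """

    voxel_size: float
    dims: tuple[int, int, int]
    attenuation_units: str = "arb"
    origin: tuple[float, float, float] | None = None

    def __post_init__(self):
        if not np.isfinite(self.voxel_size) or self.voxel_size <= 0:
            raise MetadataError(f"voxel_size must be > 0, got {self.voxel_size!r}")
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise MetadataError(f"dims must be three counts >= 1, got {self.dims!r}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size * 1e-3

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm³."""
        return self.voxel_size_mm**3

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL ( = cm³ ); voxel_size µm → cm is 1e-4."""
        return (self.voxel_size * 1e-4) ** 3


@dataclass
class AttenuationVolume:
    """A reconstructed 3D scalar attenuation grid plus its geometry."""

    values: np.ndarray
    meta: VolumeMetadata

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D grid, got {self.values.ndim}D payload"
            )
        if self.values.shape != self.meta.dims:
            raise AlignmentError(
                f"grid shape {self.values.shape} != metadata dims {self.meta.dims}"
            )
        if not np.isfinite(self.values).all():
            raise MetadataError("attenuation grid contains non-finite values")


@dataclass
class TumorMask:
    """Binary tumor region on the same grid as its companion volume."""

    values: np.ndarray
    meta: VolumeMetadata

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D mask, got {self.values.ndim}D payload"
            )
        if self.values.shape != self.meta.dims:
            raise AlignmentError(
                f"mask shape {self.values.shape} != metadata dims {self.meta.dims}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.meta.voxel_volume_mm3


# ---------------------------------------------------------------------------
# format detection


def _detect_format(path: Path, format_hint: str | None) -> str:
    if format_hint:
        hint = format_hint.lower()
        if hint in ("nifti", "nii"):
            return "nifti"
        if hint in ("tiff", "tif"):
            return "tiff"
        if hint in ("mhd", "mha", "metaimage"):
            return "metaimage"
        raise VolumeFormatError(f"unknown format hint {format_hint!r}")
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff"
    if name.endswith((".mhd", ".mha")):
        return "metaimage"
    raise VolumeFormatError(f"unsupported volume extension: {path.name!r}")


def _check_isotropic(spacing_um: np.ndarray, path: Path) -> float:
    spacing_um = np.asarray(spacing_um, dtype=float)
    if not np.allclose(spacing_um, spacing_um[0], rtol=_ISO_RTOL, atol=0.0):
        raise AnisotropyError(
            f"{path.name}: anisotropic voxel spacing {tuple(spacing_um)} µm; "
            "the pipeline requires isotropic resolution"
        )
    return float(spacing_um[0])


def _require_3d(data: np.ndarray, path: Path) -> np.ndarray:
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path.name}: expected a 3D volume, got {data.ndim}D payload"
        )
    return data


# ---------------------------------------------------------------------------
# readers

_NIFTI_UNIT_TO_UM = {"micron": 1.0, "mm": 1000.0, "meter": 1e6, "unknown": 1000.0}


def _read_nifti(path: Path) -> tuple[np.ndarray, float, str]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read NIfTI {path}: {exc}") from exc
    data = _require_3d(np.asanyarray(img.dataobj), path)
    hdr = img.header
    space_unit = hdr.get_xyzt_units()[0]
    scale = _NIFTI_UNIT_TO_UM.get(space_unit, 1000.0)
    # Prefer the (float64) affine over float32 pixdim for full precision.
    if img.affine is not None:
        spacing = np.sqrt((img.affine[:3, :3] ** 2).sum(axis=0))
    else:
        spacing = np.asarray(hdr.get_zooms()[:3], dtype=float)
    voxel_um = _check_isotropic(spacing * scale, path)
    units = hdr["descrip"].item().decode("ascii", "ignore").strip() or "arb"
    # NIfTI stores (x, y, z); internal convention is (z, y, x)
    return data.T, voxel_um, units


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _read_tiff(path: Path, voxel_size_um: float | None) -> tuple[np.ndarray, float, str]:
    try:
        data = tifffile.imread(str(path))
    except Exception as exc:
        raise VolumeFormatError(f"cannot read TIFF {path}: {exc}") from exc
    data = _require_3d(np.asarray(data), path)
    units = "arb"
    if voxel_size_um is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise MetadataError(
                f"{path.name}: TIFF carries no 3D spacing; supply voxel_size_um or a "
                f"sidecar {sidecar.name} with key 'voxel_size_um'"
            )
        meta = json.loads(sidecar.read_text())
        if "voxel_size_um" not in meta:
            raise MetadataError(f"{sidecar.name}: missing required key 'voxel_size_um'")
        voxel_size_um = float(meta["voxel_size_um"])
        units = str(meta.get("attenuation_units", "arb"))
    return data, float(voxel_size_um), units


def _read_metaimage(path: Path) -> tuple[np.ndarray, float, str]:
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:
        raise VolumeFormatError(f"cannot read MetaImage {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"{path.name}: expected a 3D volume, got {img.GetDimension()}D payload"
        )
    data = sitk.GetArrayFromImage(img)  # already (z, y, x)
    spacing_mm = np.asarray(img.GetSpacing(), dtype=float)  # (x, y, z), mm
    voxel_um = _check_isotropic(spacing_mm * 1000.0, path)
    return data, voxel_um, "arb"


def read_volume(
    path: str | os.PathLike,
    format_hint: str | None = None,
    voxel_size_um: float | None = None,
) -> AttenuationVolume:
    """Read a 3D attenuation volume from NIfTI, TIFF, or MetaImage.

    Parameters
    ----------
    path:
        Input file.  Format is inferred from the extension unless
        ``format_hint`` is one of ``"nifti"``, ``"tiff"``, ``"metaimage"``.
    voxel_size_um:
        Isotropic voxel size override; required for TIFF stacks that have no
        JSON sidecar (TIFF has no reliable 3D spacing of its own).

    Returns
    -------
    AttenuationVolume
        Grid in ``(z, y, x)`` order with populated metadata.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    fmt = _detect_format(path, format_hint)
    if fmt == "nifti":
        data, voxel_um, units = _read_nifti(path)
    elif fmt == "tiff":
        data, voxel_um, units = _read_tiff(path, voxel_size_um)
    else:
        data, voxel_um, units = _read_metaimage(path)
    if voxel_size_um is not None:
        voxel_um = float(voxel_size_um)
    meta = VolumeMetadata(voxel_size=voxel_um, dims=data.shape, attenuation_units=units)
    return AttenuationVolume(values=data, meta=meta)


# ---------------------------------------------------------------------------
# writers


def _check_writable_dir(path: Path):
    parent = path.resolve().parent
    if not parent.is_dir():
        raise OSError(f"parent directory does not exist: {parent}")
    if not os.access(parent, os.W_OK):
        raise OSError(f"parent directory not writable: {parent}")


def write_volume(volume: AttenuationVolume, path: str | os.PathLike) -> None:
    """Write a volume so that :func:`read_volume` round-trips it bit-exact.

    The container is chosen from the extension.  Values are written in the
    array's own dtype; the voxel size survives to ≤1e-6 µm (NIfTI spacing is
    stored in micron units in the float64 affine, MetaImage spacing as text,
    TIFF spacing in the JSON sidecar).
    """
    path = Path(path)
    fmt = _detect_format(path, None)
    _check_writable_dir(path)
    data = np.ascontiguousarray(volume.values)
    vs = volume.meta.voxel_size
    if fmt == "nifti":
        affine = np.diag([vs, vs, vs, 1.0])
        img = nib.Nifti1Image(data.T, affine)
        img.header.set_xyzt_units(xyz="micron")
        img.header["descrip"] = volume.meta.attenuation_units.encode("ascii", "ignore")[:79]
        nib.save(img, str(path))
    elif fmt == "tiff":
        tifffile.imwrite(str(path), data, photometric="minisblack")
        sidecar = {
            "voxel_size_um": vs,
            "attenuation_units": volume.meta.attenuation_units,
        }
        _sidecar_path(path).write_text(json.dumps(sidecar))
    else:
        img = sitk.GetImageFromArray(data)
        img.SetSpacing((vs * 1e-3,) * 3)
        sitk.WriteImage(img, str(path))


def read_mask(path: str | os.PathLike, reference_meta: VolumeMetadata) -> TumorMask:
    """Read a binary mask and check it against a reference geometry.

    Any nonzero voxel counts as foreground.  An all-zero mask is accepted
    here (validation is deferred to the analysis operations, which require a
    non-empty region).
    """
    vol = read_volume(path, voxel_size_um=reference_meta.voxel_size)
    if vol.values.shape != reference_meta.dims:
        raise AlignmentError(
            f"mask shape {vol.values.shape} does not match reference dims "
            f"{reference_meta.dims}"
        )
    return TumorMask(values=vol.values != 0, meta=reference_meta)
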