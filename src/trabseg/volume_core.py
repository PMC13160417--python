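"""Volume/mask data model, NIfTI/MetaImage I/O, density calibration, mask resampling.

Conventions
-----------
* Axis order is ``(x, y, z)`` with ``z`` the axial (slice) direction; voxel
  indices are 0-based and the physical position of voxel ``i`` is
  ``origin + i * spacing``.
* Only isotropic spacing is supported (axes must agree within 1e-4 mm).
* Density volumes carry a declared intensity unit: ``mgHA_cm3`` (hydroxyapatite
  equivalent density), ``per_mille`` (range-normalized 0–1000, the scale used
  after Laplace–Hamming filtering), or ``raw`` (uncalibrated scanner values).
* Binary masks are stored on disk as unsigned 8-bit; any nonzero voxel read
  from a third-party mask is normalized to 1.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import SimpleITK as sitk

__all__ = [
    "VoxelGrid",
    "DensityVolume",
    "BinaryVolume",
    "CalibrationLine",
    "read_volume",
    "read_mask",
    "write_volume",
    "calibrate_density",
    "resample_mask_nearest",
]

#: intensity units a DensityVolume may declare
UNITS = ("mgHA_cm3", "per_mille", "raw")

_ISO_TOL = 1e-4  # mm; max spread between axis spacings considered isotropic


@dataclass(frozen=True)
class VoxelGrid:
    """Regular isotropic 3D voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        ``(nx, ny, nz)`` voxel counts, each >= 1.
    spacing : float
        Isotropic voxel edge length in mm.
    origin : tuple of float
        Physical position (mm) of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if not (self.spacing > 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", float(self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz


@dataclass
class DensityVolume:
    """3D scalar volume with an isotropic grid and a declared intensity unit."""

    grid: VoxelGrid
    values: np.ndarray
    unit: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if self.unit == "per_mille":
            lo, hi = float(self.values.min()), float(self.values.max())
            if lo < -1e-9 or hi > 1000 + 1e-9:
                raise ValueError(
                    f"per_mille values must lie in [0, 1000], got [{lo}, {hi}]"
                )

    @property
    def spacing(self) -> float:
        return self.grid.spacing

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "DensityVolume":
        """New volume on the same grid with replaced values (and optionally unit)."""
        return DensityVolume(self.grid, values, self.unit if unit is None else unit)


@dataclass
class BinaryVolume:
    """3D 0/1 mask on an isotropic grid (segmentations and VOIs)."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={arr.ndim}")
        if tuple(arr.shape) != self.grid.shape:
            raise ValueError(f"mask shape {arr.shape} != grid shape {self.grid.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be 0/1, found {uniq[:10]}")
        self.values = arr.astype(np.uint8)

    @property
    def spacing(self) -> float:
        return self.grid.spacing

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.values.sum())

    def same_grid(self, other: Union["BinaryVolume", DensityVolume]) -> bool:
        return self.grid == other.grid


@dataclass(frozen=True)
class CalibrationLine:
    """Linear density calibration: density = slope * raw + intercept (mg HA/cm3)."""

    slope: float
    intercept: float

    def __post_init__(self):
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")


def _grid_from_sitk(img: sitk.Image) -> VoxelGrid:
    sp = img.GetSpacing()
    if max(sp) - min(sp) > _ISO_TOL:
        raise ValueError(
            f"anisotropic spacing not supported: axis spacings {tuple(sp)} mm "
            f"differ by more than {_ISO_TOL} mm"
        )
    return VoxelGrid(tuple(img.GetSize()), float(sp[0]), tuple(img.GetOrigin()))


def _to_sitk(grid: VoxelGrid, values: np.ndarray) -> sitk.Image:
    # numpy (x, y, z) -> sitk expects (z, y, x) arrays
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing((grid.spacing,) * 3)
    img.SetOrigin(grid.origin)
    return img


def _from_sitk(img: sitk.Image) -> tuple[VoxelGrid, np.ndarray]:
    grid = _grid_from_sitk(img)
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return grid, arr


def read_volume(path: str | os.PathLike, unit: str = "raw") -> DensityVolume:
    """Read a 3D scalar volume from NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd).

    Spacing and origin come from the file header. The intensity unit is not
    stored by these containers, so it defaults to ``raw`` unless the caller
    declares otherwise (e.g. ``unit="mgHA_cm3"`` for pre-calibrated data).

    Raises
    ------
    ValueError
        If the file holds non-3D data or anisotropic spacing.
    """
    img = sitk.ReadImage(os.fspath(path))
    if img.GetDimension() != 3:
        raise ValueError(f"non-3D data: {path} has dimension {img.GetDimension()}")
    grid, arr = _from_sitk(img)
    return DensityVolume(grid, arr.astype(np.float64, copy=False), unit)


def read_mask(path: str | os.PathLike) -> BinaryVolume:
    """Read a binary mask; any nonzero voxel is normalized to 1."""
    img = sitk.ReadImage(os.fspath(path))
    if img.GetDimension() != 3:
        raise ValueError(f"non-3D data: {path} has dimension {img.GetDimension()}")
    grid, arr = _from_sitk(img)
    return BinaryVolume(grid, (arr != 0).astype(np.uint8))


def write_volume(vol: DensityVolume | BinaryVolume, path: str | os.PathLike) -> None:
    """Write a volume or mask to NIfTI/MetaImage (format chosen by extension).

    Masks are written as unsigned 8-bit 0/1. Density volumes keep their
    array dtype (integer data round-trips bit-exactly; floats as float64).
    """
    path = os.fspath(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    if isinstance(vol, BinaryVolume):
        values = vol.values.astype(np.uint8)
    else:
        values = vol.values
        if np.issubdtype(values.dtype, np.floating):
            values = values.astype(np.float64, copy=False)
    sitk.WriteImage(_to_sitk(vol.grid, values), path)


def calibrate_density(vol: DensityVolume, cal: CalibrationLine) -> DensityVolume:
    """Convert raw scanner intensities to mg HA/cm3 with a linear map.

    ``out = slope * raw + intercept``. Calibrating an already-calibrated
    volume raises, to prevent accidental double application.
    """
    if vol.unit != "raw":
        raise ValueError(f"volume is already calibrated (unit={vol.unit!r})")
    out = cal.slope * vol.values.astype(np.float64) + cal.intercept
    return DensityVolume(vol.grid, out, "mgHA_cm3")


def resample_mask_nearest(mask: BinaryVolume, target: VoxelGrid) -> BinaryVolume:
    """Resample a mask onto ``target`` by nearest-neighbor lookup.

    The transform between physical spaces is the identity: each target voxel
    takes the value of the input voxel whose center is nearest to the target
    voxel center. Used to carry gold-standard masks and VOIs between the
    fine (micro-CT) and coarse (HR-pQCT) grids.
    """
    if target.n_voxels == 0:
        raise ValueError("empty target grid")
    img = _to_sitk(mask.grid, mask.values)
    ref = sitk.Image(target.shape, sitk.sitkUInt8)
    ref.SetSpacing((target.spacing,) * 3)
    ref.SetOrigin(target.origin)
    out = sitk.Resample(
        img, ref, sitk.Transform(), sitk.sitkNearestNeighbor, 0, sitk.sitkUInt8
    )
    _, arr = _from_sitk(out)
    return BinaryVolume(target, (arr != 0).astype(np.uint8))
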