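"""Synthetic trabecular-bone phantoms: paired fine ("micro-CT gold") and
degraded coarse ("HR-pQCT-like") volumes with VOIs and analytic truth.

The generator builds an analytic trabecular geometry on a fine isotropic
grid (default 0.02 mm, the micro-CT scale):

* ``plate_stack`` — parallel bone slabs of thickness t separated by gaps g
  along z; truth Tb.Th = t, Tb.Sp = g, BV/TV = t / (t + g).
* ``rod_lattice`` — three orthogonal families of cylinders (radius r,
  pitch p); truth Tb.Th = 2 r.
* ``gyroid`` — a triply periodic minimal-surface sheet (robustness cases
  only; no analytic truth claimed).

Bone voxels get a mineralized density (default 700 mg HA/cm3) and the
background a soft-tissue density (default 50 mg HA/cm3). The degradation
chain emulating HR-pQCT acquisition is: multiplicative smooth bias field
(three low-frequency cosine modes with seeded random phases, emulating
local variations in mineralization), Gaussian point-spread blur,
box-average downsampling to the coarse grid (default 0.0607 mm, a
partial-volume model of detector binning), and additive Gaussian noise.
All randomness flows from the PhantomSpec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .stack_shift import RigidTransform2D, StackLayout, apply_inplane_transform
from .volume_core import BinaryVolume, DensityVolume, VoxelGrid, resample_mask_nearest

__all__ = ["PhantomSpec", "PhantomCase", "generate_phantom", "degrade", "inject_stack_shift"]


@dataclass(frozen=True)
class PhantomSpec:
    """Synthetic phantom parameters.

    ``feature_size`` is the plate thickness (plate_stack), rod thickness
    i.e. cylinder diameter (rod_lattice), or wall-level parameter (gyroid),
    in mm.
    ``gap_size``/``pitch`` control spacing between features. Defaults target
    a realistic trabecular scale (Tb.Th ~ 0.2 mm, BV/TV ~ 0.25).
    """

    geometry: str = "plate_stack"  # 'plate_stack' | 'rod_lattice' | 'gyroid'
    feature_size: float = 0.2
    gap_size: float = 0.6  # plate gap (mm); ignored for rods/gyroid
    pitch: float = 0.8  # rod lattice / gyroid period (mm)
    extent_mm: float = 2.4  # cubic physical extent of the phantom
    spacing_fine: float = 0.02
    spacing_coarse: float = 0.0607
    bone_density: float = 700.0
    background_density: float = 50.0
    psf_sigma: float = 0.7  # PSF sigma in coarse voxels
    noise_sd: float = 30.0  # mg HA/cm3
    bias_amplitude: float = 0.2  # fraction of bone density
    seed: int = 0

    def __post_init__(self):
        if self.geometry not in ("plate_stack", "rod_lattice", "gyroid"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if not (0 < self.spacing_fine < self.spacing_coarse):
            raise ValueError("require 0 < spacing_fine < spacing_coarse")
        if self.feature_size < 2 * self.spacing_fine:
            raise ValueError(
                f"sub-resolution geometry: feature_size {self.feature_size} mm "
                f"< 2 x fine spacing {self.spacing_fine} mm"
            )
        if min(self.bone_density, self.background_density) < 0:
            raise ValueError("densities must be nonnegative")
        if not (0 <= self.bias_amplitude < 1):
            raise ValueError("bias_amplitude must lie in [0, 1)")
        if self.noise_sd < 0 or self.psf_sigma < 0:
            raise ValueError("noise_sd and psf_sigma must be nonnegative")


@dataclass
class PhantomCase:
    """Paired fine/coarse volumes with gold masks, VOIs, and analytic truth."""

    spec: PhantomSpec
    fine_volume: DensityVolume
    gold_mask: BinaryVolume  # fine grid
    coarse_volume: DensityVolume
    gold_mask_coarse: BinaryVolume  # gold resampled to the coarse grid
    voi_fine: BinaryVolume
    voi_coarse: BinaryVolume
    truth: dict  # analytic tb_th_mm / tb_sp_mm / bvtv where available


def _indicator(spec: PhantomSpec, grid: VoxelGrid) -> np.ndarray:
    """Analytic bone indicator sampled at voxel centers."""
    nx, ny, nz = grid.shape
    sp = grid.spacing
    # voxel-center coordinates: position of voxel i is origin + i * sp
    x = np.arange(nx) * sp
    y = np.arange(ny) * sp
    z = np.arange(nz) * sp

    if spec.geometry == "plate_stack":
        period = spec.feature_size + spec.gap_size
        zz = np.mod(z, period)
        plate = zz < spec.feature_size
        return np.broadcast_to(plate[None, None, :], grid.shape).copy()

    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    if spec.geometry == "rod_lattice":
        p = spec.pitch
        half = p / 2.0

        def axis_dist2(u, v):
            du = np.mod(u, p) - half
            dv = np.mod(v, p) - half
            return du * du + dv * dv

        r2 = (spec.feature_size / 2.0) ** 2  # feature_size = rod thickness (2r)
        rods = (
            (axis_dist2(Y, Z) <= r2)
            | (axis_dist2(X, Z) <= r2)
            | (axis_dist2(X, Y) <= r2)
        )
        return rods

    # gyroid sheet of wall half-thickness ~ feature_size/2
    k = 2.0 * np.pi / spec.pitch
    g = (
        np.sin(k * X) * np.cos(k * Y)
        + np.sin(k * Y) * np.cos(k * Z)
        + np.sin(k * Z) * np.cos(k * X)
    )
    # |g| < level: near the zero surface |grad g| ~ k, so a wall of
    # half-thickness feature_size/2 corresponds to level ~ k * feature_size/2
    level = 0.5 * spec.feature_size * k
    return np.abs(g) < level


def _central_box_voi(grid: VoxelGrid, margin_mm: float) -> BinaryVolume:
    m = max(1, int(round(margin_mm / grid.spacing)))
    arr = np.zeros(grid.shape, dtype=np.uint8)
    nx, ny, nz = grid.shape
    if 2 * m >= min(nx, ny, nz):
        raise ValueError("margin too large for grid")
    arr[m : nx - m, m : ny - m, m : nz - m] = 1
    return BinaryVolume(grid, arr)


def _bias_field(shape: tuple[int, int, int], extent: float, spec: PhantomSpec,
                rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + a * (sum of 3 low-frequency cosines)/3."""
    if spec.bias_amplitude == 0:
        return np.ones(shape)
    nx, ny, nz = shape
    coords = [np.linspace(0, 1, n, endpoint=False) for n in (nx, ny, nz)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    total = np.zeros(shape)
    for _ in range(3):
        kvec = rng.integers(1, 3, size=3)  # 1-2 cycles across the volume
        phase = rng.uniform(0, 2 * np.pi, size=3)
        total += np.cos(2 * np.pi * kvec[0] * X + phase[0]) * np.cos(
            2 * np.pi * kvec[1] * Y + phase[1]
        ) * np.cos(2 * np.pi * kvec[2] * Z + phase[2])
    return 1.0 + spec.bias_amplitude * total / 3.0


def _box_average(fine: np.ndarray, fine_sp: float, coarse_sp: float) -> np.ndarray:
    """Partial-volume downsampling: coarse voxel k = mean of the fine voxels
    whose centers fall in the coarse voxel cube centered at k * coarse_sp
    (shared voxel-center convention with the rest of the package)."""
    shape_c = tuple(int(np.floor(n * fine_sp / coarse_sp)) for n in fine.shape)
    if min(shape_c) < 1:
        raise ValueError("coarse grid would be empty")
    idx = []
    valid = []
    for d, n in enumerate(fine.shape):
        k = np.floor(np.arange(n) * fine_sp / coarse_sp + 0.5).astype(int)
        valid.append(k <= shape_c[d] - 1)
        idx.append(k)
    fx = idx[0][valid[0]]
    fy = idx[1][valid[1]]
    fz = idx[2][valid[2]]
    sub = fine[np.ix_(valid[0], valid[1], valid[2])]
    sums = np.zeros(shape_c)
    counts = np.zeros(shape_c)
    np.add.at(sums, (fx[:, None, None], fy[None, :, None], fz[None, None, :]), sub)
    np.add.at(
        counts, (fx[:, None, None], fy[None, :, None], fz[None, None, :]), 1.0
    )
    return sums / counts


def degrade(case_or_fine, spec: PhantomSpec) -> DensityVolume:
    """Degrade a fine phantom volume to an HR-pQCT-like coarse volume.

    Chain: multiplicative bias field -> Gaussian PSF blur -> box-average
    resample to the coarse spacing -> additive Gaussian noise. Deterministic
    given ``spec.seed``.
    """
    fine = case_or_fine.fine_volume if isinstance(case_or_fine, PhantomCase) else case_or_fine
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    x = fine.values.astype(np.float64)

    x = x * _bias_field(x.shape, spec.extent_mm, spec, rng)

    if spec.psf_sigma > 0:
        sigma_fine = spec.psf_sigma * spec.spacing_coarse / spec.spacing_fine
        x = ndimage.gaussian_filter(x, sigma_fine, mode="reflect")

    coarse = _box_average(x, spec.spacing_fine, spec.spacing_coarse)

    if spec.noise_sd > 0:
        coarse = coarse + rng.normal(0.0, spec.noise_sd, size=coarse.shape)

    grid = VoxelGrid(coarse.shape, spec.spacing_coarse, fine.grid.origin)
    return DensityVolume(grid, coarse, "mgHA_cm3")


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Build a phantom case: fine gold volume + degraded coarse volume + VOIs."""
    n_fine = int(round(spec.extent_mm / spec.spacing_fine))
    grid_f = VoxelGrid((n_fine, n_fine, n_fine), spec.spacing_fine)

    ind = _indicator(spec, grid_f)
    gold = BinaryVolume(grid_f, ind.astype(np.uint8))
    fine_vals = np.where(ind, spec.bone_density, spec.background_density).astype(
        np.float64
    )
    fine = DensityVolume(grid_f, fine_vals, "mgHA_cm3")

    coarse = degrade(fine, spec)
    gold_coarse = resample_mask_nearest(gold, coarse.grid)

    # VOI: central box, eroded ~3 coarse voxels from the bounding region
    margin = 3.0 * spec.spacing_coarse
    voi_fine = _central_box_voi(grid_f, margin)
    voi_coarse = _central_box_voi(coarse.grid, margin)

    truth: dict = {}
    if spec.geometry == "plate_stack":
        t, g = spec.feature_size, spec.gap_size
        truth = {"tb_th_mm": t, "tb_sp_mm": g, "bvtv": t / (t + g)}
    elif spec.geometry == "rod_lattice":
        truth = {"tb_th_mm": spec.feature_size}

    return PhantomCase(
        spec=spec,
        fine_volume=fine,
        gold_mask=gold,
        coarse_volume=coarse,
        gold_mask_coarse=gold_coarse,
        voi_fine=voi_fine,
        voi_coarse=voi_coarse,
        truth=truth,
    )


def inject_stack_shift(
    vol: DensityVolume, layout: StackLayout, shifts: list[RigidTransform2D]
) -> DensityVolume:
    """Apply per-stack in-plane rigid transforms (synthesizes the artifact)."""
    if len(shifts) != layout.n_stacks:
        raise ValueError(
            f"need one transform per stack: got {len(shifts)} for {layout.n_stacks}"
        )
    layout.check(vol.grid.shape[2])
    out = vol.values.astype(np.float64).copy()
    for k, t in enumerate(shifts):
        if t == RigidTransform2D():
            continue
        lo, hi = layout.z_range(k)
        apply_inplane_transform(out, lo, hi, t, vol.grid.spacing)
    return vol.with_values(out)
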