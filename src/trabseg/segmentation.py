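"""Bone segmentation methods for HR-pQCT-class volumes.

Four pathways are provided:

* ``standard`` — Gaussian smoothing (sigma 0.8, support 1.0) followed by a
  fixed global threshold of 320 mg HA/cm3 (the conventional second-generation
  HR-pQCT trabecular pipeline).
* ``laplace_hamming`` — Laplace–Hamming filtering to the per-mille scale
  followed by a fixed global threshold of 475 per mille.
* ``adaptive`` — adaptive local thresholding (AT): after an optional
  prefilter, a voxel is bone iff its intensity reaches both a global lower
  threshold and a local threshold computed over a spherical neighborhood,
  T(v) = min(mean(N), (min(N) + max(N)) / 2), followed by removal of
  connected components below a minimum structure size. Defaults are the
  carpal-bone optimum: Laplace–Hamming prefilter, kernel radius 6 voxels,
  lower threshold 350 mg HA/cm3, minimum structure size 16 voxels.
* ``otsu`` — the micro-CT gold-standard pathway: Gaussian smoothing
  (sigma 2.0, support 1.0) and a scan-specific Otsu threshold.

All thresholds compare with ``>=``. Spherical neighborhoods are clipped at
the volume border (statistics use in-volume voxels only), so no artificial
intensities enter the min/max at bone-air boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .filters import (
    GaussianParams,
    LaplaceHammingParams,
    gaussian_filter,
    laplace_hamming_filter,
    otsu_threshold,
)
from .volume_core import BinaryVolume, DensityVolume

__all__ = [
    "ATParams",
    "MethodSpec",
    "global_threshold_segment",
    "local_threshold_map",
    "adaptive_local_threshold_segment",
    "remove_small_components",
    "segment",
    "spherical_footprint",
]


@dataclass(frozen=True)
class ATParams:
    """Adaptive-local-threshold parameters (defaults = carpal-bone optimum)."""

    kernel_radius: int = 6
    lower_threshold: float = 350.0
    min_structure_size: int = 16
    prefilter: str = "none"  # 'gaussian' | 'laplace_hamming' | 'none'
    gaussian: GaussianParams = field(default_factory=GaussianParams)
    laplace_hamming: LaplaceHammingParams = field(
        default_factory=lambda: LaplaceHammingParams(output_scale="input_range")
    )
    connectivity: int = 26

    def __post_init__(self):
        if self.kernel_radius < 1:
            raise ValueError(f"kernel_radius must be >= 1, got {self.kernel_radius}")
        if self.lower_threshold < 0:
            raise ValueError("lower_threshold must be nonnegative")
        if self.min_structure_size < 0:
            raise ValueError("min_structure_size must be nonnegative")
        if self.prefilter not in ("gaussian", "laplace_hamming", "none"):
            raise ValueError(f"unknown prefilter {self.prefilter!r}")


@dataclass(frozen=True)
class MethodSpec:
    """Segmentation method selector with per-method parameters."""

    method: str  # 'standard' | 'laplace_hamming' | 'adaptive' | 'otsu'
    threshold: float | None = None  # global threshold override (standard / LH)
    gaussian: GaussianParams | None = None
    laplace_hamming: LaplaceHammingParams | None = None
    at: ATParams = field(default_factory=ATParams)
    otsu_nbins: int = 128
    connectivity: int = 26

    def __post_init__(self):
        if self.method not in ("standard", "laplace_hamming", "adaptive", "otsu"):
            raise ValueError(f"unknown method {self.method!r}")


#: fixed global thresholds of the comparator methods
STANDARD_THRESHOLD_MGHA = 320.0
LAPLACE_HAMMING_THRESHOLD_PER_MILLE = 475.0


def spherical_footprint(radius: int) -> np.ndarray:
    """Boolean ball: voxel offsets with Euclidean norm <= radius."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    return (dx * dx + dy * dy + dz * dz) <= r * r


def global_threshold_segment(vol: DensityVolume, threshold: float) -> BinaryVolume:
    """Mask of voxels with intensity >= threshold (threshold in vol's unit)."""
    return BinaryVolume(vol.grid, (vol.values >= threshold).astype(np.uint8))


def local_threshold_map(vol: DensityVolume, kernel_radius: int) -> DensityVolume:
    """Per-voxel adaptive threshold over a spherical neighborhood.

    T(v) = min( mean(N(v)), (min(N(v)) + max(N(v))) / 2 ) where N(v) is the
    Euclidean ball of ``kernel_radius`` voxels around v, clipped at the
    volume border. Same unit as the input.
    """
    if kernel_radius < 1:
        raise ValueError(f"kernel_radius must be >= 1, got {kernel_radius}")
    fp = spherical_footprint(kernel_radius)
    x = vol.values.astype(np.float64)

    kernel = fp.astype(np.float64)
    sums = ndimage.convolve(x, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(np.ones_like(x), kernel, mode="constant", cval=0.0)
    mean = sums / counts

    # +/-inf padding so border neighborhoods are truly clipped
    nmin = ndimage.minimum_filter(x, footprint=fp, mode="constant", cval=np.inf)
    nmax = ndimage.maximum_filter(x, footprint=fp, mode="constant", cval=-np.inf)

    return vol.with_values(np.minimum(mean, 0.5 * (nmin + nmax)))


def remove_small_components(
    mask: BinaryVolume, min_size: int, connectivity: int = 26
) -> BinaryVolume:
    """Drop connected foreground components smaller than ``min_size`` voxels.

    Components are defined under 6-, 18-, or 26-connectivity (default 26,
    preserving thin oblique trabecular connections).
    """
    if min_size < 0:
        raise ValueError("min_size must be nonnegative")
    if connectivity not in (6, 18, 26):
        raise ValueError(f"connectivity must be 6, 18, or 26, got {connectivity}")
    if min_size <= 1:
        return BinaryVolume(mask.grid, mask.values.copy())
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    labels, n = ndimage.label(mask.values, structure=structure)
    if n == 0:
        return BinaryVolume(mask.grid, mask.values.copy())
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return BinaryVolume(mask.grid, keep[labels].astype(np.uint8))


def _apply_prefilter(vol: DensityVolume, p: ATParams) -> DensityVolume:
    if p.prefilter == "gaussian":
        return gaussian_filter(vol, p.gaussian)
    if p.prefilter == "laplace_hamming":
        return laplace_hamming_filter(vol, p.laplace_hamming)
    return vol


def adaptive_local_threshold_segment(vol: DensityVolume, p: ATParams) -> BinaryVolume:
    """AT segmentation: prefilter, dual local/global threshold, size filter.

    A voxel is bone iff its (prefiltered) intensity >= max(T(v), lower
    threshold); the local criterion can only remove voxels relative to the
    global threshold at the same lower bound.
    """
    filtered = _apply_prefilter(vol, p)
    tmap = local_threshold_map(filtered, p.kernel_radius)
    x = filtered.values
    fg = (x >= tmap.values) & (x >= p.lower_threshold)
    mask = BinaryVolume(vol.grid, fg.astype(np.uint8))
    return remove_small_components(mask, p.min_structure_size, p.connectivity)


def segment(vol: DensityVolume, spec: MethodSpec) -> BinaryVolume:
    """Dispatch to one of the four segmentation pathways."""
    if spec.method == "standard":
        g = spec.gaussian or GaussianParams(sigma=0.8, support=1.0)
        thr = STANDARD_THRESHOLD_MGHA if spec.threshold is None else spec.threshold
        return global_threshold_segment(gaussian_filter(vol, g), thr)
    if spec.method == "laplace_hamming":
        lh = spec.laplace_hamming or LaplaceHammingParams(output_scale="per_mille")
        thr = (
            LAPLACE_HAMMING_THRESHOLD_PER_MILLE
            if spec.threshold is None
            else spec.threshold
        )
        return global_threshold_segment(laplace_hamming_filter(vol, lh), thr)
    if spec.method == "adaptive":
        return adaptive_local_threshold_segment(vol, spec.at)
    # otsu: the micro-CT gold-standard pathway
    g = spec.gaussian or GaussianParams(sigma=2.0, support=1.0)
    smoothed = gaussian_filter(vol, g)
    thr = otsu_threshold(smoothed, nbins=spec.otsu_nbins)
    return global_threshold_segment(smoothed, thr)
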