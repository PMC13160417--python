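"""Pre-segmentation filters: truncated Gaussian, Laplace–Hamming, Otsu threshold.

The Gaussian follows the scanner convention of a small bounded kernel: the
``support`` parameter is the truncation half-width in voxels (support = 1.0
gives a 3x3x3 kernel), and the truncated kernel is renormalized to sum 1.

The Laplace–Hamming filter is an edge-enhancing frequency-domain filter:
a blend of the identity and a normalized Laplacian sharpening response,
multiplied by a separable Hamming-window low-pass,

    H(f) = [(1 - eps) + eps * Lhat(f)] * W(f)

where ``Lhat`` is the magnitude response of the discrete 3D Laplacian scaled
to peak 1 at Nyquist and ``W`` is the per-axis Hamming taper
``w(f) = 0.54 + 0.46 cos(pi f / fc)`` for normalized frequency ``f <= fc``
(0 beyond). The output is then affinely rescaled either to the per-mille
scale (min -> 0, max -> 1000) used for the fixed 475 per-mille threshold, or
back to the input range so that density-unit thresholds stay meaningful when
the filter serves as an adaptive-thresholding prefilter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_core import BinaryVolume, DensityVolume

__all__ = [
    "GaussianParams",
    "LaplaceHammingParams",
    "gaussian_filter",
    "laplace_hamming_filter",
    "otsu_threshold",
]


@dataclass(frozen=True)
class GaussianParams:
    """Gaussian smoothing: sigma and truncation half-width, both in voxels."""

    sigma: float = 0.8
    support: float = 1.0

    def __post_init__(self):
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not (self.support >= 1):
            raise ValueError(f"support must be >= 1 voxel, got {self.support}")


@dataclass(frozen=True)
class LaplaceHammingParams:
    """Laplace–Hamming filter parameters.

    epsilon : Laplacian blend weight in [0, 1] (0 = pure low-pass).
    cutoff : normalized Hamming cutoff frequency in (0, 1] (1 = Nyquist).
    output_scale : 'per_mille' (range-normalize to 0–1000) or 'input_range'
        (affinely restore the input min/max, preserving the unit).
    """

    epsilon: float = 0.45
    cutoff: float = 0.3
    output_scale: str = "per_mille"

    def __post_init__(self):
        if not (0 <= self.epsilon <= 1):
            raise ValueError(f"epsilon must be in [0, 1], got {self.epsilon}")
        if not (0 < self.cutoff <= 1):
            raise ValueError(f"cutoff must be in (0, 1], got {self.cutoff}")
        if self.output_scale not in ("per_mille", "input_range"):
            raise ValueError(f"unknown output_scale {self.output_scale!r}")


def gaussian_kernel_1d(sigma: float, support: float) -> np.ndarray:
    """Truncated, renormalized 1D Gaussian kernel (half-width ceil(support))."""
    hw = int(np.ceil(support))
    x = np.arange(-hw, hw + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_filter(vol: DensityVolume, p: GaussianParams) -> DensityVolume:
    """Separable truncated-Gaussian smoothing; unit and grid unchanged.

    Boundary handling is symmetric (reflect) padding, avoiding the edge
    darkening a zero pad would cause near bone/air borders.
    """
    k = gaussian_kernel_1d(p.sigma, p.support)
    out = vol.values.astype(np.float64)
    for axis in range(3):
        out = ndimage.convolve1d(out, k, axis=axis, mode="reflect")
    return vol.with_values(out)


def _lh_transfer(shape: tuple[int, ...], p: LaplaceHammingParams) -> np.ndarray:
    """Build the Laplace–Hamming transfer function on the FFT grid."""
    # normalized frequencies per axis, f in [0, 1] with 1 = Nyquist
    freqs = [np.abs(np.fft.fftfreq(n)) * 2.0 for n in shape]
    fx, fy, fz = np.meshgrid(*freqs, indexing="ij", sparse=True)

    # discrete Laplacian response sum_i (2 cos w_i - 2), magnitude peak 12
    lap = sum(2.0 * np.cos(np.pi * f) - 2.0 for f in (fx, fy, fz))
    lhat = np.abs(lap) / 12.0

    def hamming(f):
        w = 0.54 + 0.46 * np.cos(np.pi * f / p.cutoff)
        return np.where(f <= p.cutoff, w, 0.0)

    window = hamming(fx) * hamming(fy) * hamming(fz)
    return ((1.0 - p.epsilon) + p.epsilon * lhat) * window


def laplace_hamming_filter(vol: DensityVolume, p: LaplaceHammingParams) -> DensityVolume:
    """Apply the Laplace–Hamming filter and rescale per ``p.output_scale``."""
    x = vol.values.astype(np.float64)
    in_min, in_max = float(x.min()), float(x.max())

    if in_max == in_min:
        if p.output_scale == "per_mille":
            raise ValueError(
                "degenerate range: constant input cannot be per-mille normalized"
            )
        return vol.with_values(x.copy())

    y = np.fft.ifftn(np.fft.fftn(x) * _lh_transfer(x.shape, p)).real
    y_min, y_max = float(y.min()), float(y.max())
    if y_max == y_min:  # pragma: no cover - linear filter of non-constant input
        raise ValueError("degenerate filter output range")

    if p.output_scale == "per_mille":
        out = (y - y_min) * (1000.0 / (y_max - y_min))
        # clamp tiny float excursions so the per-mille invariant holds exactly
        out = np.clip(out, 0.0, 1000.0)
        return DensityVolume(vol.grid, out, "per_mille")
    out = in_min + (y - y_min) * ((in_max - in_min) / (y_max - y_min))
    return vol.with_values(out)


def otsu_threshold(
    vol: DensityVolume, mask: BinaryVolume | None = None, nbins: int = 128
) -> float:
    """Scan-specific global threshold by Otsu's method.

    Builds a histogram of ``nbins`` equal-width bins spanning [min, max] of
    the considered voxels (all voxels, or those inside ``mask``) and returns
    the bin *boundary* maximizing the between-class variance, in the
    volume's intensity unit. Ties take the lowest maximizing boundary.
    """
    if nbins < 2:
        raise ValueError(f"nbins must be >= 2, got {nbins}")
    values = vol.values if mask is None else vol.values[mask.values == 1]
    if values.size == 0:
        raise ValueError("no voxels to threshold (empty mask?)")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError("degenerate histogram: input is constant")

    counts, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    counts = counts.astype(np.float64)
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    # between-class variance at every boundary (split after bin k)
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    s0 = np.cumsum(counts * centers)[:-1]
    s1 = (counts * centers).sum() - s0
    valid = (w0 > 0) & (w1 > 0)
    var_b = np.full(nbins - 1, -np.inf)
    var_b[valid] = (
        w0[valid] * w1[valid] * (s0[valid] / w0[valid] - s1[valid] / w1[valid]) ** 2
    )
    k = int(np.argmax(var_b))
    return float(edges[k + 1])
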