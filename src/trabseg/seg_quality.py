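"""Spatial agreement metrics between predicted and gold-standard masks.

Conventions (fixed for determinism and oracle-checkability):

* The surface of a mask is the set of foreground voxels with at least one
  6-neighbor outside the foreground; the volume edge counts as outside.
* Distances are Euclidean, in mm, between voxel centers.
* With directed distance sets D_ab = {d(x, S_b) : x in S_a} and D_ba
  likewise: ASSD is the mean and HD95 the 95th percentile (linear
  interpolation between order statistics) of the pooled multiset
  D_ab ∪ D_ba; the mean Hausdorff distance is max(mean D_ab, mean D_ba).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_core import BinaryVolume

__all__ = ["QualityReport", "dice", "surface_extract", "surface_distance_report"]


@dataclass(frozen=True)
class QualityReport:
    """DSC and surface-distance metrics for one (predicted, gold) mask pair."""

    dsc: float
    hd_mean_mm: float
    hd95_mm: float
    assd_mm: float
    n_surface_a: int
    n_surface_b: int

    def as_dict(self) -> dict:
        return {
            "dsc": self.dsc,
            "hd_mean_mm": self.hd_mean_mm,
            "hd95_mm": self.hd95_mm,
            "assd_mm": self.assd_mm,
            "n_surface_a": self.n_surface_a,
            "n_surface_b": self.n_surface_b,
        }


def _check_same_grid(a: BinaryVolume, b: BinaryVolume) -> None:
    if a.grid != b.grid:
        raise ValueError("masks must share a grid")


def dice(a: BinaryVolume, b: BinaryVolume) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|)."""
    _check_same_grid(a, b)
    na, nb = a.count(), b.count()
    if na == 0 and nb == 0:
        raise ValueError("DSC undefined: both masks empty")
    inter = int(np.logical_and(a.values, b.values).sum())
    return 2.0 * inter / (na + nb)


def _surface_bool(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with a 6-neighbor outside (edges count as outside)."""
    fg = mask.astype(bool)
    interior = ndimage.binary_erosion(
        fg, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return fg & ~interior


def surface_extract(mask: BinaryVolume) -> np.ndarray:
    """Surface voxel indices as an (n, 3) integer array (lexicographic order)."""
    if mask.count() == 0:
        raise ValueError("empty mask has no surface")
    return np.argwhere(_surface_bool(mask.values))


def _percentile_linear(values: np.ndarray, q: float) -> float:
    return float(np.percentile(values, q, method="linear"))


def surface_distance_report(
    a: BinaryVolume, b: BinaryVolume, spacing: float | None = None
) -> QualityReport:
    """DSC plus mean-Hausdorff, HD95 and ASSD between two masks' surfaces."""
    _check_same_grid(a, b)
    if a.count() == 0 or b.count() == 0:
        raise ValueError("surface distances require both masks nonempty")
    sp = a.grid.spacing if spacing is None else float(spacing)

    surf_a = _surface_bool(a.values)
    surf_b = _surface_bool(b.values)
    # distance from every voxel to the nearest surface voxel of the other mask
    dist_to_b = ndimage.distance_transform_edt(~surf_b) * sp
    dist_to_a = ndimage.distance_transform_edt(~surf_a) * sp
    d_ab = dist_to_b[surf_a]
    d_ba = dist_to_a[surf_b]

    pooled = np.concatenate([d_ab, d_ba])
    return QualityReport(
        dsc=dice(a, b),
        hd_mean_mm=float(max(d_ab.mean(), d_ba.mean())),
        hd95_mm=_percentile_linear(pooled, 95.0),
        assd_mm=float(pooled.mean()),
        n_surface_a=int(surf_a.sum()),
        n_surface_b=int(surf_b.sum()),
    )
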