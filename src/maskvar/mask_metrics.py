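"""Mask discrepancy metrics.

Two masks on the same grid are compared with an element-wise difference
map (``+1`` where only the test mask covers a voxel, ``-1`` where only
the baseline does).  The voxel discrepancy ``V_d`` is the absolute sum of
the map scaled by the baseline ROI voxel count ``N_m`` and stated as a
percentage:

    V_d = 100 * sum(|d_map|) / N_m

The baseline is always an explicitly designated reference mask, so V_d is
not symmetric in its arguments unless the two ROI sizes happen to match.

Discrepant voxels fall into two qualitative types: whole-slice extensions
(a superior/inferior slice present in only one mask) and edge
disagreements along the region boundary within shared slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, ShapeError
from .rasterize import BinaryMask

__all__ = ["DifferenceMap", "difference_map", "voxel_discrepancy", "classify_discrepancy"]


@dataclass(frozen=True)
class DifferenceMap:
    """Element-wise mask difference (test − baseline) plus baseline size."""

    values: np.ndarray  # int8 over {-1, 0, +1}
    n_baseline: int

    def __post_init__(self):
        v = np.asarray(self.values)
        if not np.isin(v, (-1, 0, 1)).all():
            raise DataError("difference map values must be in {-1, 0, 1}")
        object.__setattr__(self, "values", v.astype(np.int8))

    @property
    def n_discrepant(self) -> int:
        return int(np.abs(self.values).sum())


def _check_same_grid(mask_a: BinaryMask, mask_n: BinaryMask) -> None:
    ga, gn = mask_a.geometry, mask_n.geometry
    if ga.dims != gn.dims or not (
        np.allclose(ga.origin, gn.origin)
        and np.allclose(ga.index_to_patient_matrix, gn.index_to_patient_matrix)
    ):
        raise ShapeError("masks are not on the same grid")


def difference_map(mask_a: BinaryMask, mask_n: BinaryMask) -> DifferenceMap:
    """Element-wise subtraction ``mask_a - mask_n`` on a shared grid.

    ``mask_n`` is the designated baseline whose ROI size becomes ``N_m``.
    """
    _check_same_grid(mask_a, mask_n)
    values = mask_a.voxels.astype(np.int8) - mask_n.voxels.astype(np.int8)
    return DifferenceMap(values=values, n_baseline=int(mask_n.voxels.sum()))


def voxel_discrepancy(dmap: DifferenceMap) -> float:
    """Percentage voxel discrepancy V_d = 100 * sum(|d_map|) / N_m."""
    if dmap.n_baseline <= 0:
        raise DataError("V_d undefined: baseline mask is empty (N_m = 0)")
    return 100.0 * dmap.n_discrepant / dmap.n_baseline


def classify_discrepancy(
    dmap: DifferenceMap, mask_a: BinaryMask, mask_n: BinaryMask
) -> dict[str, int]:
    """Split discrepant voxels into slice-extension vs edge counts.

    Nonzero voxels lying on slices occupied by exactly one of the two
    masks are *slice extensions* (the additional superior/inferior planes
    seen when one conversion adds a whole slice); all remaining nonzero
    voxels are *edge* disagreements.  The two counts sum to sum(|d_map|).
    """
    _check_same_grid(mask_a, mask_n)
    occ_a = mask_a.voxels.any(axis=(0, 1))
    occ_n = mask_n.voxels.any(axis=(0, 1))
    single = occ_a ^ occ_n
    per_slice = np.abs(dmap.values).sum(axis=(0, 1))
    slice_ext = int(per_slice[single].sum())
    return {"slice_extension": slice_ext, "edge": int(per_slice.sum()) - slice_ext}
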