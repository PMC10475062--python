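"""Polygon-to-binary-mask conversion.

Two strategies are provided:

* **centre** — a voxel belongs to the region iff its centre lies inside
  the closed polygon, decided by the crossing-number (even-odd) rule.
* **supersampled** — each voxel is subdivided into ``2**split`` sub-voxel
  centres per axis (a single split gives 8 sub-voxels per voxel in 3D);
  the voxel is included iff the percentage of sub-voxel centres inside
  the polygon meets an inclusion threshold.  Strict thresholds (e.g. 90%)
  erode the mask relative to the centre method; lenient ones (e.g. 10%)
  dilate it.

Edge handling: the crossing-number test uses the half-open edge rule — an
edge is counted iff exactly one endpoint is strictly above the ray — so a
ray through a vertex is never double-counted.  Points exactly on an edge
are classified by the same arithmetic with no epsilon.

Polygons sharing a slice are combined even-odd (XOR), so nested polygons
create holes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, DataError, ShapeError
from .geometry import ContourSet, ImageGeometry

__all__ = [
    "RasterStrategy",
    "BinaryMask",
    "point_in_polygon",
    "rasterize",
    "rasterize_centre",
    "rasterize_supersampled",
    "subvoxel_offsets_1d",
    "subvoxel_offsets_3d",
    "voxel_included",
    "min_interior_subvoxels",
    "write_mask_nifti",
    "read_mask_nifti",
]


@dataclass(frozen=True)
class RasterStrategy:
    """Parameters of one polygon-to-mask conversion strategy.

    ``split`` is the number of axis bisections: split ``s`` places
    ``2**s`` sub-voxel centres per axis.  ``threshold_pct`` is the minimum
    percentage of interior sub-voxel centres for voxel inclusion, compared
    inclusively (>=).  ``z_policy`` controls which slice's polygons a
    z-displaced sub-voxel centre is tested against: ``parent_slice`` (the
    polygons of its parent voxel's slice; the z-split is then inert) or
    ``nearest_plane``.
    """

    method: str = "centre"
    split: int = 1
    threshold_pct: float = 50.0
    z_policy: str = "parent_slice"

    def __post_init__(self):
        if self.method not in ("centre", "supersampled"):
            raise ConfigError(f"unknown raster method {self.method!r}")
        if self.method == "supersampled":
            if int(self.split) < 0:
                raise ConfigError("split must be non-negative")
            if not (0.0 < float(self.threshold_pct) <= 100.0):
                raise ConfigError("threshold_pct must be in (0, 100]")
        if self.z_policy not in ("parent_slice", "nearest_plane"):
            raise ConfigError(f"unknown z_policy {self.z_policy!r}")

    def label(self) -> str:
        if self.method == "centre":
            return "centre"
        return f"ss_split{self.split}_t{self.threshold_pct:g}"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "split": int(self.split),
            "threshold_pct": float(self.threshold_pct),
            "z_policy": self.z_policy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RasterStrategy":
        return cls(**d)


@dataclass(frozen=True)
class BinaryMask:
    """Boolean ROI mask on an image grid, with conversion provenance."""

    geometry: ImageGeometry
    voxels: np.ndarray
    strategy: RasterStrategy
    roi_name: str = ""

    def __post_init__(self):
        v = np.asarray(self.voxels, dtype=bool)
        if v.shape != self.geometry.dims:
            raise ShapeError(
                f"mask shape {v.shape} != geometry dims {self.geometry.dims}"
            )
        object.__setattr__(self, "voxels", v)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


# ---------------------------------------------------------------------------
# point-in-polygon (crossing number)


def _dedup(xy: np.ndarray) -> np.ndarray:
    keep = np.any(xy != np.roll(xy, 1, axis=0), axis=1)
    return xy[keep]


def _signed_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def point_in_polygon(points, polygon) -> np.ndarray | bool:
    """Even-odd (crossing number) membership test.

    Parameters
    ----------
    points:
        A single 2-vector or an (N, 2) array of in-plane coordinates.
    polygon:
        (M, 2) ordered vertex array, implicitly closed.

    Returns
    -------
    bool or (N,) bool array — true iff a horizontal ray from the point
    crosses the polygon boundary an odd number of times.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise DataError(f"polygon must be an (M>=3, 2) array, got {poly.shape}")
    dd = _dedup(poly)
    if dd.shape[0] < 3 or abs(_signed_area(dd)) == 0.0:
        raise DataError("degenerate polygon: zero area after de-duplication")

    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    px, py = pts[:, 0], pts[:, 1]

    inside = np.zeros(len(pts), dtype=bool)
    x1, y1 = poly[:, 0], poly[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        # half-open rule: edge counted iff exactly one endpoint strictly above
        straddles = (ey1 > py) != (ey2 > py)
        if not straddles.any():
            continue
        xint = ex1 + (py - ey1) * (ex2 - ex1) / (ey2 - ey1)
        inside ^= straddles & (px < xint)
    return bool(inside[0]) if single else inside


# ---------------------------------------------------------------------------
# sub-voxel lattices


def subvoxel_offsets_1d(split: int) -> np.ndarray:
    """Sub-voxel centre offsets along one axis, in voxel widths.

    ``split`` bisections give ``2**split`` centres placed symmetrically
    about the voxel centre: split 0 -> [0]; split 1 -> [-1/4, +1/4];
    split 2 -> [-3/8, -1/8, +1/8, +3/8]; ...
    """
    if split < 0:
        raise ConfigError("split must be non-negative")
    n = 2**split
    return (np.arange(n) + 0.5) / n - 0.5


def subvoxel_offsets_3d(split: int) -> np.ndarray:
    """(8**split, 3) array of 3D sub-voxel centre offsets (voxel widths)."""
    o = subvoxel_offsets_1d(split)
    return np.array(list(itertools.product(o, o, o)), dtype=float).reshape(-1, 3)


def voxel_included(n_interior: int, n_subvoxels: int, threshold_pct: float) -> bool:
    """Inclusion rule: interior percentage >= threshold (inclusive)."""
    return 100.0 * n_interior / n_subvoxels >= threshold_pct


def min_interior_subvoxels(threshold_pct: float, n_subvoxels: int) -> int:
    """Smallest interior sub-voxel count satisfying the inclusion rule.

    E.g. with a single 2D split (4 sub-voxels) and a 25% threshold, one
    interior sub-voxel suffices.
    """
    for k in range(n_subvoxels + 1):
        if voxel_included(k, n_subvoxels, threshold_pct):
            return k
    raise ConfigError(f"threshold {threshold_pct}% unsatisfiable")  # pragma: no cover


# ---------------------------------------------------------------------------
# rasterisation


def _polygons_by_slice(
    contours: ContourSet, geometry: ImageGeometry
) -> dict[int, list[np.ndarray]]:
    """Assign each polygon to a slice plane; vertices in (row, col) units.

    A polygon matches slice ``s`` when its continuous slice index is
    within half a slice spacing of ``s``.
    """
    by_slice: dict[int, list[np.ndarray]] = {}
    for poly in contours.polygons:
        idx = geometry.patient_to_voxel(poly.vertices)
        s_f = float(idx[:, 2].mean())
        s = int(round(s_f))
        if abs(s_f - s) > 0.5 + 1e-9 or not (0 <= s < geometry.dims[2]):
            raise DataError(
                f"polygon at z={poly.slice_z:g} mm matches no slice plane"
            )
        by_slice.setdefault(s, []).append(idx[:, :2])
    return by_slice


def _evenodd_inside(points_rc: np.ndarray, polys: list[np.ndarray]) -> np.ndarray:
    inside = np.zeros(len(points_rc), dtype=bool)
    for poly in polys:
        inside ^= point_in_polygon(points_rc, poly)
    return inside


def _candidate_box(polys: list[np.ndarray], dims) -> tuple[np.ndarray, np.ndarray]:
    """Integer (row, col) voxel centres near the polygons' bounding box."""
    allv = np.vstack(polys)
    r0 = max(0, int(np.floor(allv[:, 0].min())) - 1)
    r1 = min(dims[0] - 1, int(np.ceil(allv[:, 0].max())) + 1)
    c0 = max(0, int(np.floor(allv[:, 1].min())) - 1)
    c1 = min(dims[1] - 1, int(np.ceil(allv[:, 1].max())) + 1)
    rr, cc = np.meshgrid(
        np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij"
    )
    return rr.ravel(), cc.ravel()


def rasterize_centre(contours: ContourSet, geometry: ImageGeometry) -> BinaryMask:
    """Voxel-centre conversion: a voxel is in the region iff its centre is
    inside the (even-odd combined) polygons of its slice."""
    mask = np.zeros(geometry.dims, dtype=bool)
    for s, polys in _polygons_by_slice(contours, geometry).items():
        rr, cc = _candidate_box(polys, geometry.dims)
        pts = np.column_stack([rr, cc]).astype(float)
        inside = _evenodd_inside(pts, polys)
        mask[rr[inside], cc[inside], s] = True
    return BinaryMask(
        geometry=geometry,
        voxels=mask,
        strategy=RasterStrategy(method="centre"),
        roi_name=contours.roi_name,
    )


def rasterize_supersampled(
    contours: ContourSet, geometry: ImageGeometry, strategy: RasterStrategy
) -> BinaryMask:
    """Grid super-sampling conversion.

    Each voxel is subdivided into ``2**split`` sub-voxel centres per axis
    (8 sub-voxels per voxel in 3D at split 1) placed symmetrically about
    the voxel centre; the voxel is included iff the interior percentage
    of sub-voxel centres meets ``strategy.threshold_pct`` (inclusive).
    """
    if strategy.method != "supersampled":
        raise ConfigError("strategy.method must be 'supersampled'")
    split = int(strategy.split)
    by_slice = _polygons_by_slice(contours, geometry)
    mask = np.zeros(geometry.dims, dtype=bool)
    off = subvoxel_offsets_1d(split)
    n_inplane = len(off) ** 2
    inplane = np.array(list(itertools.product(off, off)), dtype=float)

    if strategy.z_policy == "parent_slice":
        # z-displaced sub-voxels are tested against the parent slice's
        # polygons, so every z-layer repeats the in-plane pattern and the
        # interior fraction reduces to the in-plane fraction.
        for s, polys in by_slice.items():
            rr, cc = _candidate_box(polys, geometry.dims)
            centres = np.column_stack([rr, cc]).astype(float)
            counts = np.zeros(len(centres), dtype=int)
            for d in inplane:
                counts += _evenodd_inside(centres + d, polys)
            frac_ok = 100.0 * counts / n_inplane >= strategy.threshold_pct
            mask[rr[frac_ok], cc[frac_ok], s] = True
    else:  # nearest_plane
        n_sub = len(off) ** 3
        occupied = sorted(by_slice)
        # all slices whose sub-voxels can reach an occupied plane
        slices = sorted(
            {
                s2
                for s in occupied
                for s2 in range(max(0, s - 1), min(geometry.dims[2], s + 2))
            }
        )
        for s in slices:
            counts_by_rc: dict[tuple[int, int], int] = {}
            rr = cc = None
            counts = None
            for dz in off:
                target = int(round(s + dz))
                polys = by_slice.get(target)
                if polys is None:
                    continue
                if counts is None:
                    box_polys = [p for t in occupied for p in by_slice[t]]
                    rr, cc = _candidate_box(box_polys, geometry.dims)
                    counts = np.zeros(len(rr), dtype=int)
                centres = np.column_stack([rr, cc]).astype(float)
                for d in inplane:
                    counts += _evenodd_inside(centres + d, polys)
            if counts is None:
                continue
            frac_ok = 100.0 * counts / n_sub >= strategy.threshold_pct
            mask[rr[frac_ok], cc[frac_ok], s] = True
    return BinaryMask(
        geometry=geometry, voxels=mask, strategy=strategy, roi_name=contours.roi_name
    )


def rasterize(
    contours: ContourSet, geometry: ImageGeometry, strategy: RasterStrategy
) -> BinaryMask:
    """Dispatch to the centre or supersampled rasteriser."""
    if strategy.method == "centre":
        mask = rasterize_centre(contours, geometry)
        return replace(mask, strategy=strategy)
    return rasterize_supersampled(contours, geometry, strategy)


# ---------------------------------------------------------------------------
# NIfTI mask exchange (baseline masks are commonly shipped as 0/1 volumes)


def _affine(geometry: ImageGeometry) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = geometry.index_to_patient_matrix
    aff[:3, 3] = geometry.origin
    return aff


def write_mask_nifti(mask: BinaryMask, path) -> None:
    """Write a mask as a 0/1 integer NIfTI volume (patient-mm affine)."""
    import nibabel as nib

    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.geometry))
    nib.save(img, str(path))


def read_mask_nifti(path, geometry: ImageGeometry, roi_name: str = "") -> BinaryMask:
    """Read a 0/1 NIfTI volume as a designated reference mask."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.shape != geometry.dims:
        raise ShapeError(f"NIfTI shape {data.shape} != geometry dims {geometry.dims}")
    return BinaryMask(
        geometry=geometry,
        voxels=data > 0,
        strategy=RasterStrategy(method="centre"),
        roi_name=roi_name,
    )
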