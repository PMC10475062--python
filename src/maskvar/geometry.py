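"""Contour and image-grid geometry.

RTSTRUCT delineations are closed planar polygons whose vertices live in
patient coordinates (millimetres).  Aligning them with a voxel grid needs
the image geometry: the position of the first voxel centre (DICOM Image
Position), the direction cosines of rows and columns (Image Orientation),
the slice direction, and the voxel spacing.  This module provides the
coordinate transforms between patient space and continuous voxel indices,
plus readers for DICOM RTSTRUCT and for a small JSON contour dialect used
to exchange synthetic fixtures.

Convention: an *integer* index ``(r, c, s)`` addresses a voxel **centre**;
indices are 0-based, so the patient position of voxel ``(r, c, s)`` is
``origin + r*dr*row_dir + c*dc*col_dir + s*ds*slice_dir``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, FormatError

__all__ = [
    "ImageGeometry",
    "ContourPolygon",
    "ContourSet",
    "ImageVolume",
    "read_rtstruct",
    "read_contours_json",
    "write_contours_json",
]

#: Maximum |z - mean z| (mm) for a contour item to count as planar.
PLANARITY_TOL_MM = 1e-3

_UNIT_TOL = 1e-9


def _as_unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise DataError(f"{name} must be a 3-vector, got shape {v.shape}")
    if abs(np.linalg.norm(v) - 1.0) > _UNIT_TOL:
        raise DataError(f"{name} must have unit norm, got {np.linalg.norm(v)!r}")
    return v


@dataclass(frozen=True)
class ImageGeometry:
    """Geometry of a 3D voxel grid in patient coordinates.

    Parameters
    ----------
    origin:
        Patient-space position (mm) of the centre of voxel (0, 0, 0) —
        the upper-left corner voxel of the first slice.
    row_dir, col_dir:
        Unit direction cosines of increasing row index and column index.
    slice_dir:
        Unit direction of increasing slice index.
    spacing:
        (row, col, slice) voxel spacing in mm, all strictly positive.
    dims:
        (n_rows, n_cols, n_slices).
    """

    origin: np.ndarray
    row_dir: np.ndarray
    col_dir: np.ndarray
    slice_dir: np.ndarray
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if self.origin.shape != (3,):
            raise DataError("origin must be a 3-vector")
        object.__setattr__(self, "row_dir", _as_unit(self.row_dir, "row_dir"))
        object.__setattr__(self, "col_dir", _as_unit(self.col_dir, "col_dir"))
        object.__setattr__(self, "slice_dir", _as_unit(self.slice_dir, "slice_dir"))
        if abs(float(self.row_dir @ self.col_dir)) > _UNIT_TOL:
            raise DataError("row_dir and col_dir must be orthogonal")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise DataError(f"spacing must be 3 strictly positive values, got {spacing}")
        object.__setattr__(self, "spacing", spacing)
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise DataError(f"dims must be 3 positive integers, got {dims}")
        object.__setattr__(self, "dims", dims)

    @property
    def index_to_patient_matrix(self) -> np.ndarray:
        """3x3 matrix whose columns map unit index steps to patient mm."""
        return np.column_stack(
            [
                self.row_dir * self.spacing[0],
                self.col_dir * self.spacing[1],
                self.slice_dir * self.spacing[2],
            ]
        )

    def voxel_to_patient(self, indices) -> np.ndarray:
        """Map continuous (row, col, slice) indices to patient mm.

        Accepts a single 3-vector or an (N, 3) array.
        """
        idx = np.asarray(indices, dtype=float)
        return idx @ self.index_to_patient_matrix.T + self.origin

    def patient_to_voxel(self, points) -> np.ndarray:
        """Map patient-space mm points to continuous (row, col, slice).

        Exact inverse of :meth:`voxel_to_patient`; points outside the grid
        simply return out-of-range indices.
        """
        p = np.asarray(points, dtype=float)
        rel = p - self.origin
        sol = np.linalg.solve(self.index_to_patient_matrix, rel.reshape(-1, 3).T).T
        return sol.reshape(p.shape)

    def slice_z(self, s: int) -> float:
        """Patient z-coordinate of slice plane ``s``."""
        return float(self.voxel_to_patient([0.0, 0.0, float(s)])[2])


@dataclass(frozen=True)
class ContourPolygon:
    """One closed planar polygon: (N, 3) patient-mm vertices sharing z.

    The polygon is implicitly closed (last vertex connects to first).
    """

    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 3:
            raise DataError(
                f"polygon needs an (N>=3, 3) vertex array, got shape {v.shape}"
            )
        z = v[:, 2]
        if np.max(np.abs(z - z.mean())) > PLANARITY_TOL_MM:
            raise DataError(
                f"polygon is not planar: z spread {np.ptp(z):.6g} mm exceeds "
                f"{PLANARITY_TOL_MM} mm"
            )
        nxt = np.roll(v, -1, axis=0)
        if np.any(np.all(np.isclose(v, nxt, rtol=0.0, atol=0.0), axis=1)):
            raise DataError("polygon has duplicated consecutive vertices")
        object.__setattr__(self, "vertices", v)

    @property
    def slice_z(self) -> float:
        return float(self.vertices[:, 2].mean())

    @property
    def xy(self) -> np.ndarray:
        return self.vertices[:, :2]


@dataclass(frozen=True)
class ContourSet:
    """All polygons delineating one ROI, grouped implicitly by slice z."""

    roi_name: str
    polygons: tuple[ContourPolygon, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "polygons", tuple(self.polygons))

    def __len__(self) -> int:
        return len(self.polygons)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ContourSet):
            return NotImplemented
        return (
            self.roi_name == other.roi_name
            and len(self) == len(other)
            and all(
                a.vertices.shape == b.vertices.shape
                and np.array_equal(a.vertices, b.vertices)
                for a, b in zip(self.polygons, other.polygons)
            )
        )


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar image on an :class:`ImageGeometry` grid."""

    geometry: ImageGeometry
    voxels: np.ndarray
    modality_tag: str = ""

    def __post_init__(self):
        v = np.asarray(self.voxels, dtype=float)
        if v.shape != self.geometry.dims:
            raise DataError(
                f"voxel array shape {v.shape} != geometry dims {self.geometry.dims}"
            )
        object.__setattr__(self, "voxels", v)


# ---------------------------------------------------------------------------
# DICOM RTSTRUCT


def read_rtstruct(path, geometry: ImageGeometry, roi_name: str | None = None) -> ContourSet:
    """Read one ROI's CLOSED_PLANAR contours from a DICOM RTSTRUCT file.

    Vertex order and the number of contour items are preserved from the
    file.  ``geometry`` comes from the referenced image series (contours
    alone do not define the grid).

    Parameters
    ----------
    roi_name:
        ROI to select by its ROI Name; ``None`` selects the first ROI.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    if "StructureSetROISequence" not in ds or "ROIContourSequence" not in ds:
        raise FormatError("file is not an RTSTRUCT: missing ROI sequences")

    names = {
        int(item.ROINumber): str(getattr(item, "ROIName", ""))
        for item in ds.StructureSetROISequence
    }
    selected = None
    for rc in ds.ROIContourSequence:
        name = names.get(int(rc.ReferencedROINumber), "")
        if roi_name is None or name == roi_name:
            selected = (name, rc)
            break
    if selected is None:
        raise DataError(f"ROI {roi_name!r} not found in RTSTRUCT")
    name, rc = selected

    polygons = []
    for i, item in enumerate(getattr(rc, "ContourSequence", [])):
        gtype = str(getattr(item, "ContourGeometricType", "")).strip()
        if gtype != "CLOSED_PLANAR":
            raise DataError(
                f"contour item {i}: geometric type {gtype!r} not supported "
                "(only CLOSED_PLANAR)"
            )
        if "ContourData" not in item:
            raise FormatError(f"contour item {i}: missing Contour Data (3006,0050)")
        data = [float(x) for x in item.ContourData]
        if len(data) % 3 != 0:
            raise FormatError(
                f"contour item {i}: Contour Data length {len(data)} is not a "
                "multiple of 3"
            )
        verts = np.asarray(data, dtype=float).reshape(-1, 3)
        z = verts[:, 2]
        if verts.shape[0] >= 1 and np.max(np.abs(z - z.mean())) > PLANARITY_TOL_MM:
            raise DataError(f"contour item {i}: not planar (z spread {np.ptp(z):.6g} mm)")
        polygons.append(ContourPolygon(verts))
    return ContourSet(roi_name=name, polygons=tuple(polygons))


# ---------------------------------------------------------------------------
# JSON contour fixture dialect
#
# {"geometry": {"origin": [x,y,z], "row_dir": [...], "col_dir": [...],
#               "slice_dir": [...], "spacing": [r,c,s], "dims": [nr,nc,ns]},
#  "roi_name": str,
#  "polygons": [{"z": float, "xy": [[x,y], ...]}, ...]}


def _require(obj, key, path):
    if not isinstance(obj, dict) or key not in obj:
        raise FormatError(f"missing required field at {path}.{key}")
    return obj[key]


def read_contours_json(path) -> tuple[ContourSet, ImageGeometry]:
    """Read a contour fixture document; see the module docstring dialect.

    Raises :class:`FormatError` naming the JSON path of the first
    offending field.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid JSON: {exc}") from exc

    g = _require(doc, "geometry", "$")
    fields = {}
    for key in ("origin", "row_dir", "col_dir", "slice_dir", "spacing", "dims"):
        val = _require(g, key, "$.geometry")
        if not isinstance(val, list) or len(val) != 3:
            raise FormatError(f"expected a 3-element list at $.geometry.{key}")
        fields[key] = val
    try:
        geometry = ImageGeometry(
            origin=fields["origin"],
            row_dir=fields["row_dir"],
            col_dir=fields["col_dir"],
            slice_dir=fields["slice_dir"],
            spacing=tuple(fields["spacing"]),
            dims=tuple(fields["dims"]),
        )
    except DataError as exc:
        raise FormatError(f"invalid geometry at $.geometry: {exc}") from exc

    roi_name = _require(doc, "roi_name", "$")
    polys_doc = _require(doc, "polygons", "$")
    if not isinstance(polys_doc, list):
        raise FormatError("expected a list at $.polygons")
    polygons = []
    for i, p in enumerate(polys_doc):
        z = _require(p, "z", f"$.polygons[{i}]")
        xy = _require(p, "xy", f"$.polygons[{i}]")
        if not isinstance(xy, list) or len(xy) < 3:
            raise FormatError(f"expected >=3 [x,y] pairs at $.polygons[{i}].xy")
        try:
            verts = np.asarray(
                [[float(x), float(y), float(z)] for x, y in xy], dtype=float
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"bad vertex data at $.polygons[{i}].xy: {exc}") from exc
        try:
            polygons.append(ContourPolygon(verts))
        except DataError as exc:
            raise FormatError(f"invalid polygon at $.polygons[{i}]: {exc}") from exc
    return ContourSet(roi_name=str(roi_name), polygons=tuple(polygons)), geometry


def write_contours_json(contours: ContourSet, geometry: ImageGeometry, path) -> None:
    """Write the JSON fixture dialect; lossless round-trip with the reader."""
    doc = {
        "geometry": {
            "origin": [float(x) for x in geometry.origin],
            "row_dir": [float(x) for x in geometry.row_dir],
            "col_dir": [float(x) for x in geometry.col_dir],
            "slice_dir": [float(x) for x in geometry.slice_dir],
            "spacing": [float(x) for x in geometry.spacing],
            "dims": [int(x) for x in geometry.dims],
        },
        "roi_name": contours.roi_name,
        "polygons": [
            {
                "z": poly.slice_z,
                "xy": [[float(x), float(y)] for x, y in poly.xy],
            }
            for poly in contours.polygons
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
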