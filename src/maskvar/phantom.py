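"""Synthetic multi-modality phantom cohort.

Generates a seeded cohort of patients, each carrying one ellipsoidal
lesion (one anatomy) expressed on three voxel grids that emulate the
resolution regimes of clinical imaging: a fine "CT" grid, an
intermediate "MRI" grid and a coarse "PET" grid.  Per-slice closed
polygon contours are sampled from the analytic ellipsoid cross-sections
at sub-voxel patient coordinates with optional vertex jitter, so that
different rasterisation strategies genuinely disagree at region edges.
Lesion intensities are spatially correlated noise on top of a
patient-specific mean and contrast, giving non-degenerate texture
matrices and feature variation across patients; the background is white
noise.

Because PET voxels are large, a PET ROI holds tens of voxels where the
CT ROI holds hundreds to thousands — reproducing the size effect whereby
small/low-resolution ROIs amplify mask-conversion feature differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DataError
from .geometry import (
    ContourPolygon,
    ContourSet,
    ImageGeometry,
    ImageVolume,
    read_contours_json,
    write_contours_json,
)

__all__ = [
    "ModalitySpec",
    "CohortConfig",
    "Lesion",
    "Patient",
    "Cohort",
    "generate_lesion_contours",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class ModalitySpec:
    """One imaging grid: tag, (row, col, slice) spacing mm, dims."""

    tag: str
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def geometry(self) -> ImageGeometry:
        # axis-aligned grid centred on the patient origin
        origin = [
            -(self.dims[i] - 1) / 2.0 * self.spacing[i] for i in range(3)
        ]
        return ImageGeometry(
            origin=origin,
            row_dir=[1.0, 0.0, 0.0],
            col_dir=[0.0, 1.0, 0.0],
            slice_dir=[0.0, 0.0, 1.0],
            spacing=self.spacing,
            dims=self.dims,
        )


DEFAULT_MODALITIES = (
    ModalitySpec("CT", (1.0, 1.0, 3.0), (64, 64, 24)),
    ModalitySpec("MRI", (1.0, 1.0, 5.0), (48, 48, 16)),
    ModalitySpec("PET", (4.0, 4.0, 4.0), (32, 32, 16)),
)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults give a 20-patient cohort in which the PET ROI averages tens
    of voxels and the CT ROI hundreds or more.
    """

    n_patients: int = 20
    modalities: tuple[ModalitySpec, ...] = DEFAULT_MODALITIES
    radius_range_mm: tuple[float, float] = (6.0, 12.0)
    n_vertices: int = 64
    jitter_sd_mm: float = 0.3
    centre_jitter_mm: float = 2.0
    texture_corr_mm: float = 3.0
    lesion_mean: float = 100.0
    lesion_mean_sd: float = 20.0
    contrast_range: tuple[float, float] = (10.0, 25.0)
    noise_sd: float = 5.0
    seed: int = 42

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigError("n_patients must be positive")
        lo, hi = self.radius_range_mm
        if not (0 < lo <= hi):
            raise ConfigError("radius_range_mm must be 0 < lo <= hi")
        if self.n_vertices < 3:
            raise ConfigError("n_vertices must be >= 3")


@dataclass(frozen=True)
class Lesion:
    """A randomly oriented ellipsoid: (x-c)^T A (x-c) = 1 bounds it."""

    centre: np.ndarray  # (3,) mm
    semiaxes: np.ndarray  # (3,) mm
    rotation: np.ndarray  # (3, 3) proper rotation

    @property
    def quadric(self) -> np.ndarray:
        R = self.rotation
        return R @ np.diag(1.0 / self.semiaxes**2) @ R.T

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership of (N, 3) patient-mm points."""
        rel = np.atleast_2d(points) - self.centre
        return np.einsum("ni,ij,nj->n", rel, self.quadric, rel) <= 1.0


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _ellipse_cross_section(lesion: Lesion, z: float):
    """In-plane centre, 2x2 shape matrix and scale of the ellipsoid's
    intersection with the plane at patient z, or None if disjoint."""
    A = lesion.quadric
    dz = z - lesion.centre[2]
    A2 = A[:2, :2]
    b = A[:2, 2]
    rho = 1.0 - dz**2 * A[2, 2] + dz**2 * float(b @ np.linalg.solve(A2, b))
    if rho <= 1e-12:
        return None
    u0 = lesion.centre[:2] - dz * np.linalg.solve(A2, b)
    return u0, A2, rho


def _smooth_jitter(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """(n, 2) circularly correlated vertex jitter with pointwise sd."""
    noise = rng.normal(size=(n, 2))
    k = np.exp(-0.5 * (np.arange(n) - n // 2) ** 2 / max(n / 16.0, 1.0) ** 2)
    k /= k.sum()
    sm = np.empty_like(noise)
    for ax in range(2):
        f = np.fft.rfft(noise[:, ax]) * np.fft.rfft(np.roll(k, -(n // 2)))
        sm[:, ax] = np.fft.irfft(f, n)
    scale = sm.std()
    return sm * (sd / scale) if scale > 0 else sm


def generate_lesion_contours(
    lesion: Lesion,
    geometry: ImageGeometry,
    n_vertices: int,
    jitter_sd_mm: float,
    rng: np.random.Generator,
    roi_name: str = "lesion",
    max_resample: int = 20,
) -> ContourSet:
    """Sample per-slice polygon contours of an ellipsoidal lesion.

    Each slice plane intersecting the ellipsoid contributes one polygon:
    the cross-section ellipse sampled at ``n_vertices`` evenly spaced
    angles, with independent Gaussian jitter (sd ``jitter_sd_mm``) on the
    in-plane coordinates.  Jittered polygons that self-intersect are
    resampled.  Assumes the axis-aligned grids produced by
    :class:`ModalitySpec` (slice planes at constant patient z).
    """
    import shapely

    half = np.asarray(geometry.spacing) / 2.0
    lo = geometry.origin - half
    hi = geometry.voxel_to_patient(np.asarray(geometry.dims, dtype=float) - 1) + half
    rmax = float(lesion.semiaxes.max())
    if np.any(lesion.centre - rmax < lo) or np.any(lesion.centre + rmax > hi):
        raise ConfigError("lesion extends outside the imaging field of view")

    theta = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    polygons = []
    for s in range(geometry.dims[2]):
        z = geometry.slice_z(s)
        sec = _ellipse_cross_section(lesion, z)
        if sec is None:
            continue
        u0, A2, rho = sec
        # boundary: u0 + sqrt(rho) * A2^(-1/2) [cos t, sin t]
        w, v = np.linalg.eigh(A2)
        min_semiaxis = float(np.sqrt(rho) / np.sqrt(w.max()))
        if min_semiaxis < 0.5:
            continue  # sub-half-mm polar sliver: not clinically contoured
        half_mat = v @ np.diag(np.sqrt(rho) / np.sqrt(w)) @ v.T
        ring = u0 + (half_mat @ np.vstack([np.cos(theta), np.sin(theta)])).T
        # delineation noise is smooth along the contour: circularly
        # correlated jitter, capped relative to the local contour size,
        # keeps the jittered loop simple
        sd = min(jitter_sd_mm, 0.15 * min_semiaxis)
        for _ in range(max_resample + 1):
            xy = ring + _smooth_jitter(n_vertices, sd, rng) if sd > 0 else ring
            if shapely.Polygon(xy).is_valid:
                break
        else:
            raise DataError(f"could not draw a simple polygon on slice {s}")
        verts = np.column_stack([xy, np.full(n_vertices, z)])
        polygons.append(ContourPolygon(verts))
    return ContourSet(roi_name=roi_name, polygons=tuple(polygons))


@dataclass(frozen=True)
class Patient:
    """One synthetic patient: a lesion imaged on every modality grid."""

    patient_id: str
    lesion: Lesion
    images: dict[str, ImageVolume]
    contours: dict[str, ContourSet]


@dataclass(frozen=True)
class Cohort:
    config: CohortConfig
    patients: tuple[Patient, ...] = ()

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(m.tag for m in self.config.modalities)


def _lesion_image(
    spec: ModalitySpec,
    geometry: ImageGeometry,
    lesion: Lesion,
    cfg: CohortConfig,
    mean: float,
    contrast: float,
    rng: np.random.Generator,
) -> ImageVolume:
    dims = spec.dims
    vox = cfg.noise_sd * rng.standard_normal(dims)
    tex = rng.standard_normal(dims)
    sigma = [max(cfg.texture_corr_mm / s, 1e-6) for s in spec.spacing]
    tex = ndimage.gaussian_filter(tex, sigma=sigma, mode="reflect")
    sd = tex.std()
    if sd > 0:
        tex /= sd
    rr, cc, ss = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    centres = geometry.voxel_to_patient(
        np.column_stack([rr.ravel(), cc.ravel(), ss.ravel()]).astype(float)
    )
    inside = lesion.contains(centres).reshape(dims)
    vox[inside] += mean + contrast * tex[inside]
    return ImageVolume(geometry=geometry, voxels=vox, modality_tag=spec.tag)


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate the full seeded cohort (bit-identical per seed)."""
    cfg = config or CohortConfig()
    root = np.random.SeedSequence(cfg.seed)
    patients = []
    for p, ss in enumerate(root.spawn(cfg.n_patients)):
        rng = np.random.default_rng(ss)
        pid = f"P{p + 1:02d}"
        semiaxes = rng.uniform(*cfg.radius_range_mm, size=3)
        centre = rng.uniform(-cfg.centre_jitter_mm, cfg.centre_jitter_mm, size=3)
        lesion = Lesion(
            centre=centre, semiaxes=semiaxes, rotation=_random_rotation(rng)
        )
        mean = rng.normal(cfg.lesion_mean, cfg.lesion_mean_sd)
        contrast = rng.uniform(*cfg.contrast_range)
        images: dict[str, ImageVolume] = {}
        contours: dict[str, ContourSet] = {}
        for spec in cfg.modalities:
            geom = spec.geometry()
            contours[spec.tag] = generate_lesion_contours(
                lesion,
                geom,
                cfg.n_vertices,
                cfg.jitter_sd_mm,
                rng,
                roi_name=f"{pid}_lesion",
            )
            images[spec.tag] = _lesion_image(
                spec, geom, lesion, cfg, mean, contrast, rng
            )
        patients.append(
            Patient(patient_id=pid, lesion=lesion, images=images, contours=contours)
        )
    return Cohort(config=cfg, patients=tuple(patients))


# ---------------------------------------------------------------------------
# on-disk cohort layout: <dir>/<pid>_<tag>.contours.json + .nii.gz + manifest


def save_cohort(cohort: Cohort, outdir) -> None:
    """Write contours (JSON dialect), images (NIfTI) and a manifest CSV."""
    import nibabel as nib
    import pandas as pd
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for pat in cohort.patients:
        for tag, vol in pat.images.items():
            stem = f"{pat.patient_id}_{tag}"
            write_contours_json(
                pat.contours[tag], vol.geometry, out / f"{stem}.contours.json"
            )
            aff = np.eye(4)
            aff[:3, :3] = vol.geometry.index_to_patient_matrix
            aff[:3, 3] = vol.geometry.origin
            nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), aff),
                     str(out / f"{stem}.nii.gz"))
            rows.append({"patient_id": pat.patient_id, "modality": tag,
                         "contours": f"{stem}.contours.json",
                         "image": f"{stem}.nii.gz"})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)


def load_cohort(indir) -> Cohort:
    """Reload a saved cohort (lesion parameters are not persisted)."""
    import nibabel as nib
    import pandas as pd
    from pathlib import Path

    ind = Path(indir)
    manifest = pd.read_csv(ind / "manifest.csv")
    patients = []
    specs: dict[str, ModalitySpec] = {}
    for pid, group in manifest.groupby("patient_id", sort=True):
        images: dict[str, ImageVolume] = {}
        contours: dict[str, ContourSet] = {}
        for _, row in group.iterrows():
            cset, geom = read_contours_json(ind / row["contours"])
            data = np.asarray(nib.load(str(ind / row["image"])).dataobj, dtype=float)
            tag = str(row["modality"])
            images[tag] = ImageVolume(geometry=geom, voxels=data, modality_tag=tag)
            contours[tag] = cset
            specs.setdefault(tag, ModalitySpec(tag, geom.spacing, geom.dims))
        placeholder = Lesion(
            centre=np.zeros(3), semiaxes=np.ones(3), rotation=np.eye(3)
        )
        patients.append(Patient(patient_id=str(pid), lesion=placeholder,
                                images=images, contours=contours))
    cfg = CohortConfig(n_patients=len(patients), modalities=tuple(specs.values()))
    return Cohort(config=cfg, patients=tuple(patients))
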