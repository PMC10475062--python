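"""IBSI-style radiomic feature extraction.

A representative registry of ~45 standardised features spanning all nine
feature families: morphology (morph), intensity statistics (stat),
intensity histogram (ih), grey level co-occurrence matrix (cm), grey
level run length matrix (rlm), grey level size zone matrix (szm), grey
level distance zone matrix (dzm), neighbouring grey tone difference
matrix (ngt) and neighbouring grey level dependence matrix (ngl).

Conventions (fixed here, documented in docs/methods.md):

* features are computed on the original voxel grid — no interpolation or
  resampling;
* texture matrices use Chebyshev distance 1 and merged-3D aggregation:
  co-occurrences and runs are accumulated over the 13 unique 3D direction
  vectors and pooled into a single matrix before feature computation;
* zones (szm/dzm) use 26-connectivity; dzm distance is the city-block
  distance to the nearest out-of-mask voxel with the volume border
  counting as outside (minimum distance 1);
* ngl dependence counts identical-level 26-neighbours (alpha = 0) and is
  stored at column j = k + 1;
* log2(0) terms in entropies are 0; eps = 2**-52 guards the coarseness
  and busyness denominators; kurtosis is excess (Fisher) kurtosis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DataError, UsageError
from .geometry import ImageVolume
from .rasterize import BinaryMask

__all__ = [
    "ExtractionConfig",
    "GreyLevelVolume",
    "FeatureVector",
    "discretise",
    "build_texture_matrix",
    "extract_features",
    "FEATURE_FAMILIES",
    "feature_family",
]

FEATURE_FAMILIES = ("morph", "stat", "ih", "cm", "rlm", "szm", "dzm", "ngt", "ngl")

_EPS = 2.0**-52

#: the 13 unique 3D direction vectors at Chebyshev distance 1
DIRECTIONS_13 = tuple(
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d > (0, 0, 0)
)

#: all 26 neighbour offsets
OFFSETS_26 = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)


@dataclass(frozen=True)
class ExtractionConfig:
    """Feature-extraction settings.

    ``discretisation`` is ``"FBN"`` (fixed bin number, ``n_bins``) or
    ``"FBS"`` (fixed bin size, ``bin_width`` starting at ``min_bound``).
    Texture distance is fixed at 1 (Chebyshev) with merged-3D
    aggregation.
    """

    discretisation: str = "FBN"
    n_bins: int = 32
    bin_width: float = 1.0
    min_bound: float = 0.0
    modality_tag: str = ""

    def __post_init__(self):
        if self.discretisation not in ("FBN", "FBS"):
            raise ConfigError(f"unknown discretisation {self.discretisation!r}")
        if self.discretisation == "FBN" and int(self.n_bins) < 2:
            raise ConfigError("FBN requires n_bins >= 2")
        if self.discretisation == "FBS" and float(self.bin_width) <= 0:
            raise ConfigError("FBS requires bin_width > 0")

    def to_dict(self) -> dict:
        return {
            "discretisation": self.discretisation,
            "n_bins": int(self.n_bins),
            "bin_width": float(self.bin_width),
            "min_bound": float(self.min_bound),
            "modality_tag": self.modality_tag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExtractionConfig":
        return cls(**d)


@dataclass(frozen=True)
class GreyLevelVolume:
    """Discretised intensities: level 1..Ng inside the mask, 0 outside."""

    levels: np.ndarray
    Ng: int
    mask: BinaryMask

    def __post_init__(self):
        lv = np.asarray(self.levels)
        m = self.mask.voxels
        if lv.shape != m.shape:
            raise DataError("levels shape != mask shape")
        inside = lv[m]
        if inside.size and (inside.min() < 1 or inside.max() > self.Ng):
            raise DataError("in-mask levels must lie in [1, Ng]")
        if (lv[~m] != 0).any():
            raise DataError("out-of-mask levels must be 0")
        object.__setattr__(self, "levels", lv.astype(np.int32))


@dataclass(frozen=True)
class FeatureVector:
    """Ordered feature_id -> value map with extraction provenance."""

    values: dict[str, float]
    config: ExtractionConfig
    strategy_label: str = ""

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def families(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {f: [] for f in FEATURE_FAMILIES}
        for fid in self.values:
            out[feature_family(fid)].append(fid)
        return out


def feature_family(feature_id: str) -> str:
    fam = feature_id.split("_", 1)[0]
    if fam not in FEATURE_FAMILIES:
        raise UsageError(f"feature id {feature_id!r} has unknown family tag")
    return fam


# ---------------------------------------------------------------------------
# discretisation


def discretise(
    image: ImageVolume, mask: BinaryMask, config: ExtractionConfig
) -> GreyLevelVolume:
    """Bin in-mask intensities to integer grey levels 1..Ng.

    FBN: ``level = min(Ng, 1 + floor(Ng*(x - min)/(max - min)))`` with a
    constant region mapping to level 1.  FBS: ``level = 1 +
    floor((x - min_bound)/bin_width)``.
    """
    m = mask.voxels
    if not m.any():
        raise DataError("cannot discretise an empty mask")
    x = image.voxels[m]
    levels = np.zeros(m.shape, dtype=np.int32)
    if config.discretisation == "FBN":
        ng = int(config.n_bins)
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            lv = np.ones(x.shape, dtype=np.int32)
        else:
            lv = np.minimum(ng, 1 + np.floor(ng * (x - lo) / (hi - lo)).astype(np.int32))
        levels[m] = lv
        return GreyLevelVolume(levels=levels, Ng=ng, mask=mask)
    lv = 1 + np.floor((x - config.min_bound) / config.bin_width).astype(np.int32)
    if lv.min() < 1:
        raise DataError("FBS: intensities below min_bound")
    levels[m] = lv
    return GreyLevelVolume(levels=levels, Ng=int(lv.max()), mask=mask)


# ---------------------------------------------------------------------------
# texture matrices


def _shift_slices(shape, d):
    """Paired slicing views so that a[sa] and a[sb] align voxel v with v+d."""
    sa, sb = [], []
    for n, step in zip(shape, d):
        if step == 0:
            sa.append(slice(0, n))
            sb.append(slice(0, n))
        elif step > 0:
            sa.append(slice(0, n - step))
            sb.append(slice(step, n))
        else:
            sa.append(slice(-step, n))
            sb.append(slice(0, n + step))
    return tuple(sa), tuple(sb)


def _glcm(gvol: GreyLevelVolume) -> np.ndarray:
    """Symmetric co-occurrence counts merged over the 13 directions."""
    lv, m, ng = gvol.levels, gvol.mask.voxels, gvol.Ng
    M = np.zeros((ng, ng))
    for d in DIRECTIONS_13:
        sa, sb = _shift_slices(lv.shape, d)
        valid = m[sa] & m[sb]
        i = lv[sa][valid] - 1
        j = lv[sb][valid] - 1
        np.add.at(M, (i, j), 1.0)
        np.add.at(M, (j, i), 1.0)
    return M


def _glrlm(gvol: GreyLevelVolume) -> np.ndarray:
    """Run-length counts (level x run length) merged over 13 directions."""
    lv, m = gvol.levels, gvol.mask.voxels
    shape = lv.shape
    runs: dict[tuple[int, int], int] = {}
    max_len = 1
    for d in DIRECTIONS_13:
        sa, sb = _shift_slices(shape, d)
        ext = np.zeros(shape, dtype=bool)  # ext[v]: run continues v -> v+d
        ext[sa] = m[sa] & m[sb] & (lv[sa] == lv[sb])
        # a run starts where there is no same-level in-mask predecessor
        start = m.copy()
        start[sb] &= ~ext[sa]
        pos = np.argwhere(start)
        lev = lv[start]
        length = np.ones(len(pos), dtype=int)
        step = np.asarray(d)
        active = np.arange(len(pos))
        cur = pos.copy()
        while active.size:
            cont = ext[tuple(cur[active].T)]
            active = active[cont]
            length[active] += 1
            cur[active] += step
        for gl, ln in zip(lev, length):
            runs[(int(gl), int(ln))] = runs.get((int(gl), int(ln)), 0) + 1
            max_len = max(max_len, int(ln))
    R = np.zeros((gvol.Ng, max_len))
    for (gl, ln), n in runs.items():
        R[gl - 1, ln - 1] = n
    return R


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _zones(gvol: GreyLevelVolume):
    """Yield (level, zone_sizes, labelled, n_zones) per occupied level."""
    lv = gvol.levels
    for g in range(1, gvol.Ng + 1):
        where = lv == g
        if not where.any():
            continue
        lab, n = ndimage.label(where, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        yield g, sizes, lab, n


def _glszm(gvol: GreyLevelVolume) -> np.ndarray:
    counts: dict[tuple[int, int], int] = {}
    max_size = 1
    for g, sizes, _, _ in _zones(gvol):
        for sz in sizes:
            counts[(g, int(sz))] = counts.get((g, int(sz)), 0) + 1
            max_size = max(max_size, int(sz))
    S = np.zeros((gvol.Ng, max_size))
    for (g, sz), n in counts.items():
        S[g - 1, sz - 1] = n
    return S


def _gldzm(gvol: GreyLevelVolume) -> np.ndarray:
    """Zone counts by (level, city-block distance of zone to mask border)."""
    m = gvol.mask.voxels
    padded = np.pad(m, 1)
    dist = ndimage.distance_transform_cdt(padded, metric="taxicab")[1:-1, 1:-1, 1:-1]
    counts: dict[tuple[int, int], int] = {}
    max_d = 1
    for g, _, lab, n in _zones(gvol):
        if n == 0:
            continue
        mins = ndimage.minimum(dist, labels=lab, index=np.arange(1, n + 1))
        for dmin in np.atleast_1d(mins):
            dmin = max(1, int(dmin))
            counts[(g, dmin)] = counts.get((g, dmin), 0) + 1
            max_d = max(max_d, dmin)
    D = np.zeros((gvol.Ng, max_d))
    for (g, dmin), n in counts.items():
        D[g - 1, dmin - 1] = n
    return D


def _ngtdm(gvol: GreyLevelVolume) -> np.ndarray:
    """Rows i: [p_i, s_i] — occurrence probability and summed absolute
    deviation of level i+1 from the mean of its valid 26-neighbourhood."""
    lv, m = gvol.levels, gvol.mask.voxels
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nsum = ndimage.correlate(lv.astype(float) * m, kernel, mode="constant", cval=0.0)
    ncnt = ndimage.correlate(m.astype(float), kernel, mode="constant", cval=0.0)
    valid = m & (ncnt > 0)
    mean_nb = np.zeros(lv.shape)
    mean_nb[valid] = nsum[valid] / ncnt[valid]
    dev = np.abs(lv - mean_nb)[valid]
    lab = lv[valid] - 1
    n_valid = int(valid.sum())
    s = np.bincount(lab, weights=dev, minlength=gvol.Ng)
    n_i = np.bincount(lab, minlength=gvol.Ng).astype(float)
    p = n_i / n_valid if n_valid else n_i
    return np.column_stack([p, s])


def _ngldm(gvol: GreyLevelVolume) -> np.ndarray:
    """Dependence counts: D[i-1, k] = in-mask voxels with level i and k
    identical-level 26-neighbours (stored at column j = k + 1)."""
    lv, m = gvol.levels, gvol.mask.voxels
    dep = np.zeros(lv.shape, dtype=np.int32)
    for d in OFFSETS_26:
        sa, sb = _shift_slices(lv.shape, d)
        dep[sa] += (m[sa] & m[sb] & (lv[sa] == lv[sb])).astype(np.int32)
    kmax = int(dep[m].max()) if m.any() else 0
    D = np.zeros((gvol.Ng, kmax + 1))
    np.add.at(D, (lv[m] - 1, dep[m]), 1.0)
    return D


_MATRIX_BUILDERS = {
    "cm": _glcm,
    "rlm": _glrlm,
    "szm": _glszm,
    "dzm": _gldzm,
    "ngt": _ngtdm,
    "ngl": _ngldm,
}


def build_texture_matrix(gvol: GreyLevelVolume, kind: str) -> np.ndarray:
    """Build one texture matrix (counts; callers normalise as needed).

    ``kind`` is one of cm, rlm, szm, dzm, ngt, ngl; see the individual
    builders for each matrix's convention.
    """
    try:
        builder = _MATRIX_BUILDERS[kind]
    except KeyError:
        raise UsageError(f"unknown texture matrix kind {kind!r}") from None
    return builder(gvol)


# ---------------------------------------------------------------------------
# feature computation


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _morph_features(mask: BinaryMask) -> dict[str, float]:
    m = mask.voxels
    sp = mask.geometry.spacing
    nv = int(m.sum())
    voxvol = sp[0] * sp[1] * sp[2]
    volume = nv * voxvol
    face_areas = (sp[1] * sp[2], sp[0] * sp[2], sp[0] * sp[1])
    surface = 0.0
    for ax, fa in enumerate(face_areas):
        padded = np.pad(m, [(1, 1) if a == ax else (0, 0) for a in range(3)])
        surface += float(np.abs(np.diff(padded.astype(np.int8), axis=ax)).sum()) * fa
    idx = np.argwhere(m).astype(float)
    pts = mask.geometry.voxel_to_patient(idx)
    if len(pts) == 1:
        diam = 0.0
    else:
        if len(pts) > 300:
            from scipy.spatial import ConvexHull, QhullError

            try:
                pts = pts[ConvexHull(pts).vertices]
            except QhullError:
                pass  # flat ROIs: fall back to all points
        diff = pts[:, None, :] - pts[None, :, :]
        diam = float(np.sqrt((diff**2).sum(-1)).max())
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface
    return {
        "morph_volume": volume,
        "morph_surface_area": surface,
        "morph_max_diameter": diam,
        "morph_sphericity": float(sphericity),
    }


def _stat_features(x: np.ndarray) -> dict[str, float]:
    mu = float(x.mean())
    var = float(x.var())  # population variance
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(((x - mu) ** 3).mean() / sd**3)
        kurt = float(((x - mu) ** 4).mean() / sd**4) - 3.0  # excess
    else:
        skew = kurt = 0.0
    return {
        "stat_mean": mu,
        "stat_variance": var,
        "stat_skewness": skew,
        "stat_kurtosis": kurt,
        "stat_median": float(np.median(x)),
        "stat_min": float(x.min()),
        "stat_max": float(x.max()),
        "stat_range": float(x.max() - x.min()),
        "stat_energy": float((x.astype(float) ** 2).sum()),
    }


def _ih_features(levels_in: np.ndarray, ng: int) -> dict[str, float]:
    counts = np.bincount(levels_in, minlength=ng + 1)[1:].astype(float)
    p = counts / counts.sum()
    i = np.arange(1, ng + 1, dtype=float)
    mean = float((i * p).sum())
    return {
        "ih_mean": mean,
        "ih_variance": float(((i - mean) ** 2 * p).sum()),
        "ih_entropy": _entropy(p),
        "ih_uniformity": float((p**2).sum()),
        "ih_mode": float(np.argmax(counts) + 1),  # argmax takes lowest on ties
    }


def _cm_features(M: np.ndarray) -> dict[str, float]:
    total = M.sum()
    P = M / total if total > 0 else M
    ng = P.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = P.sum(axis=1)
    mu_i = float((i * pi).sum())
    sig_i = float(np.sqrt(((i - mu_i) ** 2 * pi).sum()))
    # symmetric matrix: both marginals coincide
    if sig_i > 0:
        corr = (float((ii * jj * P).sum()) - mu_i * mu_i) / (sig_i * sig_i)
    else:
        corr = 1.0  # constant region: degenerate correlation defined as 1
    return {
        "cm_joint_max": float(P.max()),
        "cm_joint_entropy": _entropy(P.ravel()),
        "cm_contrast": float(((ii - jj) ** 2 * P).sum()),
        "cm_dissimilarity": float((np.abs(ii - jj) * P).sum()),
        "cm_inverse_difference": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "cm_correlation": float(corr),
    }


def _rlm_features(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    ns = R.sum()
    j = np.arange(1, R.shape[1] + 1, dtype=float)
    rj = R.sum(axis=0)
    ri = R.sum(axis=1)
    return {
        "rlm_short_run_emphasis": float((rj / j**2).sum() / ns),
        "rlm_long_run_emphasis": float((rj * j**2).sum() / ns),
        "rlm_grey_level_nonuniformity": float((ri**2).sum() / ns),
        "rlm_run_percentage": float(ns / n_voxels),
        "rlm_run_entropy": _entropy((R / ns).ravel()),
    }


def _szm_features(S: np.ndarray, n_voxels: int) -> dict[str, float]:
    ns = S.sum()
    j = np.arange(1, S.shape[1] + 1, dtype=float)
    sj = S.sum(axis=0)
    return {
        "szm_small_zone_emphasis": float((sj / j**2).sum() / ns),
        "szm_large_zone_emphasis": float((sj * j**2).sum() / ns),
        "szm_zone_size_entropy": _entropy((S / ns).ravel()),
        "szm_zone_percentage": float(ns / n_voxels),
    }


def _dzm_features(D: np.ndarray) -> dict[str, float]:
    ns = D.sum()
    d = np.arange(1, D.shape[1] + 1, dtype=float)
    dd = D.sum(axis=0)
    return {
        "dzm_small_distance_emphasis": float((dd / d**2).sum() / ns),
        "dzm_large_distance_emphasis": float((dd * d**2).sum() / ns),
        "dzm_distance_entropy": _entropy((D / ns).ravel()),
    }


def _ngt_features(ps: np.ndarray, n_valid: int) -> dict[str, float]:
    p, s = ps[:, 0], ps[:, 1]
    occ = p > 0
    i = np.arange(1, len(p) + 1, dtype=float)
    ngp = int(occ.sum())
    coarseness = 1.0 / max((p * s).sum(), _EPS)
    if ngp > 1:
        pi_, si_, ii_ = p[occ], s[occ], i[occ]
        dif2 = (ii_[:, None] - ii_[None, :]) ** 2
        pp = pi_[:, None] * pi_[None, :]
        contrast = float((pp * dif2).sum() / (ngp * (ngp - 1)) * s.sum() / n_valid)
        ipi = ii_ * pi_
        busy_den = np.abs(ipi[:, None] - ipi[None, :]).sum()
        busyness = float((p * s).sum() / max(busy_den, _EPS))
        pspj = pi_[:, None] * si_[:, None] + pi_[None, :] * si_[None, :]
        complexity = float(
            (np.abs(ii_[:, None] - ii_[None, :]) * pspj / (pi_[:, None] + pi_[None, :])).sum()
            / n_valid
        )
        strength = float(
            ((pi_[:, None] + pi_[None, :]) * dif2).sum() / (_EPS + s.sum())
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngt_coarseness": float(coarseness),
        "ngt_contrast": contrast,
        "ngt_busyness": busyness,
        "ngt_complexity": complexity,
        "ngt_strength": strength,
    }


def _ngl_features(D: np.ndarray) -> dict[str, float]:
    ns = D.sum()
    j = np.arange(1, D.shape[1] + 1, dtype=float)  # j = k + 1
    dj = D.sum(axis=0)
    return {
        "ngl_low_dependence_emphasis": float((dj / j**2).sum() / ns),
        "ngl_high_dependence_emphasis": float((dj * j**2).sum() / ns),
        "ngl_dependence_count_entropy": _entropy((D / ns).ravel()),
        "ngl_dependence_count_nonuniformity": float((dj**2).sum() / ns),
    }


def extract_features(
    image: ImageVolume, mask: BinaryMask, config: ExtractionConfig
) -> FeatureVector:
    """Extract the full feature registry from an image + mask.

    Morphology and intensity statistics use raw voxels; the histogram and
    texture families use the discretised grey levels.
    """
    if not isinstance(config, ExtractionConfig):
        raise UsageError("config must be an ExtractionConfig")
    m = mask.voxels
    if not m.any():
        raise DataError("cannot extract features from an empty mask")
    if image.voxels.shape != m.shape:
        raise DataError("image and mask shapes differ")
    gvol = discretise(image, mask, config)
    x = image.voxels[m]
    nv = int(m.sum())

    values: dict[str, float] = {}
    values.update(_morph_features(mask))
    values.update(_stat_features(x))
    values.update(_ih_features(gvol.levels[m], gvol.Ng))
    values.update(_cm_features(_glcm(gvol)))
    values.update(_rlm_features(_glrlm(gvol), nv))
    values.update(_szm_features(_glszm(gvol), nv))
    values.update(_dzm_features(_gldzm(gvol)))
    ps = _ngtdm(gvol)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    ncnt = ndimage.correlate(m.astype(float), kernel, mode="constant", cval=0.0)
    n_valid = int((m & (ncnt > 0)).sum())
    values.update(_ngt_features(ps, n_valid))
    values.update(_ngl_features(_ngldm(gvol)))
    return FeatureVector(values=values, config=config, strategy_label=mask.strategy.label())
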