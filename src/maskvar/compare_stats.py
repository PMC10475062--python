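"""Pairwise feature comparison and cross-method stability statistics.

Raw feature values from two mask-generation strategies are compared with
a symmetric percentage difference

    P_d = 100 * |f_A - f_B| / |(f_A + f_B) / 2|

with two explicit conventions: matching zeros (f_A = f_B = 0) are defined
as having no variation (P_d = 0), and a zero mean with a nonzero
difference yields an undefined-value sentinel reported in the worst
category.  P_d values are binned into four half-open severity groups
([0, 0.5), [0.5, 3), [3, 10), [10, inf)) for heatmap display.

Cross-method stability uses Spearman's rank correlation (patient-ranking
stability per feature) and the intraclass correlation ICC(2,1) — two-way
random-effects, absolute-agreement, single-rater — with each mask
generation method as a rater and each patient as a subject.
"""

from __future__ import annotations

import math


import numpy as np

from .errors import DataError, UsageError

__all__ = [
    "PD_SENTINEL",
    "CATEGORIES",
    "percent_difference",
    "categorise",
    "spearman_rho",
    "icc2",
]

#: undefined-P_d sentinel (zero mean, nonzero difference)
PD_SENTINEL = float("nan")

#: (label, colour, lower bound) of the half-open severity bins
CATEGORIES = (
    ("G1", "green", 0.0),
    ("G2", "yellow", 0.5),
    ("G3", "orange", 3.0),
    ("G4", "red", 10.0),
)


def percent_difference(f_a: float, f_b: float) -> float:
    """Symmetric percentage difference P_d between two feature values.

    Returns 0 when both values are exactly 0 (no variation by
    definition) and the NaN sentinel when the mean is zero but the
    difference is not.
    """
    if f_a == 0.0 and f_b == 0.0:
        return 0.0
    mean = (f_a + f_b) / 2.0
    if mean == 0.0:
        return PD_SENTINEL
    return 100.0 * abs(f_a - f_b) / abs(mean)


def categorise(p_d: float) -> str:
    """Map a P_d value to its severity group G1..G4 (sentinel -> G4)."""
    if math.isnan(p_d):
        return "G4"
    if p_d < 0.0:
        raise UsageError(f"P_d must be non-negative, got {p_d}")
    label = "G1"
    for name, _, lo in CATEGORIES:
        if p_d >= lo:
            label = name
    return label


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation: Pearson correlation of average ranks.

    Ties receive average ranks.  Returns the NaN sentinel when either
    vector has zero rank variance (undefined, reported rather than
    silently dropped).
    """
    from scipy.stats import rankdata

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise UsageError("spearman_rho needs two equal-length vectors, n >= 3")
    rx, ry = rankdata(x), rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))


def icc2(ratings) -> float:
    """Intraclass correlation ICC(2,1): two-way random effects, absolute
    agreement, single rater.

    ``ratings`` is an (n subjects x k raters) matrix with no missing
    cells.  With MS_R the between-subject, MS_C the between-rater and
    MS_E the residual mean squares,

        ICC2 = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    A fully degenerate matrix (all cells equal) returns 1 by convention.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise UsageError("icc2 needs an (n>=2 subjects, k>=2 raters) matrix")
    if np.isnan(m).any():
        raise DataError("icc2 does not accept missing cells")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    # guard against tiny negative residuals from cancellation
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0.0:
        return 1.0  # all cells equal: perfect absolute agreement
    return float((ms_r - ms_e) / denom)
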