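"""Independent brute-force oracles used to validate the implementation.

Everything here is written in the most literal way possible (pure-Python
loops, direct definitions) and deliberately shares no code with the
package internals it checks.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# point in polygon: winding number


def winding_number_inside(point, polygon) -> bool:
    """Nonzero winding number membership (counts signed angle turns)."""
    px, py = point
    total = 0.0
    n = len(polygon)
    for k in range(n):
        x1, y1 = polygon[k]
        x2, y2 = polygon[(k + 1) % n]
        a1 = math.atan2(y1 - py, x1 - px)
        a2 = math.atan2(y2 - py, x2 - px)
        da = a2 - a1
        while da > math.pi:
            da -= 2 * math.pi
        while da < -math.pi:
            da += 2 * math.pi
        total += da
    return abs(total) > math.pi  # ~2*pi for inside, ~0 for outside


def dist_to_edges(point, polygon) -> float:
    """Minimum distance from a point to any polygon edge."""
    px, py = point
    best = math.inf
    n = len(polygon)
    for k in range(n):
        x1, y1 = polygon[k]
        x2, y2 = polygon[(k + 1) % n]
        dx, dy = x2 - x1, y2 - y1
        denom = dx * dx + dy * dy
        t = 0.0 if denom == 0 else max(0.0, min(1.0, ((px - x1) * dx + (py - y1) * dy) / denom))
        best = min(best, math.hypot(px - (x1 + t * dx), py - (y1 + t * dy)))
    return best


def random_simple_polygon(rng, n_vertices=8, radius=5.0) -> np.ndarray:
    """Star-shaped (hence simple) polygon around a random centre."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(0.3 * radius, radius, n_vertices)
    cx, cy = rng.uniform(-2, 2, 2)
    return np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])


# ---------------------------------------------------------------------------
# texture matrices by exhaustive enumeration

_ALL_26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]
_DIRS_13 = [d for d in _ALL_26 if d > (0, 0, 0)]


def _in_bounds(pos, shape):
    return all(0 <= p < s for p, s in zip(pos, shape))


def glcm_oracle(levels, mask, ng) -> np.ndarray:
    """Count every ordered in-mask level pair at the 13 offsets +/-."""
    M = np.zeros((ng, ng))
    shape = levels.shape
    for r in range(shape[0]):
        for c in range(shape[1]):
            for s in range(shape[2]):
                if not mask[r, c, s]:
                    continue
                for d in _DIRS_13:
                    for sign in (1, -1):
                        q = (r + sign * d[0], c + sign * d[1], s + sign * d[2])
                        if _in_bounds(q, shape) and mask[q]:
                            M[levels[r, c, s] - 1, levels[q] - 1] += 1
    return M


def glrlm_oracle(levels, mask, ng) -> np.ndarray:
    """Enumerate maximal same-level runs along each of the 13 directions."""
    shape = levels.shape
    runs = []
    for d in _DIRS_13:
        for r in range(shape[0]):
            for c in range(shape[1]):
                for s in range(shape[2]):
                    if not mask[r, c, s]:
                        continue
                    prev = (r - d[0], c - d[1], s - d[2])
                    if (
                        _in_bounds(prev, shape)
                        and mask[prev]
                        and levels[prev] == levels[r, c, s]
                    ):
                        continue  # not a run start
                    length = 1
                    cur = (r, c, s)
                    while True:
                        nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                        if (
                            _in_bounds(nxt, shape)
                            and mask[nxt]
                            and levels[nxt] == levels[r, c, s]
                        ):
                            length += 1
                            cur = nxt
                        else:
                            break
                    runs.append((levels[r, c, s], length))
    max_len = max(l for _, l in runs)
    R = np.zeros((ng, max_len))
    for g, l in runs:
        R[g - 1, l - 1] += 1
    return R


def _zones_oracle(levels, mask, ng):
    """26-connected constant-level zones by BFS flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for r in range(shape[0]):
        for c in range(shape[1]):
            for s in range(shape[2]):
                if not mask[r, c, s] or seen[r, c, s]:
                    continue
                g = levels[r, c, s]
                stack = [(r, c, s)]
                seen[r, c, s] = True
                members = []
                while stack:
                    p = stack.pop()
                    members.append(p)
                    for d in _ALL_26:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if (
                            _in_bounds(q, shape)
                            and mask[q]
                            and not seen[q]
                            and levels[q] == g
                        ):
                            seen[q] = True
                            stack.append(q)
                zones.append((g, members))
    return zones


def glszm_oracle(levels, mask, ng) -> np.ndarray:
    zones = _zones_oracle(levels, mask, ng)
    max_size = max(len(m) for _, m in zones)
    S = np.zeros((ng, max_size))
    for g, members in zones:
        S[g - 1, len(members) - 1] += 1
    return S


def gldzm_oracle(levels, mask, ng) -> np.ndarray:
    """Zone distance = min over zone of city-block steps to outside."""
    shape = levels.shape

    def border_dist(p):
        best = math.inf
        for r in range(-(shape[0] + 1), shape[0] + 2):
            for c in range(-(shape[1] + 1), shape[1] + 2):
                for s in range(-(shape[2] + 1), shape[2] + 2):
                    q = (r, c, s)
                    outside = not _in_bounds(q, shape) or not mask[q]
                    if outside:
                        best = min(
                            best,
                            abs(q[0] - p[0]) + abs(q[1] - p[1]) + abs(q[2] - p[2]),
                        )
        return max(1, best)

    zones = _zones_oracle(levels, mask, ng)
    dists = [(g, min(border_dist(p) for p in members)) for g, members in zones]
    max_d = max(d for _, d in dists)
    D = np.zeros((ng, max_d))
    for g, d in dists:
        D[g - 1, d - 1] += 1
    return D


def ngtdm_oracle(levels, mask, ng) -> np.ndarray:
    """Rows [p_i, s_i] from per-voxel valid 26-neighbourhood means."""
    shape = levels.shape
    s = np.zeros(ng)
    n = np.zeros(ng)
    n_valid = 0
    for r in range(shape[0]):
        for c in range(shape[1]):
            for sl in range(shape[2]):
                if not mask[r, c, sl]:
                    continue
                nb = [
                    levels[r + d[0], c + d[1], sl + d[2]]
                    for d in _ALL_26
                    if _in_bounds((r + d[0], c + d[1], sl + d[2]), shape)
                    and mask[r + d[0], c + d[1], sl + d[2]]
                ]
                if not nb:
                    continue
                n_valid += 1
                g = levels[r, c, sl]
                n[g - 1] += 1
                s[g - 1] += abs(g - sum(nb) / len(nb))
    p = n / n_valid if n_valid else n
    return np.column_stack([p, s])


def ngldm_oracle(levels, mask, ng) -> np.ndarray:
    """Counts of (level, #identical-level 26-neighbours) per voxel."""
    shape = levels.shape
    entries = []
    for r in range(shape[0]):
        for c in range(shape[1]):
            for sl in range(shape[2]):
                if not mask[r, c, sl]:
                    continue
                g = levels[r, c, sl]
                k = sum(
                    1
                    for d in _ALL_26
                    if _in_bounds((r + d[0], c + d[1], sl + d[2]), shape)
                    and mask[r + d[0], c + d[1], sl + d[2]]
                    and levels[r + d[0], c + d[1], sl + d[2]] == g
                )
                entries.append((g, k))
    kmax = max(k for _, k in entries)
    D = np.zeros((ng, kmax + 1))
    for g, k in entries:
        D[g - 1, k] += 1
    return D


# ---------------------------------------------------------------------------
# ICC(2,1) via an explicit two-way ANOVA table


def icc2_anova_oracle(m) -> float:
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = m.mean()
    ms_r = sum(k * (m[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    ms_c = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (m[i, j] - m[i].mean() - m[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    ms_e = sse / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))


# ---------------------------------------------------------------------------
# complete linkage by direct recomputation


def complete_linkage_heights(x) -> list[float]:
    """Merge heights from a literal complete-linkage agglomeration."""
    x = np.asarray(x, dtype=float)
    clusters = [[i] for i in range(len(x))]
    heights = []

    def cdist(a, b):
        return max(
            float(np.linalg.norm(x[i] - x[j])) for i in a for j in b
        )

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cdist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        clusters.pop(j)
    return heights
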