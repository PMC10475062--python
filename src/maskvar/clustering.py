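"""Z-score scaling, complete-linkage clustering and dendrogram entanglement.

Patients are clustered on Z-scored feature columns with agglomerative
complete-linkage clustering (Euclidean distance).  Two dendrograms over
the same patients are compared by *entanglement*: the L-norm of the
differences between each label's leaf positions in the two trees,
normalised by the worst case (one order the exact reverse of the other).
Entanglement is 0 iff the leaf orders match and 1 for a full reversal.

The linkage is implemented directly (O(n^3), fine for cohort-sized n) so
that tie-breaking is fully pinned down: patients are ranked by sorted
label; among minimum-distance cluster pairs the one with the
lexicographically smallest (minimum patient rank) pair merges first, and
at each merge the subtree containing the smaller patient rank is placed
on the left.  Leaf orders — and hence entanglement — are therefore
reproducible and independent of the input row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, UsageError

__all__ = ["Dendrogram", "zscore_scale", "hclust_complete", "entanglement"]


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration tree over patient labels.

    ``merges`` holds (left_node, right_node, height, new_node) tuples
    with nodes 0..n-1 the leaves (in input order) and n.. the merged
    clusters; ``leaf_order`` is the left-to-right label sequence.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]
    leaf_order: tuple[str, ...]

    @property
    def heights(self) -> tuple[float, ...]:
        return tuple(m[2] for m in self.merges)

    def to_newick(self) -> str:
        """Serialise with branch lengths derived from merge heights."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for left, right, h, new in self.merges:
            bl_l = h - height[left]
            bl_r = h - height[right]
            node[new] = f"({node[left]}:{bl_l:g},{node[right]}:{bl_r:g})"
            height[new] = h
        root = self.merges[-1][3] if self.merges else 0
        return node[root] + ";"


def zscore_scale(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature column (mean 0, population sd 1).

    Constant columns become all-zero and are flagged in
    ``result.attrs["constant_columns"]``.
    """
    if len(table) < 2:
        raise UsageError("zscore_scale needs at least 2 patients")
    mu = table.mean(axis=0)
    sd = table.std(axis=0, ddof=0)
    constant = sd[sd == 0.0].index.tolist()
    sd_safe = sd.replace(0.0, 1.0)
    out = (table - mu) / sd_safe
    out[constant] = 0.0
    out.attrs["constant_columns"] = constant
    return out


def hclust_complete(table: pd.DataFrame) -> Dendrogram:
    """Complete-linkage agglomerative clustering of the table's rows.

    Distances are Euclidean; the input is expected to be Z-scored
    already (this function does not rescale).
    """
    labels = tuple(str(i) for i in table.index)
    n = len(labels)
    if n < 2:
        raise UsageError("clustering needs at least 2 patients")
    x = table.to_numpy(dtype=float)
    diff = x[:, None, :] - x[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    # intrinsic patient rank (sorted label order), so ties and leaf
    # placement do not depend on the input row order
    rank = {i: r for r, i in enumerate(sorted(range(n), key=lambda i: labels[i]))}

    # active cluster id -> (member leaf set, min patient rank, node id)
    clusters: dict[int, tuple[frozenset[int], int, int]] = {
        i: (frozenset([i]), rank[i], i) for i in range(n)
    }
    cdist: dict[tuple[int, int], float] = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float, int]] = []
    order: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_node = n
    while len(clusters) > 1:
        # minimum-distance pair; ties -> smallest (min original index) pair
        best = min(
            cdist.items(),
            key=lambda kv: (kv[1], clusters[kv[0][0]][1], clusters[kv[0][1]][1]),
        )
        (a, b), h = best
        set_a, min_a, node_a = clusters[a]
        set_b, min_b, node_b = clusters[b]
        if min_b < min_a:
            a, b = b, a
            set_a, min_a, node_a, set_b, min_b, node_b = (
                set_b, min_b, node_b, set_a, min_a, node_a,
            )
        merges.append((node_a, node_b, h, next_node))
        merged = set_a | set_b
        new_id = min(a, b)
        other_id = max(a, b)
        order[new_id] = order[a] + order[b]
        clusters.pop(other_id)
        clusters[new_id] = (merged, min(min_a, min_b), next_node)
        next_node += 1
        for key in [k for k in cdist if other_id in k or new_id in k]:
            cdist.pop(key)
        for cid, (members, _, _) in clusters.items():
            if cid == new_id:
                continue
            key = (min(cid, new_id), max(cid, new_id))
            cdist[key] = float(
                dist[np.ix_(sorted(merged), sorted(members))].max()
            )
    leaf_order = tuple(labels[i] for i in order[next(iter(clusters))])
    return Dendrogram(labels=labels, merges=tuple(merges), leaf_order=leaf_order)


def entanglement(d1: Dendrogram, d2: Dendrogram, L: float = 1.0) -> float:
    """Normalised leaf-position disagreement between two dendrograms.

    With pos1/pos2 the 1-based positions of each label in the two leaf
    orders,

        sum_i |pos1(i) - pos2(i)|**L / sum_i |i - (n+1-i)|**L

    where the denominator is the worst case of one order being the exact
    reverse of the other.  0 iff identical orders; symmetric; in [0, 1].
    """
    if L <= 0:
        raise UsageError("L must be positive")
    if set(d1.leaf_order) != set(d2.leaf_order):
        raise DataError("dendrograms have different label sets")
    n = len(d1.leaf_order)
    pos2 = {lab: i + 1 for i, lab in enumerate(d2.leaf_order)}
    num = sum(
        abs((i + 1) - pos2[lab]) ** L for i, lab in enumerate(d1.leaf_order)
    )
    i = np.arange(1, n + 1, dtype=float)
    den = float(np.sum(np.abs(i - (n + 1 - i)) ** L))
    if den == 0.0:
        return 0.0
    return float(num / den)
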