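"""Genetic distances and neighbor-joining tree reconstruction.

The distance between two individuals is the allele-sharing (IBS-based)
distance: the mean over co-called sites of |dosage_i - dosage_j| / 2,
bounded in [0, 1] and free of phase assumptions.  Trees are built with
the canonical Saitou–Nei neighbor-joining algorithm, which is consistent
on additive distances — the property the test suite uses as its oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix

logger = logging.getLogger("sweepscan")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal not zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass
class Tree:
    """Unrooted tree with labelled leaves and branch lengths.

    Stored as an adjacency map node -> {neighbor: branch length}; leaves
    carry labels.  Internal nodes of an NJ tree have degree 3.
    """

    adjacency: dict[int, dict[int, float]] = field(default_factory=dict)
    leaf_label: dict[int, str] = field(default_factory=dict)

    def add_edge(self, u: int, v: int, length: float) -> None:
        self.adjacency.setdefault(u, {})[v] = length
        self.adjacency.setdefault(v, {})[u] = length

    def leaf_labels(self) -> list[str]:
        return [self.leaf_label[n] for n in sorted(self.leaf_label)]

    def leaf_branch_lengths(self) -> dict[str, float]:
        return {
            lbl: next(iter(self.adjacency[n].values()))
            for n, lbl in self.leaf_label.items()
        }

    def splits(self) -> set[frozenset[str]]:
        """Leaf bipartitions induced by internal edges (topology signature)."""
        labels = set(self.leaf_label.values())
        out: set[frozenset[str]] = set()
        for u in self.adjacency:
            for v in self.adjacency[u]:
                if u < v:
                    side = self._leaves_beyond(u, v)
                    if 1 < len(side) < len(labels) - 1:
                        out.add(frozenset(side))
        # canonicalize: keep the lexicographically smaller side
        canon = set()
        for s in out:
            other = frozenset(labels - s)
            canon.add(min(s, other, key=lambda x: sorted(x)))
        return canon

    def _leaves_beyond(self, u: int, v: int) -> set[str]:
        """Leaves on v's side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        leaves = set()
        while stack:
            node = stack.pop()
            if node in self.leaf_label:
                leaves.add(self.leaf_label[node])
            for nxt in self.adjacency[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return leaves

    def leaf_distances(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        leaves = sorted(self.leaf_label)
        n = len(leaves)
        d = np.zeros((n, n))
        for a, la in enumerate(leaves):
            dist = {la: 0.0}
            stack = [la]
            while stack:
                node = stack.pop()
                for nxt, ln in self.adjacency[node].items():
                    if nxt not in dist:
                        dist[nxt] = dist[node] + ln
                        stack.append(nxt)
            for b, lb in enumerate(leaves):
                d[a, b] = dist[lb]
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix([self.leaf_label[x] for x in leaves], d)

    def to_newick(self) -> str:
        # root at an internal node (any node not a leaf), or at a leaf's
        # neighbor for tiny trees
        internal = [n for n in self.adjacency if n not in self.leaf_label]
        root = internal[0] if internal else min(self.adjacency)

        def emit(node: int, parent: int | None) -> str:
            children = [v for v in sorted(self.adjacency[node]) if v != parent]
            if not children:
                return self.leaf_label[node]
            inner = ",".join(
                f"{emit(c, node)}:{self.adjacency[node][c]:.10g}" for c in children
            )
            return f"({inner})"

        return emit(root, None) + ";"


# ---------------------------------------------------------------------------
# IBS distance
# ---------------------------------------------------------------------------

def ibs_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise allele-sharing distance matrix over all samples.

    d(i, j) = mean over co-called sites of |dosage_i - dosage_j| / 2.
    A pair with no co-called site is an error.
    """
    if gm.n_samples < 3:
        raise ValueError("distance matrix needs >= 3 samples")
    calls = gm.calls.astype(np.int16)
    called = calls >= 0
    n = gm.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called[i + 1:]
        diff = np.abs(calls[i] - calls[i + 1:]) * both
        co = both.sum(axis=1)
        if (co == 0).any():
            j = int(np.flatnonzero(co == 0)[0]) + i + 1
            raise ValueError(
                f"samples {gm.sample_ids[i]!r} and {gm.sample_ids[j]!r} share no called site"
            )
        d[i, i + 1:] = diff.sum(axis=1) / (2.0 * co)
    d = d + d.T
    return DistanceMatrix(list(gm.sample_ids), d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Canonical Saitou–Nei neighbor joining.

    Iteratively joins the pair minimizing the Q-criterion, with branch
    lengths from the standard two-point formulas, reducing the matrix
    until three nodes remain (closed form).  Ties in Q are broken by the
    lowest (i, j) index pair, making the output deterministic.  Negative
    branch lengths are clamped to 0 with a warning.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("non-finite distances")

    tree = Tree()
    for i, label in enumerate(dm.labels):
        tree.leaf_label[i] = label
        tree.adjacency.setdefault(i, {})

    def clamp(x: float) -> float:
        if x < 0:
            logger.warning(
                "neighbor_joining negative branch length %.3g clamped to 0", x
            )
            return 0.0
        return x

    nodes = list(range(n0))  # node ids aligned with rows/cols of D
    D = dm.d.copy()
    next_id = n0

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = (0, 1)
        best_q = np.inf
        for a in range(m):
            for b in range(a + 1, m):
                qab = (m - 2) * D[a, b] - r[a] - r[b]
                if qab < best_q - 1e-15:
                    best_q = qab
                    best = (a, b)
        a, b = best
        dij = D[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        new = next_id
        next_id += 1
        tree.add_edge(nodes[a], new, clamp(li))
        tree.add_edge(nodes[b], new, clamp(lj))

        keep = [k for k in range(m) if k not in (a, b)]
        d_new = 0.5 * (D[a, keep] + D[b, keep] - dij)
        reduced = np.zeros((m - 1, m - 1))
        reduced[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        reduced[m - 2, : m - 2] = d_new
        reduced[: m - 2, m - 2] = d_new
        D = reduced
        nodes = [nodes[k] for k in keep] + [new]

    # three remaining nodes: closed-form three-point formulas
    da, db, dc = D[0, 1], D[0, 2], D[1, 2]
    center = next_id
    tree.add_edge(nodes[0], center, clamp(0.5 * (da + db - dc)))
    tree.add_edge(nodes[1], center, clamp(0.5 * (da + dc - db)))
    tree.add_edge(nodes[2], center, clamp(0.5 * (db + dc - da)))
    return tree
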