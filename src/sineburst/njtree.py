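"""Neighbor-joining trees of subfamily consensus sequences.

Distances are p-distances from pairwise global alignments (mismatches plus
indel events over aligned columns); the tree is built with the classic
Saitou-Nei agglomeration (Q-matrix minimization), with deterministic
tie-breaking (lexicographically smallest joined pair) and negative branch
lengths clamped to zero.  The Newick leaf order doubles as the stacking
order for divergence-histogram reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._align import align_stats, make_aligner


@dataclass
class Node:
    name: str = ""
    children: list[tuple["Node", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


def pairwise_distances(library: dict[str, str],
                       match: int = 2, mismatch: int = -3,
                       gap_open: int = -5, gap_extend: int = -1,
                       ) -> tuple[list[str], np.ndarray]:
    """p-distance matrix over all consensus pairs by global alignment."""
    sequences = getattr(library, "sequences", library)
    labels = list(sequences)
    if len(labels) < 2:
        raise ValueError("need at least 2 consensuses")
    for name, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty consensus sequence for {name!r}")
    aligner = make_aligner(match, mismatch, gap_open, gap_extend, mode="global")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            stats = align_stats(aligner, sequences[labels[i]], sequences[labels[j]])
            aligned = stats.identities + stats.mismatches
            dist = (stats.mismatches + stats.gap_events) / aligned if aligned else 1.0
            d[i, j] = d[j, i] = dist
    return labels, d


def neighbor_joining(labels: list[str], d: np.ndarray) -> Node:
    """Saitou-Nei NJ.  Ties in Q pick the lexicographically smallest pair
    (by the smallest leaf name each subtree contains); negative branch
    lengths are clamped to 0 with a warning."""
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    nodes: list[Node] = [Node(name=l) for l in labels]
    reps: list[str] = list(labels)        # smallest leaf name per subtree
    dm = d.copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn("negative NJ branch length clamped to 0")
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dm[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * dm[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((reps[i], reps[j])))
                if best is None or q < best[0] - 1e-12 or (
                        abs(q - best[0]) <= 1e-12 and pair_key < best[1]):
                    best = (q, pair_key, i, j)
        _, _, i, j = best
        li = clamp(dm[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(dm[i, j] - dm[i, j] / 2 - (r[i] - r[j]) / (2 * (m - 2)))
        parent = Node(children=[(nodes[i], li), (nodes[j], lj)])
        k = len(nodes)
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        dm = np.pad(dm, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            dm[k, x] = dm[x, k] = (dm[i, x] + dm[j, x] - dm[i, j]) / 2
        active = [x for x in active if x not in (i, j)] + [k]

    i, j, k = active
    # three-point formulas for the final star
    li = clamp((dm[i, j] + dm[i, k] - dm[j, k]) / 2)
    lj = clamp((dm[i, j] + dm[j, k] - dm[i, k]) / 2)
    lk = clamp((dm[i, k] + dm[j, k] - dm[i, j]) / 2)
    order = sorted([(reps[i], i, li), (reps[j], j, lj), (reps[k], k, lk)])
    root = Node(children=[(nodes[x], l) for _, x, l in order])
    return root


def newick(tree: Node, digits: int = 6) -> str:
    def fmt(node: Node) -> str:
        if node.is_leaf:
            return node.name
        inner = ",".join(f"{fmt(c)}:{l:.{digits}g}" for c, l in node.children)
        return f"({inner})"

    return fmt(tree) + ";"


def leaf_order(tree: Node) -> list[str]:
    """Stacking order for divergence histograms: Newick traversal order."""
    return tree.leaves()


def tree_distances(tree: Node) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix (for additivity checks)."""
    leaves = tree.leaves()
    n = len(leaves)
    index = {name: i for i, name in enumerate(leaves)}
    dm = np.zeros((n, n))

    def down(node: Node) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        merged: dict[str, float] = {}
        sub = []
        for child, length in node.children:
            dists = {k: v + length for k, v in down(child).items()}
            sub.append(dists)
            merged.update(dists)
        for a_i in range(len(sub)):
            for b_i in range(a_i + 1, len(sub)):
                for la, va in sub[a_i].items():
                    for lb, vb in sub[b_i].items():
                        dm[index[la], index[lb]] = dm[index[lb], index[la]] = va + vb
        return merged

    down(tree)
    return leaves, dm
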