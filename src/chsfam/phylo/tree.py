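"""Neighbor joining, bipartitions and bootstrap support.

The tree builder is standard neighbor joining (Saitou-Nei Q-criterion) with
two determinism rules: ties in Q are broken by the lexicographically smallest
cluster-label pair (a cluster is labelled by its smallest leaf name), and
negative branch lengths are clamped to zero with the deficit transferred to
the sister branch.  Bootstrap support of an internal edge is the percentage
of column-resampled replicate trees containing the same (unrooted)
bipartition.
"""

from __future__ import annotations

import numpy as np

from ..io_formats import Tree, TreeNode
from .align import Alignment
from .distance import DistanceMatrix, compute_distances

__all__ = [
    "build_nj_tree",
    "bipartition_sets",
    "annotate_supports",
    "bootstrap_support",
    "bootstrap_from_alignment",
]


def build_nj_tree(D: DistanceMatrix) -> Tree:
    """Neighbor joining on >= 3 taxa; returns an unrooted tree represented
    with a trifurcating root."""
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    d = D.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=name) for name in D.ids]
    labels: list[str] = list(D.ids)  # cluster label = min leaf name inside
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0.0, atol=1e-12))
        best = min(
            (tuple(sorted((labels[active[i]], labels[active[j]]))), i, j)
            for i, j in ties
            if i < j
        )
        _, ai, aj = best
        i, j = active[ai], active[aj]

        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0

        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj

        dk = 0.5 * (d[i, active] + d[j, active] - dij)
        d[i, active] = dk
        d[active, i] = dk
        d[i, i] = 0.0
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    a, b, c = active
    # three-point formulas for the final star
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(0.0, float(length))
    order = sorted((a, b, c), key=lambda k: labels[k])
    root = TreeNode(children=[nodes[k] for k in order])
    return Tree(root=root)


def _canonical(side: frozenset[str], all_leaves: frozenset[str]) -> frozenset[str]:
    """Canonicalise a bipartition by the side not containing the smallest
    leaf name (so both orientations map to one key)."""
    anchor = min(all_leaves)
    return side if anchor not in side else all_leaves - side


def bipartition_sets(tree: Tree) -> dict[frozenset[str], TreeNode]:
    """Map each internal (non-trivial) bipartition to the child node whose
    subtree defines it."""
    all_leaves = frozenset(tree.leaf_names())
    out: dict[frozenset[str], TreeNode] = {}

    def visit(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.label or ""])
        below = frozenset().union(*(visit(c) for c in node.children))
        if node is not tree.root and 1 < len(below) < len(all_leaves) - 1:
            out[_canonical(below, all_leaves)] = node
        return below

    visit(tree.root)
    return out


def annotate_supports(tree: Tree, supports: dict[frozenset[str], float]) -> Tree:
    """Label internal edges of *tree* with support percentages in place."""
    for split, node in bipartition_sets(tree).items():
        if split in supports:
            node.label = f"{supports[split]:g}"
    return tree


def bootstrap_from_alignment(
    aln: Alignment,
    n_reps: int,
    seed: int | np.random.Generator,
    *,
    site_rule: str = "partial_deletion",
    coverage: float = 0.95,
    correction: str | None = None,
) -> tuple[Tree, dict[frozenset[str], float]]:
    """Point-estimate NJ tree plus bootstrap supports for its bipartitions.

    Columns are resampled with replacement per replicate; supports are
    percentages in [0, 100], reproducible for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def dist(a: Alignment) -> DistanceMatrix:
        return compute_distances(
            a, site_rule, coverage=coverage, correction=correction
        )

    point = build_nj_tree(dist(aln))
    point_splits = bipartition_sets(point)
    counts = {split: 0 for split in point_splits}

    L = aln.n_columns
    arr = aln.to_array()
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep_rows = tuple("".join(row) for row in arr[:, cols])
        rep_aln = Alignment(ids=aln.ids, rows=rep_rows)
        rep_splits = bipartition_sets(build_nj_tree(dist(rep_aln)))
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    supports = {split: 100.0 * c / n_reps for split, c in counts.items()}
    annotate_supports(point, supports)
    return point, supports


def bootstrap_support(
    regions,
    n_reps: int = 100,
    seed: int | np.random.Generator = 0,
    **dist_kwargs,
) -> Tree:
    """Align CON1 regions, build the NJ tree and annotate bootstrap supports."""
    from .align import align_con1

    aln = align_con1(regions)
    tree, _ = bootstrap_from_alignment(aln, n_reps, seed, **dist_kwargs)
    return tree
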