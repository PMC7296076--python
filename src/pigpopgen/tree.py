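"""Neighbor-joining trees from distance matrices, with SNP-bootstrap support.

The agglomeration is the standard Saitou–Nei algorithm on the Q-criterion.
Two deterministic conventions are fixed: ties in Q are broken by the lowest
active-node index pair, and negative branch lengths are clamped to zero with
the deficit transferred to the sibling edge (keeping the pair's summed length
equal to their distance), which keeps Newick output valid.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix, allele_sharing_distance
from .plink import GenotypePanel


@dataclass
class TreeNode:
    name: str | None = None
    children: list = field(default_factory=list)  # [(TreeNode, branch_length)]

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaf_names())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree held at an internal trifurcation, with optional supports.

    ``support`` maps canonical bipartitions (frozenset of the side not
    containing the reference leaf, which is the lexicographically smallest
    leaf name) to bootstrap fractions.
    """

    root: TreeNode
    support: dict = field(default_factory=dict)

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def _reference(self) -> str:
        return min(self.leaf_names())

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions as canonical frozensets of leaf names."""
        all_leaves = set(self.leaf_names())
        ref = min(all_leaves)
        out: set[frozenset] = set()

        def visit(node: TreeNode) -> set:
            if node.is_leaf:
                return {node.name}
            below: set = set()
            for child, _ in node.children:
                below |= visit(child)
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if ref not in below else all_leaves - below
                out.add(frozenset(side))
            return below

        visit(self.root)
        return out

    def newick(self, include_support: bool = False) -> str:
        all_leaves = set(self.leaf_names())
        ref = min(all_leaves)

        def fmt(node: TreeNode, length: float | None) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, bl) for c, bl in node.children)
                label = ""
                if include_support:
                    below = set(node.leaf_names())
                    side = below if ref not in below else all_leaves - below
                    sup = self.support.get(frozenset(side))
                    if sup is not None:
                        label = f"{sup:g}"
                body = f"({inner}){label}"
            return body if length is None else f"{body}:{length:.10g}"

        return fmt(self.root, None) + ";"


def neighbor_joining(dist: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking."""
    n = len(dist.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dist.values)):
        raise ValueError("non-finite distances")

    d = dist.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dist.ids]
    active = list(range(n))

    def clamp_pair(li: float, lj: float, dij: float) -> tuple[float, float]:
        # negative lengths clamped to 0, deficit moved to the sibling edge
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        return li, lj

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2.0) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: scan row-major over the active ordering
        flat = np.argmin(q)
        qmin = q.flat[flat]
        ii, jj = np.nonzero(np.isclose(q, qmin, rtol=0, atol=1e-12))
        pick = min((a, b) for a, b in zip(ii, jj) if a < b)
        ai, aj = pick
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2.0))
        lj = dij - li
        li, lj = clamp_pair(li, lj, dij)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_idx = len(nodes)
        nodes.append(new)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            duk = (d[i, k] + d[j, k] - dij) / 2.0
            d[new_idx, k] = d[k, new_idx] = duk
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j, k = active
    b1 = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    b2 = d[i, j] - b1
    b3 = d[i, k] - b1
    b1, b2, b3 = (max(b, 0.0) for b in (b1, b2, b3))
    root = TreeNode(children=[(nodes[i], b1), (nodes[j], b2), (nodes[k], b3)])
    return PhyloTree(root=root)


def bootstrap_nj(
    panel: GenotypePanel, n_reps: int = 1000, seed: int = 0
) -> PhyloTree:
    """NJ tree from allele-sharing distances with SNP-column bootstrap supports.

    Supports are the fraction of replicate trees (SNP columns resampled with
    replacement) containing each bipartition of the point-estimate tree.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    point = neighbor_joining(allele_sharing_distance(panel))
    target = point.bipartitions()
    counts = {bp: 0 for bp in target}
    m = panel.n_variants
    ids = list(panel.samples["sample_id"])
    for _ in range(n_reps):
        cols = rng.integers(m, size=m)
        dist = _distance_no_meta(panel.genotypes[:, cols], ids)
        bps = neighbor_joining(dist).bipartitions()
        for bp in target:
            if bp in bps:
                counts[bp] += 1
    point.support = {bp: counts[bp] / n_reps for bp in target}
    return point


def _distance_no_meta(geno: np.ndarray, ids: list[str]) -> DistanceMatrix:
    d = geno.astype(float)
    d[geno == -1] = np.nan
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n - 1):
        diff = np.abs(d[i + 1:] - d[i])
        values[i, i + 1:] = values[i + 1:, i] = np.nanmean(diff, axis=1) / 2.0
    return DistanceMatrix(ids=ids, values=values)
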