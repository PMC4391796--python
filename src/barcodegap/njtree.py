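"""Neighbor-joining trees with nonparametric bootstrap support.

Saitou–Nei agglomeration with the rate-corrected selection criterion
Q(i,j) = (n-2) d(i,j) - r_i - r_j.  Tie-breaking is deterministic: among
minimal-Q pairs the pair whose clusters carry the lexicographically lowest
canonical leaf ids is joined, so identical inputs always yield identical
trees.  Negative branch lengths are clamped to zero and the clamp count kept
so additivity checks can assert zero clamps.

Bootstrap support resamples alignment columns with replacement, recomputes
the K2P matrix and NJ tree per replicate, and reports for each internal edge
the percentage of replicates containing the same bipartition of leaves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .distances import DistanceMatrix, GapMode, k2p_matrix
from .seqio import AlignedSet

logger = logging.getLogger(__name__)


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0  # branch length to parent
    children: list["Node"] = field(default_factory=list)
    support: float | None = None  # % of bootstrap replicates

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree (stored rooted at the final join) over leaf seq_ids."""

    root: Node
    n_clamped: int = 0  # negative branch lengths clamped to zero
    bootstrap_skipped: int = 0  # replicates skipped (undefined distances)

    @property
    def leaf_names(self) -> list[str]:
        return sorted(n.name for n in self.root.leaves())

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial splits, each canonicalised as the side not containing
        the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names)
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 2 <= len(below) <= len(all_leaves) - 2:
                side = below if anchor not in below else all_leaves - below
                out.add(side)
            return below

        walk(self.root)
        return out

    def _edge_nodes(self) -> dict[frozenset[str], Node]:
        all_leaves = frozenset(self.leaf_names)
        anchor = min(all_leaves)
        found: dict[frozenset[str], Node] = {}

        def walk(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 2 <= len(below) <= len(all_leaves) - 2:
                side = below if anchor not in below else all_leaves - below
                found[side] = node
            return below

        walk(self.root)
        return found

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the leaf-to-leaf path."""

        def down(node: Node, name: str) -> float | None:
            # distance from *node* down to the named leaf (lengths of all
            # nodes strictly below, including the leaf's own branch)
            if node.is_leaf:
                return 0.0 if node.name == name else None
            for c in node.children:
                r = down(c, name)
                if r is not None:
                    return r + c.length
            return None

        def at_lca(node: Node) -> float | None:
            for c in node.children:
                r = at_lca(c)
                if r is not None:
                    return r
            pa, pb = down(node, a), down(node, b)
            if pa is not None and pb is not None:
                return pa + pb
            return None

        r = at_lca(self.root)
        if r is None:
            raise KeyError((a, b))
        return r

    def to_newick(self, support_floor: float | None = None,
                  member_counts: dict[str, int] | None = None) -> str:
        """Newick string; support printed as internal labels only when
        >= support_floor; leaves with N>1 collapsed members suffixed 'Nind'."""

        def label(name: str) -> str:
            n = (member_counts or {}).get(name, 1)
            return f"{name}_{n}ind" if n > 1 else name

        def fmt(node: Node, top: bool) -> str:
            if node.is_leaf:
                return f"{label(node.name)}:{node.length:.10g}"
            inner = ",".join(fmt(c, False) for c in node.children)
            sup = ""
            if (node.support is not None and support_floor is not None
                    and node.support >= support_floor):
                sup = f"{node.support:.10g}"
            elif node.support is not None and support_floor is None:
                sup = f"{node.support:.10g}"
            if top:
                return f"({inner}){sup}"
            return f"({inner}){sup}:{node.length:.10g}"

        return fmt(self.root, True) + ";"


def nj(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a fully defined distance matrix."""
    n = len(dm)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if dm.undefined_pairs:
        pair = sorted(next(iter(dm.undefined_pairs)))
        raise ValueError(
            f"undefined distance between {pair[0]!r} and {pair[1]!r}; "
            "collapse or drop saturated sequences before tree building")
    D = dm.values.copy()
    nodes = [Node(name=i) for i in dm.ids]
    keys = list(dm.ids)  # canonical tie-break key: smallest leaf id in cluster
    active = list(range(n))
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0.0:
            clamped += 1
            logger.debug("clamped negative branch length %.3g to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((keys[active[a]], keys[active[b]]))), (a, b))
            for a, b in cand if a < b
        )[1]
        ai, bi = best
        i, j = active[ai], active[bi]
        dij = D[i, j]
        vi = 0.5 * dij + (r[ai] - r[bi]) / (2.0 * (m - 2))
        vj = dij - vi
        u = Node(children=[nodes[i], nodes[j]])
        nodes[i].length = clamp(vi)
        nodes[j].length = clamp(vj)
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = 0.0
        nodes[i] = u
        keys[i] = min(keys[i], keys[j])
        active.remove(j)

    if len(active) == 3:
        i, j, k = active
        vi = clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
        vj = clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
        vk = clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
        nodes[i].length, nodes[j].length, nodes[k].length = vi, vj, vk
        root = Node(children=[nodes[i], nodes[j], nodes[k]])
    else:
        i, j = active
        half = D[i, j] / 2.0
        nodes[i].length = nodes[j].length = clamp(half)
        root = Node(children=[nodes[i], nodes[j]])
    return PhyloTree(root, n_clamped=clamped)


def bootstrap_support(aligned: AlignedSet, n_reps: int = 1000,
                      seed: int | None = None,
                      gap_mode: GapMode = "pairwise_deletion") -> PhyloTree:
    """NJ tree with bootstrap support on the original alignment.

    Columns are resampled with replacement from a single seeded stream in a
    fixed replicate order, so identical seeds yield bit-identical support.
    Replicates whose resampled matrix contains undefined distances are
    skipped and counted in :attr:`PhyloTree.bootstrap_skipped`.
    """
    if n_reps > 0 and seed is None:
        raise ValueError("a seed is mandatory when bootstrapping")
    dm = k2p_matrix(aligned, gap_mode=gap_mode)
    tree = nj(dm)
    if n_reps <= 0:
        return tree
    rng = np.random.default_rng(seed)
    L = aligned.length
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    skipped = 0
    records = aligned.records
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        resampled = AlignedSet(
            [type(r)(seq_id=r.seq_id,
                     residues="".join(r.residues[c] for c in cols),
                     marker=r.marker)
             for r in records],
            marker=aligned.marker)
        try:
            rep_dm = k2p_matrix(resampled, gap_mode=gap_mode)
            if rep_dm.undefined_pairs:
                skipped += 1
                continue
            rep_tree = nj(rep_dm)
        except ValueError:
            skipped += 1
            continue
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    ok = n_reps - skipped
    if skipped:
        logger.warning("%d/%d bootstrap replicates skipped "
                       "(undefined distances)", skipped, n_reps)
    edge_nodes = tree._edge_nodes()
    for bp, node in edge_nodes.items():
        node.support = 100.0 * counts.get(bp, 0) / ok if ok else math.nan
    tree.bootstrap_skipped = skipped
    return tree


def write_newick(tree: PhyloTree, path: str | Path,
                 support_floor: float = 80.0,
                 member_counts: dict[str, int] | None = None) -> None:
    """Write newick; only support values >= support_floor are printed, and
    collapsed-haplotype representatives get an 'Nind' member-count suffix."""
    Path(path).write_text(
        tree.to_newick(support_floor=support_floor,
                       member_counts=member_counts) + "\n")
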