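"""Neighbor joining: closed forms, additivity, bootstrap, newick output."""

import math

import numpy as np
import pytest

from barcodegap.distances import DistanceMatrix
from barcodegap.njtree import bootstrap_support, nj, write_newick

from conftest import make_dm


def additive_matrix_from_random_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths -> (ids, D, tree).

    Path lengths on a tree form an additive matrix; NJ must recover both
    topology (as bipartitions) and every leaf-to-leaf path length.
    """
    import itertools
    ids = [f"t{i}" for i in range(n_taxa)]
    # random sequential join
    nodes = {i: (i,) for i in range(n_taxa)}  # node -> leafset
    dist = {(i, i): 0.0 for i in range(n_taxa)}
    # build by random agglomeration with random positive lengths
    lengths = {}
    children = {}
    nxt = n_taxa
    active = list(range(n_taxa))
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        la, lb = rng.uniform(0.5, 3.0, size=2)
        children[nxt] = [(a, la), (b, lb)]
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1

    # leaf-to-leaf distances via recursion
    def leaf_dists(node):
        if node < n_taxa:
            return {node: 0.0}
        out = {}
        for child, ln in children[node]:
            for leaf, d in leaf_dists(child).items():
                out[leaf] = d + ln
        return out

    D = np.zeros((n_taxa, n_taxa))

    def fill(node):
        if node < n_taxa:
            return
        (a, la), (b, lb) = children[node]
        da, db = leaf_dists(a), leaf_dists(b)
        for x, dx in da.items():
            for y, dy in db.items():
                D[x, y] = D[y, x] = dx + la + dy + lb
        fill(a)
        fill(b)

    fill(nxt - 1)
    splits = set()
    all_leaves = frozenset(ids)
    anchor = min(all_leaves)

    def collect(node):
        if node < n_taxa:
            return frozenset([ids[node]])
        below = frozenset()
        for child, _ in children[node]:
            below |= collect(child)
        if 2 <= len(below) <= n_taxa - 2:
            side = below if anchor not in below else all_leaves - below
            splits.add(side)
        return below

    collect(nxt - 1)
    dm = DistanceMatrix(ids, D, np.full((n_taxa, n_taxa), 600,
                                        dtype=np.int64))
    return dm, splits


class TestNJ:
    def test_three_taxon_closed_form(self):
        d = {frozenset("AB"): 2.0, frozenset("AC"): 3.0,
             frozenset("BC"): 4.0}
        dm = make_dm(list("ABC"), lambda a, b: d[frozenset((a, b))])
        tree = nj(dm)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:1,D:3)): additive path-length matrix
        paths = {frozenset("AB"): 3.0, frozenset("AC"): 3.0,
                 frozenset("AD"): 5.0, frozenset("BC"): 4.0,
                 frozenset("BD"): 6.0, frozenset("CD"): 4.0}
        dm = make_dm(list("ABCD"), lambda a, b: paths[frozenset((a, b))])
        tree = nj(dm)
        assert tree.n_clamped == 0
        assert tree.bipartitions() == {frozenset("CD")}
        for pair, exp in paths.items():
            a, b = sorted(pair)
            assert tree.path_length(a, b) == pytest.approx(exp, abs=1e-9)

    @pytest.mark.parametrize("n_taxa", [5, 6, 8])
    def test_random_additive_matrices_recovered(self, rng, n_taxa):
        for _ in range(10):
            dm, true_splits = additive_matrix_from_random_tree(rng, n_taxa)
            tree = nj(dm)
            assert tree.bipartitions() == true_splits
            for i, a in enumerate(dm.ids):
                for b in dm.ids[i + 1:]:
                    assert tree.path_length(a, b) == \
                        pytest.approx(dm.get(a, b), abs=1e-9)

    def test_equal_distances_tie_break_is_deterministic(self):
        dm = make_dm(list("ABCD"), lambda a, b: 1.0)
        t1, t2 = nj(dm), nj(dm)
        assert t1.to_newick() == t2.to_newick()

    def test_undefined_pair_is_hard_error(self):
        vals = np.array([[0.0, np.nan, 0.1], [np.nan, 0.0, 0.1],
                         [0.1, 0.1, 0.0]])
        dm = DistanceMatrix(list("ABC"), vals,
                            np.full((3, 3), 10, dtype=np.int64))
        with pytest.raises(ValueError, match="'A'.*'B'"):
            nj(dm)

    def test_matches_skbio_on_additive_matrices(self, rng):
        """Independent cross-check against scikit-bio's NJ implementation."""
        skbio = pytest.importorskip("skbio")
        for _ in range(5):
            dm, _ = additive_matrix_from_random_tree(rng, 6)
            ours = nj(dm)
            theirs = skbio.tree.nj(
                skbio.DistanceMatrix(dm.values, ids=dm.ids))
            anchor = min(dm.ids)
            all_leaves = frozenset(dm.ids)
            their_splits = set()
            for node in theirs.non_tips():
                below = frozenset(t.name for t in node.tips())
                if 2 <= len(below) <= len(dm.ids) - 2:
                    side = (below if anchor not in below
                            else all_leaves - below)
                    their_splits.add(side)
            assert ours.bipartitions() == their_splits


class TestBootstrap:
    def test_separating_edge_strongly_supported(self, two_cluster_alignment):
        tree = bootstrap_support(two_cluster_alignment, n_reps=100, seed=42)
        supports = [n.support for n in _internal_nodes(tree.root)
                    if n.support is not None]
        # the clade split spans hundreds of informative columns
        assert max(supports) >= 95.0

    def test_zero_replicates_gives_plain_tree(self, two_cluster_alignment):
        tree = bootstrap_support(two_cluster_alignment, n_reps=0)
        assert all(n.support is None for n in _internal_nodes(tree.root))

    def test_fixed_seed_reproducible(self, two_cluster_alignment):
        t1 = bootstrap_support(two_cluster_alignment, n_reps=25, seed=7)
        t2 = bootstrap_support(two_cluster_alignment, n_reps=25, seed=7)
        assert t1.to_newick(support_floor=0) == t2.to_newick(support_floor=0)

    def test_seed_mandatory(self, two_cluster_alignment):
        with pytest.raises(ValueError, match="seed"):
            bootstrap_support(two_cluster_alignment, n_reps=10)


def _internal_nodes(node):
    if node.children:
        yield node
        for c in node.children:
            yield from _internal_nodes(c)


class TestNewick:
    def test_three_taxon_output_parses(self, tmp_path):
        d = {frozenset("AB"): 2.0, frozenset("AC"): 3.0,
             frozenset("BC"): 4.0}
        dm = make_dm(list("ABC"), lambda a, b: d[frozenset((a, b))])
        tree = nj(dm)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        dendropy = pytest.importorskip("dendropy")
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == set("ABC")

    def test_newick_round_trip_preserves_lengths(self, tmp_path,
                                                 two_cluster_alignment):
        dendropy = pytest.importorskip("dendropy")
        tree = bootstrap_support(two_cluster_alignment, n_reps=0)
        path = tmp_path / "t.nwk"
        write_newick(tree, path, support_floor=80)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        ids = tree.leaf_names
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                assert pdm.distance(taxa[a], taxa[b]) == \
                    pytest.approx(tree.path_length(a, b), abs=1e-6)

    def test_support_floor_boundary(self):
        d = {frozenset("AB"): 2.0, frozenset("AC"): 3.0,
             frozenset("AD"): 5.0, frozenset("BC"): 4.0,
             frozenset("BD"): 6.0, frozenset("CD"): 4.0}
        dm = make_dm(list("ABCD"), lambda a, b: d[frozenset((a, b))])
        tree = nj(dm)
        for node in _internal_nodes(tree.root):
            if node is not tree.root:
                node.support = 79.0
        assert "79" not in tree.to_newick(support_floor=80)
        assert "79" in tree.to_newick(support_floor=50)

    def test_member_count_suffix(self):
        d = {frozenset("AB"): 2.0, frozenset("AC"): 3.0,
             frozenset("BC"): 4.0}
        dm = make_dm(list("ABC"), lambda a, b: d[frozenset((a, b))])
        tree = nj(dm)
        out = tree.to_newick(member_counts={"A": 6})
        assert "A_6ind" in out
        assert "B_" not in out
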