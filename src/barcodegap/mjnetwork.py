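"""Median-joining haplotype networks with single-step indel coding.

Aligned sequences are recoded into equally weighted characters before
network construction: each variable nucleotide column becomes a
substitution character, each maximal multi- or single-column gap run a
binary indel character (simple indel coding: a 5-bp deletion is one
mutational step, not five), and annotated structural rearrangements such
as inversions one binary character each, their columns excluded from
substitution coding.

The network itself is the classic median-joining construction: the union
of all minimum spanning trees of the haplotype distance graph (the minimum
spanning network at tolerance epsilon), iteratively augmented with median
(Steiner) vectors — majority-consensus haplotypes of connectable triplets
that reduce the connection cost — then pruned of obsolete medians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .delimit import LineagePartition
from .seqio import AlignedSet

MISSING = -1


class Character(NamedTuple):
    kind: str  # substitution_site | indel_block | structural
    definition: tuple  # (column,) or (start, stop) half-open interval


@dataclass
class CharacterMatrix:
    """Recoded haplotype characters; all characters weight one step.

    ``states[id]`` is an integer vector, one entry per character; MISSING
    (-1) marks inapplicable states (e.g. a residue column under a gap),
    which are skipped pairwise in step counts.
    """

    ids: list[str]
    characters: list[Character]
    states: dict[str, np.ndarray]

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def hamming(self, a: str, b: str) -> int:
        if a not in self.states or b not in self.states:
            missing = a if a not in self.states else b
            raise KeyError(f"id {missing!r} not in character encoding")
        sa, sb = self.states[a], self.states[b]
        ok = (sa != MISSING) & (sb != MISSING)
        return int(((sa != sb) & ok).sum())

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{c.kind}:{'-'.join(map(str, c.definition))}"
                for c in self.characters]
        return pd.DataFrame({sid: self.states[sid] for sid in self.ids},
                            index=cols).T

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="seq_id")


def _gap_runs(residues: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' as half-open (start, stop) intervals."""
    runs = []
    start = None
    for i, ch in enumerate(residues):
        if ch == "-" and start is None:
            start = i
        elif ch != "-" and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(residues)))
    return runs


def encode_characters(aligned: AlignedSet,
                      structural_annotations: Sequence[tuple[int, int]] | None
                      = None) -> CharacterMatrix:
    """Recode an alignment into single-step characters.

    Gap runs: every distinct maximal gap run observed in any sequence becomes
    one binary indel character (state 1 = the sequence carries exactly that
    run; 0 = no gap overlapping it; MISSING = overlapped by a different run).
    Structural annotations are half-open column intervals (e.g. a known
    inversion): one binary character each, scored 0 when the sequence matches
    the first sequence's residues over the interval and 1 otherwise; their
    columns are excluded from substitution coding.  Remaining variable
    columns become substitution characters with gap/ambiguity as MISSING.
    """
    structural = sorted(structural_annotations or [])
    for (a1, b1), (a2, b2) in zip(structural, structural[1:]):
        if a2 < b1:
            raise ValueError(
                f"overlapping structural annotations ({a1},{b1}) and ({a2},{b2})")
    struct_cols = {c for s, e in structural for c in range(s, e)}

    runs: list[tuple[int, int]] = sorted(
        {run for rec in aligned for run in _gap_runs(rec.residues)})

    characters: list[Character] = []
    columns: list[np.ndarray] = []
    ids = aligned.ids

    for s, e in runs:
        states = []
        for rec in aligned:
            rec_runs = _gap_runs(rec.residues)
            if (s, e) in rec_runs:
                states.append(1)
            elif any(rs < e and s < re_ for rs, re_ in rec_runs):
                states.append(MISSING)  # a different, overlapping run
            else:
                states.append(0)
        characters.append(Character("indel_block", (s, e)))
        columns.append(np.array(states))

    for s, e in structural:
        ref = aligned.records[0].residues[s:e]
        states = [0 if rec.residues[s:e] == ref else 1 for rec in aligned]
        characters.append(Character("structural", (s, e)))
        columns.append(np.array(states))

    base_code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for col in range(aligned.length):
        if col in struct_cols:
            continue
        states = [base_code.get(rec.residues[col], MISSING)
                  for rec in aligned]
        observed = {s for s in states if s != MISSING}
        if len(observed) >= 2:
            characters.append(Character("substitution_site", (col,)))
            columns.append(np.array(states))

    mat = (np.stack(columns, axis=1) if columns
           else np.empty((len(ids), 0), dtype=int))
    return CharacterMatrix(list(ids), characters,
                           {sid: mat[i] for i, sid in enumerate(ids)})


@dataclass
class HaploNetwork:
    """Haplotype graph: observed haplotype nodes (with member multiplicity)
    plus inferred median vectors, edges weighted in mutational steps."""

    graph: nx.Graph
    epsilon: int = 0
    #: minimum spanning weight of the growing node set, one entry per median
    #: acceptance round (non-increasing: medians only ever cheapen the span)
    mst_weight_history: list[int] = field(default_factory=list)

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["is_median"]]

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["is_median"]]

    def members_of(self, node: str) -> list[str]:
        return self.graph.nodes[node]["members"]

    def total_weight(self) -> int:
        return int(sum(w for _, _, w in self.graph.edges(data="weight")))

    def node_table(self) -> pd.DataFrame:
        rows = [{"node": n, "multiplicity": d["multiplicity"],
                 "is_median": d["is_median"],
                 "members": ";".join(d["members"])}
                for n, d in sorted(self.graph.nodes(data=True))]
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [{"node_a": a, "node_b": b, "steps": w}
                for a, b, w in sorted(self.graph.edges(data="weight"))]
        return pd.DataFrame(rows)

    def write_tables(self, nodes_path: str | Path,
                     edges_path: str | Path) -> None:
        self.node_table().to_csv(nodes_path, sep="\t", index=False)
        self.edge_table().to_csv(edges_path, sep="\t", index=False)


def _dedup(cm: CharacterMatrix) -> tuple[list[tuple[int, ...]], dict[tuple, list[str]]]:
    """Unique state vectors in first-seen order of sorted ids, with members."""
    members: dict[tuple, list[str]] = {}
    order: list[tuple[int, ...]] = []
    for sid in sorted(cm.ids):
        key = tuple(int(x) for x in cm.states[sid])
        if key not in members:
            members[key] = []
            order.append(key)
        members[key].append(sid)
    return order, members


def _vec_dist(a: Sequence[int], b: Sequence[int]) -> int:
    return sum(1 for x, y in zip(a, b)
               if x != MISSING and y != MISSING and x != y)


def _msn_edges(vectors: list[tuple[int, ...]], epsilon: int
               ) -> list[tuple[int, int, int]]:
    """Union of all minimum spanning trees at tolerance epsilon.

    Edges are added in ascending weight; at each weight level w, every edge
    with weight <= w_level + epsilon joining vertices in different components
    (components as of the start of the level) is kept.
    """
    n = len(vectors)
    if n < 2:
        return []
    edges = sorted(
        (_vec_dist(vectors[i], vectors[j]), i, j)
        for i, j in combinations(range(n), 2)
    )
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    kept: list[tuple[int, int, int]] = []
    for w_level in sorted({w for w, _, _ in edges}):
        if all(find(i) == find(0) for i in range(1, n)):
            break
        # components as of the start of this weight level: every edge within
        # epsilon of the level that crosses them belongs to some MST (exactly
        # the tied minimal edges when epsilon = 0)
        comp_before = {i: find(i) for i in range(n)}
        joins = [(w, i, j) for w, i, j in edges
                 if w_level <= w <= w_level + epsilon
                 and comp_before[i] != comp_before[j]]
        for w, i, j in joins:
            kept.append((i, j, w))
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return kept


def _median_vector(a: tuple[int, ...], b: tuple[int, ...],
                   c: tuple[int, ...]) -> tuple[int, ...]:
    """Per-character majority consensus; ties resolved toward the first."""
    out = []
    for x, y, z in zip(a, b, c):
        if y == z and y != MISSING:
            out.append(y)
        else:
            out.append(x)
    return tuple(out)


def median_joining(cm: CharacterMatrix, epsilon: int = 0) -> HaploNetwork:
    """Build the median-joining network of a character matrix.

    Deterministic under the fixed (sorted-id) input ordering.  Median
    vectors are accepted when connecting a triplet through the median is
    strictly cheaper than the triplet's minimum spanning connection; the
    loop reruns until no median is accepted, then medians of degree <= 2
    lying on no observed-pair geodesic are pruned as obsolete.
    """
    order, members = _dedup(cm)
    if len(order) < 2:
        warnings.warn("single haplotype: network has one node and no edges")
    vectors: list[tuple[int, ...]] = list(order)
    n_observed = len(vectors)

    def mst_weight(vecs: list[tuple[int, ...]]) -> int:
        if len(vecs) < 2:
            return 0
        g = nx.Graph()
        g.add_nodes_from(range(len(vecs)))
        for i, j in combinations(range(len(vecs)), 2):
            g.add_edge(i, j, weight=_vec_dist(vecs[i], vecs[j]))
        return int(nx.minimum_spanning_tree(g).size(weight="weight"))

    history = [mst_weight(vectors)]
    while True:
        kept = _msn_edges(vectors, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(vectors))}
        for i, j, _ in kept:
            adj[i].add(j)
            adj[j].add(i)
        existing = set(vectors)
        new_medians: list[tuple[int, ...]] = []
        # connectable triplets: u-v an edge, w adjacent to u or v
        triplets = set()
        for i, j, _ in kept:
            for k in (adj[i] | adj[j]) - {i, j}:
                triplets.add(tuple(sorted((i, j, k))))
        current_w = history[-1]
        for i, j, k in sorted(triplets):
            u, v, w = vectors[i], vectors[j], vectors[k]
            m = _median_vector(u, v, w)
            if m in existing:
                continue
            via = _vec_dist(m, u) + _vec_dist(m, v) + _vec_dist(m, w)
            duv, duw, dvw = (_vec_dist(u, v), _vec_dist(u, w),
                             _vec_dist(v, w))
            mst3 = duv + duw + dvw - max(duv, duw, dvw)
            if via >= mst3:
                continue
            # accept only medians that cheapen the global span, so the
            # spanning cost is strictly decreasing and the loop terminates
            cand_w = mst_weight(vectors + new_medians + [m])
            if cand_w < current_w:
                new_medians.append(m)
                existing.add(m)
                current_w = cand_w
        if not new_medians:
            break
        vectors.extend(new_medians)
        history.append(current_w)

    # prune obsolete medians: degree <= 2 and on no observed-pair geodesic
    while True:
        kept = _msn_edges(vectors, epsilon)
        g = nx.Graph()
        g.add_nodes_from(range(len(vectors)))
        g.add_weighted_edges_from(kept)
        sp = dict(nx.all_pairs_dijkstra_path_length(g))
        removable = None
        for m_idx in range(n_observed, len(vectors)):
            if g.degree(m_idx) > 2:
                continue
            on_geodesic = any(
                abs(sp[i][m_idx] + sp[m_idx][j] - sp[i][j]) < 1e-9
                for i in range(n_observed) for j in range(i + 1, n_observed)
            )
            if not on_geodesic:
                removable = m_idx
                break
        if removable is None:
            break
        vectors.pop(removable)

    kept = _msn_edges(vectors, epsilon)
    graph = nx.Graph()
    names: list[str] = []
    n_h = n_m = 0
    for idx, vec in enumerate(vectors):
        if idx < n_observed:
            n_h += 1
            name = f"H{n_h}"
            mem = members[vec]
        else:
            n_m += 1
            name = f"MV{n_m}"
            mem = []
        names.append(name)
        graph.add_node(name, states=vec, members=mem,
                       multiplicity=len(mem), is_median=idx >= n_observed)
    for i, j, w in kept:
        graph.add_edge(names[i], names[j], weight=w)
    return HaploNetwork(graph, epsilon=epsilon, mst_weight_history=history)


def lineage_separation(net: HaploNetwork,
                       partition: LineagePartition) -> pd.DataFrame:
    """Minimum geodesic step count between the node sets of each lineage pair.

    Sequence ids are mapped to the haplotype nodes containing them; median
    vectors belong to no lineage but may carry geodesics.
    """
    node_of: dict[str, str] = {}
    for node in net.observed_nodes:
        for sid in net.members_of(node):
            node_of[sid] = node
    missing = [s for s in partition.assignment if s not in node_of]
    if missing:
        raise KeyError(f"partition ids not in network: {missing}")
    lineage_nodes: dict[str, set[str]] = {}
    for sid, lab in partition.assignment.items():
        lineage_nodes.setdefault(lab, set()).add(node_of[sid])
    sp = dict(nx.all_pairs_dijkstra_path_length(net.graph))
    labels = sorted(lineage_nodes)
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        best = min(sp[u][v] for u in lineage_nodes[a]
                   for v in lineage_nodes[b])
        mat.loc[a, b] = mat.loc[b, a] = best
    return mat
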