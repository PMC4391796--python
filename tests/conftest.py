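"""Shared fixtures: tiny alignments, toy distance matrices, random helpers."""

from __future__ import annotations

import numpy as np
import pytest

from barcodegap.distances import DistanceMatrix
from barcodegap.seqio import AlignedSet, Marker, SequenceRecord


def make_aligned(seqs: dict[str, str], marker: Marker = Marker.COI) -> AlignedSet:
    return AlignedSet(
        [SequenceRecord(seq_id=k, residues=v, marker=marker)
         for k, v in seqs.items()],
        marker=marker)


def make_dm(ids: list[str], dist_of) -> DistanceMatrix:
    """Distance matrix from a callable dist_of(id_a, id_b)."""
    n = len(ids)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = dist_of(ids[i], ids[j])
    return DistanceMatrix(ids, vals, np.full((n, n), 600, dtype=np.int64))


def cluster_dm(sizes: list[int], intra: float, inter: float,
               prefix: str = "c") -> tuple[DistanceMatrix, list[frozenset]]:
    """Blocked matrix: constant intra within clusters, inter between."""
    ids, truth = [], []
    for k, s in enumerate(sizes):
        members = [f"{prefix}{k}_{m}" for m in range(s)]
        ids.extend(members)
        truth.append(frozenset(members))
    cluster_of = {i: i.split("_")[0] for i in ids}
    dm = make_dm(ids, lambda a, b: intra if cluster_of[a] == cluster_of[b]
                 else inter)
    return dm, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_cluster_alignment(rng) -> AlignedSet:
    """Two 3-member clades, ~1% within and ~25% between, 600 nt."""
    from barcodegap.synthetic import SimConfig, simulate_dataset
    cfg = SimConfig(n_lineages=2, members_per_lineage=(3, 3),
                    inter_divergence=(0.25, 0.25),
                    intra_divergence=(0.0, 0.01), seed=11)
    return simulate_dataset(cfg).marker1
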