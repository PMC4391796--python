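"""Threshold-based lineage delimitation and per-lineage statistics.

A lineage (MOTU) at threshold *t* is a connected component of the graph with
an edge between two sequences iff their distance is strictly below *t*
(single linkage).  Single linkage is the only rule guaranteeing that output
lineages are separated by at least *t*; because of chaining, intra-lineage
maxima above *t* are possible and are reported honestly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix

logger = logging.getLogger(__name__)

InterMode = Literal["min_nearest", "mean_nearest"]

#: sentinel printed for the intra-lineage variability of singleton lineages
NC = "NC"


@dataclass
class LineagePartition:
    """Assignment of sequences to lineages delimited at one threshold.

    Labels are deterministic ordinals ("L1", "L2", ...) assigned by
    first-seen order of a canonical (sorted) id ordering, so reruns are
    reproducible; a morphogroup prefix can be supplied instead of "L".
    """

    assignment: dict[str, str]
    threshold: float | None = None
    representative: dict[str, str] = field(default_factory=dict)

    @property
    def n_lineages(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid in sorted(self.assignment):
            seen.setdefault(self.assignment[sid], None)
        return list(seen)

    def members(self, label: str) -> list[str]:
        return sorted(s for s, l in self.assignment.items() if l == label)

    def lineages(self) -> dict[str, list[str]]:
        return {lab: self.members(lab) for lab in self.labels}

    def as_frozensets(self) -> set[frozenset[str]]:
        """Label-free view for comparing partitions."""
        return {frozenset(m) for m in self.lineages().values()}

    def restricted(self, ids: Iterable[str]) -> "LineagePartition":
        keep = set(ids)
        return LineagePartition(
            {s: l for s, l in self.assignment.items() if s in keep},
            threshold=self.threshold,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"seq_id": sid, "lineage": lab,
             "is_representative": self.representative.get(lab) == sid}
            for sid, lab in sorted(self.assignment.items())
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _components(dm: DistanceMatrix, ids: list[str], cutoff: float,
                strict: bool) -> list[list[str]]:
    """Connected components among *ids* with edges d < cutoff (strict) or
    d <= cutoff; NaN (undefined) pairs contribute no edge."""
    idx = [dm.index(i) for i in ids]
    sub = dm.values[np.ix_(idx, idx)]
    with np.errstate(invalid="ignore"):
        adj = (sub < cutoff) if strict else (sub <= cutoff)
    adj &= ~np.isnan(sub)
    n_undef = int(np.isnan(sub).sum()) // 2
    if n_undef:
        logger.info("%d undefined pairs contribute no clustering edge", n_undef)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    comps: dict[int, list[str]] = {}
    for sid, lab in zip(ids, labels):
        comps.setdefault(int(lab), []).append(sid)
    # deterministic order: by smallest member id
    return sorted((sorted(c) for c in comps.values()), key=lambda c: c[0])


def label_components(components: list[list[str]],
                     prefix: str = "L") -> LineagePartition:
    assignment: dict[str, str] = {}
    representative: dict[str, str] = {}
    for k, comp in enumerate(components, start=1):
        lab = f"{prefix}{k}"
        representative[lab] = comp[0]
        for sid in comp:
            assignment[sid] = lab
    return LineagePartition(assignment, representative=representative)


def threshold_partition(dm: DistanceMatrix, t: float,
                        prefix: str = "L") -> LineagePartition:
    """Partition sequences into lineages separated by at least *t*.

    Edge rule is strict (d < t): sequence pairs at exactly *t* are treated as
    separated, matching the convention that lineages are "separated by more
    than" the threshold.
    """
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must be a proportion in (0, 1)")
    comps = _components(dm, list(dm.ids), t, strict=True)
    part = label_components(comps, prefix=prefix)
    part.threshold = t
    return part


def collapse_haplotypes(dm: DistanceMatrix, collapse_t: float = 0.01
                        ) -> tuple[list[str], dict[str, list[str]]]:
    """Combine sequences that are identical or diverge by less than *collapse_t*.

    Returns the representatives (lexicographically lowest id per connected
    component under edges d < collapse_t) and the member map used for "N ind"
    display suffixes.  All sequences remain in the distance matrix; collapsing
    affects display and tree size only.
    """
    comps = _components(dm, list(dm.ids), collapse_t, strict=True)
    member_map = {c[0]: c for c in comps}
    return sorted(member_map), member_map


class SublineageSplit(NamedTuple):
    lineage: str
    n_sublineages: int
    divergence: float  # max between-sublineage pairwise distance
    sublineages: tuple[frozenset, ...]


def sublineage_scan(dm: DistanceMatrix, partition: LineagePartition,
                    t2: float) -> list[SublineageSplit]:
    """Re-partition each lineage at the finer threshold *t2* and report splits.

    Reports every lineage whose member set separates into >= 2 sublineages at
    *t2*, with the maximum between-sublineage distance (the divergence that
    the coarser threshold had absorbed).
    """
    if partition.threshold is not None and t2 >= partition.threshold:
        raise ValueError("t2 must be finer than the partition's threshold")
    out: list[SublineageSplit] = []
    for lab, members in partition.lineages().items():
        if len(members) < 2:
            continue
        comps = _components(dm, members, t2, strict=True)
        if len(comps) < 2:
            continue
        div = 0.0
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                for a in comps[i]:
                    for b in comps[j]:
                        v = dm.get(a, b)
                        if not math.isnan(v):
                            div = max(div, v)
        out.append(SublineageSplit(lab, len(comps), div,
                                   tuple(frozenset(c) for c in comps)))
    return out


class LineageStat(NamedTuple):
    lineage: str
    n_members: int
    intra_min: float | None  # None => NC (singleton)
    intra_max: float | None
    nearest_lineage: str | None
    inter_nearest: float | None


def lineage_stats(dm: DistanceMatrix, partition: LineagePartition,
                  inter_mode: InterMode = "min_nearest") -> list[LineageStat]:
    """Intra-lineage distance range and distance to the nearest other lineage.

    The nearest other lineage is located by minimum pairwise distance;
    ``inter_mode`` chooses the reported statistic: the minimum pair
    (``min_nearest``) or the mean of all pairs to that nearest lineage
    (``mean_nearest``).  Singletons report no intra range (NC).
    """
    groups = partition.lineages()
    out: list[LineageStat] = []
    for lab, members in groups.items():
        intra = [dm.get(a, b)
                 for i, a in enumerate(members) for b in members[i + 1:]
                 if not math.isnan(dm.get(a, b))]
        intra_min = min(intra) if intra else None
        intra_max = max(intra) if intra else None
        nearest, stat = None, None
        for other, omembers in groups.items():
            if other == lab:
                continue
            pairs = [dm.get(a, b) for a in members for b in omembers
                     if not math.isnan(dm.get(a, b))]
            if not pairs:
                continue
            if stat is None or min(pairs) < stat[0]:
                stat = (min(pairs), float(np.mean(pairs)))
                nearest = other
        inter = None
        if stat is not None:
            inter = stat[0] if inter_mode == "min_nearest" else stat[1]
        out.append(LineageStat(lab, len(members), intra_min, intra_max,
                               nearest, inter))
    return out


def stats_report(stats: list[LineageStat],
                 morphotaxon_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Variability table: one row per lineage, percentages with the NC sentinel."""

    def pct(x: float | None) -> str:
        return NC if x is None else f"{100.0 * x:.3f}"

    rows = []
    for s in stats:
        intra = NC if s.intra_min is None else \
            (pct(s.intra_min) if s.intra_min == s.intra_max
             else f"{100 * s.intra_min:.3f}-{100 * s.intra_max:.3f}")
        rows.append({
            "lineage": s.lineage,
            "n_seqs": s.n_members,
            "morphotaxon": (morphotaxon_of or {}).get(s.lineage, ""),
            "intra_lineage_variability_pct": intra,
            "inter_lineage_variability_pct": pct(s.inter_nearest),
            "nearest_lineage": s.nearest_lineage or "",
        })
    return pd.DataFrame(rows)
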