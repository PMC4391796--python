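"""Cross-marker concordance and morphology-vs-genetics accounting.

Lineage partitions from two markers are compared through the specimens
sequenced for both (sequence-level mapping is undefined across loci).
Discrepancy types:

* ``merge`` — one lineage of marker B contains specimens from two or more
  marker-A lineages (B fails to separate what A separates);
* ``split`` — the inverse;
* ``tangled`` — divergent copies from the *same* specimen fall into
  different lineages (intra-individual copy polymorphism, typical of
  multi-copy nuclear markers), so the specimen cannot be force-assigned.

The diversity summary counts morphotaxa against genetic lineages per
higher group (family/subfamily): identified morphotaxon labels count as
taxa, as do group labels carried by immatures (e.g. "with/without hair
setae"); unlabelled immatures contribute to lineage counts only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, NamedTuple

import pandas as pd

from .delimit import LineagePartition

DiscrepancyKind = Literal["merge", "split", "tangled"]


class Discrepancy(NamedTuple):
    kind: DiscrepancyKind
    lineages_a: tuple[str, ...]
    lineages_b: tuple[str, ...]
    specimens: tuple[str, ...]


def specimen_lineage(partition: LineagePartition,
                     metadata: pd.DataFrame) -> dict[str, set[str]]:
    """Map each specimen to the set of lineages its sequences fall into.

    Specimens with clones in two or more lineages are returned with a
    multi-element set (polymorphic — tangled evidence), never force-assigned.
    """
    out: dict[str, set[str]] = {}
    for sid, lab in partition.assignment.items():
        if sid in metadata.index:
            spec = metadata.loc[sid, "specimen_id"] or sid
        else:
            raise KeyError(f"seq_id {sid!r} missing from metadata")
        out.setdefault(spec, set()).add(lab)
    return out


def polymorphic_specimens(partition: LineagePartition,
                          metadata: pd.DataFrame) -> dict[str, set[str]]:
    return {s: labs for s, labs
            in specimen_lineage(partition, metadata).items() if len(labs) > 1}


@dataclass
class ConcordanceReport:
    shared_specimens: set[str]
    mapping_ab: dict[str, set[str]]  # A lineage -> B lineages (via specimens)
    mapping_ba: dict[str, set[str]]
    discrepancies: list[Discrepancy]
    n_concordant: int

    @property
    def n_discrepancies(self) -> int:
        return len(self.discrepancies)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"kind": d.kind,
             "lineages_a": ";".join(d.lineages_a),
             "lineages_b": ";".join(d.lineages_b),
             "specimens": ";".join(d.specimens)}
            for d in self.discrepancies
        ], columns=["kind", "lineages_a", "lineages_b", "specimens"])


def compare_partitions(p_a: LineagePartition, p_b: LineagePartition,
                       metadata: pd.DataFrame) -> ConcordanceReport:
    """Compare two marker partitions over their shared specimens.

    Tangled specimens (polymorphic within a marker) are reported once each
    and excluded from the merge/split accounting; a lineage pair implicated
    by the same specimens is counted as one discrepancy.
    """
    spec_a = specimen_lineage(p_a, metadata)
    spec_b = specimen_lineage(p_b, metadata)
    shared = set(spec_a) & set(spec_b)
    if not shared:
        warnings.warn("no shared specimens between the two partitions")
        return ConcordanceReport(set(), {}, {}, [], 0)

    discrepancies: list[Discrepancy] = []
    tangled = {s for s in shared
               if len(spec_a[s]) > 1 or len(spec_b[s]) > 1}
    for s in sorted(tangled):
        discrepancies.append(Discrepancy(
            "tangled", tuple(sorted(spec_a[s])), tuple(sorted(spec_b[s])),
            (s,)))

    clean = shared - tangled
    mapping_ab: dict[str, set[str]] = {}
    mapping_ba: dict[str, set[str]] = {}
    for s in clean:
        (a,), (b,) = spec_a[s], spec_b[s]
        mapping_ab.setdefault(a, set()).add(b)
        mapping_ba.setdefault(b, set()).add(a)

    for b, a_set in sorted(mapping_ba.items()):
        if len(a_set) > 1:
            specs = tuple(sorted(s for s in clean
                                 if next(iter(spec_b[s])) == b))
            discrepancies.append(Discrepancy("merge", tuple(sorted(a_set)),
                                             (b,), specs))
    for a, b_set in sorted(mapping_ab.items()):
        if len(b_set) > 1:
            specs = tuple(sorted(s for s in clean
                                 if next(iter(spec_a[s])) == a))
            discrepancies.append(Discrepancy("split", (a,),
                                             tuple(sorted(b_set)), specs))

    n_concordant = sum(
        1 for a, b_set in mapping_ab.items()
        if len(b_set) == 1 and len(mapping_ba[next(iter(b_set))]) == 1)
    return ConcordanceReport(shared, mapping_ab, mapping_ba, discrepancies,
                             n_concordant)


def diversity_summary(partition: LineagePartition,
                      metadata: pd.DataFrame) -> pd.DataFrame:
    """Morphotaxa vs genetic lineages per group, with a totals row.

    A morphotaxon label (identified species or an immature group label)
    counts once per group; a lineage is attributed to the modal group of its
    members.  Sequences without a morphotaxon label contribute to lineage
    counts only.
    """
    rows: dict[str, dict[str, set]] = {}
    lineage_group: dict[str, str] = {}
    for lab, members in partition.lineages().items():
        groups = [metadata.loc[s, "group"] if s in metadata.index else ""
                  for s in members]
        groups = [g or "unassigned" for g in groups]
        lineage_group[lab] = max(set(groups), key=groups.count)
    for sid, lab in partition.assignment.items():
        grp = lineage_group[lab]
        row = rows.setdefault(grp, {"taxa": set(), "lineages": set()})
        row["lineages"].add(lab)
        if sid in metadata.index:
            taxon = metadata.loc[sid, "morphotaxon"]
            if taxon:
                row["taxa"].add(taxon)
    table = [{"group": g, "n_morphotaxa": len(r["taxa"]),
              "n_lineages": len(r["lineages"])}
             for g, r in sorted(rows.items())]
    total_taxa = len({t for r in rows.values() for t in r["taxa"]})
    total_lineages = sum(len(r["lineages"]) for r in rows.values())
    table.append({"group": "Total", "n_morphotaxa": total_taxa,
                  "n_lineages": total_lineages})
    return pd.DataFrame(table)


def cryptic_complexes(partition: LineagePartition,
                      metadata: pd.DataFrame) -> dict[str, list[str]]:
    """Morphotaxa whose sequences fall into >= 2 lineages (cryptic diversity)."""
    by_taxon: dict[str, set[str]] = {}
    for sid, lab in partition.assignment.items():
        if sid in metadata.index:
            taxon = metadata.loc[sid, "morphotaxon"]
            if taxon:
                by_taxon.setdefault(taxon, set()).add(lab)
    return {t: sorted(labs) for t, labs in sorted(by_taxon.items())
            if len(labs) > 1}
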