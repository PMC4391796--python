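"""Lineage-structured two-marker sequence simulator with known truth.

The generator emulates the distance structure of a barcoding study: K
discrete lineages whose members diverge by at most a few percent while
lineages sit 12–25% apart (a barcode gap by construction), substitutions
transition-biased (kappa), a second slower-evolving multi-copy marker
carrying lineage-level multi-base indel blocks, and one-to-several clone
sequences per specimen with low-level copy polymorphism.

Substitutions are placed by expected-count inversion of the K2P formula:
for a target distance the transition/transversion site counts are solved
in closed form and placed on randomly chosen distinct sites, so realized
pairwise distances track the nominal targets up to binomial noise and the
convexity of the correction.  This targets distance structure, not
population-genetic process (no coalescent, recombination or selection).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .delimit import LineagePartition
from .seqio import AlignedSet, Marker, Maturity, SequenceRecord, write_fasta

_BASES = np.array(list("ACGT"))
# transition partner (A<->G, C<->T) by base code
_TRANSITION = np.array([2, 3, 0, 1])
# the two transversion partners by base code
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Distances are proportions.  ``inter_divergence`` is the target range of
    *pairwise* between-lineage K2P distance (lineage ancestors are placed at
    half that from a common root), ``intra_divergence`` the range of each
    member's distance to its lineage ancestor.  ``planted_sublineages`` maps
    lineage indices to a within-lineage split divergence, used to emulate
    cryptic sublineages sitting between two thresholds.  ``close_pairs``
    entries (i, j, div) derive lineage j's ancestor from lineage i's at the
    given divergence instead of from the root, planting lineage pairs only
    slightly above a delimitation threshold.

    Two knobs plant marker discordance: ``marker2_merge_pairs`` (i, j) give
    lineage j the *identical* marker-2 ancestor as lineage i while marker 1
    diverges normally (two lineages one marker cannot separate), and
    ``marker2_tangle_pairs`` (i, j) give the first specimen of lineage j an
    extra marker-2 clone derived from lineage i (divergent copies within
    one individual).
    """

    n_lineages: int = 8
    members_per_lineage: tuple[int, int] = (2, 6)
    seq_length: int = 600  # ~ Folmer COI fragment
    inter_divergence: tuple[float, float] = (0.12, 0.25)
    intra_divergence: tuple[float, float] = (0.0, 0.02)
    kappa: float = 4.0  # transition/transversion rate ratio
    marker2_rate_scale: float = 0.25
    marker2_length: int = 400
    marker2_indel_rate: float = 0.5  # expected indel blocks per lineage
    indel_length: tuple[int, int] = (2, 8)
    clones_per_specimen: tuple[int, int] = (1, 4)
    clone_noise_rate: float = 0.002  # per-site copy-polymorphism probability
    planted_sublineages: tuple[tuple[int, float], ...] = ()
    planted_member_noise: float = 0.005
    close_pairs: tuple[tuple[int, int, float], ...] = ()
    marker2_merge_pairs: tuple[tuple[int, int], ...] = ()
    marker2_tangle_pairs: tuple[tuple[int, int], ...] = ()
    member_counts: tuple[int, ...] | None = None  # overrides the range
    morphotaxon_complexes: tuple[tuple[int, ...], ...] = ()
    #: indices into morphotaxon_complexes whose specimens are immature but
    #: still carry the shared group label (e.g. "with/without hair setae")
    immature_complexes: tuple[int, ...] = ()
    #: lineages of unidentifiable specimens with no label at all
    immature_lineages: tuple[int, ...] = ()
    enforce_gap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enforce_gap and not self.planted_sublineages:
            # pairwise intra can reach twice the member offset ceiling
            if 2 * self.intra_divergence[1] >= self.inter_divergence[0]:
                raise ValueError(
                    "intra range overlaps inter range: no barcode gap by "
                    "construction (set enforce_gap=False to allow)")


@dataclass
class SimulatedDataset:
    marker1: AlignedSet
    marker2: AlignedSet
    truth_marker1: LineagePartition
    truth_marker2: LineagePartition
    metadata: pd.DataFrame
    config: SimConfig


def _solve_counts(target_d: float, length: int, kappa: float
                  ) -> tuple[int, int]:
    """Transition/transversion site counts realizing a target K2P distance.

    With transition:transversion *rate* ratio kappa and two transversion
    classes, the expected proportion ratio is P/Q = kappa/2 at low
    divergence; the total changed proportion p is solved from the K2P
    closed form with that ratio fixed.
    """
    if target_d <= 0:
        return 0, 0
    rho = kappa / 2.0
    f_p = rho / (1.0 + rho)  # fraction of changes that are transitions

    def k2p_of(p: float) -> float:
        P, Q = f_p * p, (1.0 - f_p) * p
        return (-0.5 * np.log(1 - 2 * P - Q) - 0.25 * np.log(1 - 2 * Q)
                - target_d)

    p_hi = 0.999 / (2 * f_p + (1 - f_p))  # just inside the log domain
    p = brentq(k2p_of, 1e-12, p_hi - 1e-9)
    n_ts = int(round(f_p * p * length))
    n_tv = int(round((1 - f_p) * p * length))
    return n_ts, n_tv


def _mutate(seq: np.ndarray, target_d: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """Derive a sequence at ~target_d K2P distance from *seq*."""
    out = seq.copy()
    n_ts, n_tv = _solve_counts(target_d, len(seq), kappa)
    if n_ts + n_tv == 0:
        return out
    sites = rng.choice(len(seq), size=n_ts + n_tv, replace=False)
    ts_sites, tv_sites = sites[:n_ts], sites[n_ts:]
    out[ts_sites] = _TRANSITION[out[ts_sites]]
    picks = rng.integers(0, 2, size=len(tv_sites))
    out[tv_sites] = _TRANSVERSIONS[out[tv_sites], picks]
    return out


def _copy_noise(seq: np.ndarray, rate: float,
                rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    n = rng.binomial(len(seq), rate)
    if n:
        sites = rng.choice(len(seq), size=n, replace=False)
        shift = rng.integers(1, 4, size=n)
        out[sites] = (out[sites] + shift) % 4
    return out


def _decode(seq: np.ndarray, gaps: Sequence[tuple[int, int]] = ()) -> str:
    chars = _BASES[seq].copy()
    for s, e in gaps:
        chars[s:e] = "-"
    return "".join(chars)


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate the two aligned marker sets, metadata and truth partitions.

    Deterministic: identical config (including seed) gives byte-identical
    FASTA output.  Clone structure exists for marker 2 only (marker 1 is a
    directly sequenced single-copy locus).
    """
    rng = np.random.default_rng(cfg.seed)
    L1, L2 = cfg.seq_length, cfg.marker2_length
    root1 = rng.integers(0, 4, size=L1)
    root2 = rng.integers(0, 4, size=L2)
    planted = dict(cfg.planted_sublineages)

    if cfg.member_counts is not None:
        if len(cfg.member_counts) != cfg.n_lineages:
            raise ValueError("member_counts length must equal n_lineages")
        counts = list(cfg.member_counts)
    else:
        lo, hi = cfg.members_per_lineage
        counts = [int(rng.integers(lo, hi + 1)) for _ in range(cfg.n_lineages)]

    taxon_of = {k: f"Morphosp{k + 1:02d}" for k in range(cfg.n_lineages)}
    immature_set = set(cfg.immature_lineages)
    for ci, complex_members in enumerate(cfg.morphotaxon_complexes):
        shared = taxon_of[complex_members[0]]
        for k in complex_members:
            taxon_of[k] = shared
            if ci in cfg.immature_complexes:
                immature_set.add(k)
    for k in cfg.immature_lineages:
        taxon_of[k] = ""

    rec1: list[SequenceRecord] = []
    rec2: list[SequenceRecord] = []
    meta_rows: list[dict] = []
    truth1: dict[str, str] = {}
    truth2: dict[str, str] = {}
    iso = 0

    close_map = {j: (i, div) for i, j, div in cfg.close_pairs}
    merge_map = {j: i for i, j in cfg.marker2_merge_pairs}
    tangle_map = {j: i for i, j in cfg.marker2_tangle_pairs}
    planted_refs = (list(merge_map.items()) + list(tangle_map.items())
                    + [(j, i) for j, (i, _) in close_map.items()])
    if any(j <= i for j, i in planted_refs):
        raise ValueError("planted pairs must reference an earlier lineage")

    # pass 1: lineage ancestors and shared indel blocks
    ancestors1: list[np.ndarray] = []
    ancestors2: list[np.ndarray] = []
    lineage_gaps: list[list[tuple[int, int]]] = []
    for k in range(cfg.n_lineages):
        if k in close_map:
            src, div = close_map[k]
            anc1 = _mutate(ancestors1[src], div, cfg.kappa, rng)
            anc2 = _mutate(ancestors2[src], div * cfg.marker2_rate_scale,
                           cfg.kappa, rng)
        else:
            half_pair = rng.uniform(*cfg.inter_divergence) / 2.0
            anc1 = _mutate(root1, half_pair, cfg.kappa, rng)
            anc2 = _mutate(root2, half_pair * cfg.marker2_rate_scale,
                           cfg.kappa, rng)
        if k in merge_map:
            anc2 = ancestors2[merge_map[k]].copy()
        ancestors1.append(anc1)
        ancestors2.append(anc2)
        n_blocks = rng.poisson(cfg.marker2_indel_rate)
        gaps = []
        for _ in range(n_blocks):
            blen = int(rng.integers(cfg.indel_length[0],
                                    cfg.indel_length[1] + 1))
            start = int(rng.integers(0, L2 - blen))
            gaps.append((start, start + blen))
        if k in merge_map:
            gaps = list(lineage_gaps[merge_map[k]])
        lineage_gaps.append(gaps)

    # pass 2: members, specimens and clones
    for k in range(cfg.n_lineages):
        lab = f"SIM{k + 1:02d}"
        anc1, anc2, gaps = ancestors1[k], ancestors2[k], lineage_gaps[k]
        n_members = counts[k]
        sub_div = planted.get(k)
        anc1_b = anc2_b = None
        if sub_div is not None:
            n_members = max(n_members, 2)
            anc1_b = _mutate(anc1, sub_div, cfg.kappa, rng)
            anc2_b = _mutate(anc2, sub_div * cfg.marker2_rate_scale,
                             cfg.kappa, rng)

        for m in range(n_members):
            iso += 1
            spec = f"iso{iso:03d}"
            in_b = sub_div is not None and m >= n_members // 2
            base1 = anc1_b if in_b else anc1
            base2 = anc2_b if in_b else anc2
            if sub_div is not None:
                off1 = rng.uniform(0, cfg.planted_member_noise)
                off2 = off1 * cfg.marker2_rate_scale
            else:
                off1 = rng.uniform(*cfg.intra_divergence)
                off2 = off1 * cfg.marker2_rate_scale
            seq1 = _mutate(base1, off1, cfg.kappa, rng)
            seq2 = _mutate(base2, off2, cfg.kappa, rng)
            taxon = taxon_of[k]
            maturity = (Maturity.IDENTIFIED if taxon and k not in immature_set
                        else Maturity.IMMATURE)
            rec1.append(SequenceRecord(
                seq_id=spec, residues=_decode(seq1), marker=Marker.COI,
                specimen_id=spec, morphotaxon=taxon or None,
                maturity=maturity))
            truth1[spec] = lab
            meta_rows.append({"seq_id": spec, "specimen_id": spec,
                              "clone_id": "", "marker": "COI",
                              "morphotaxon": taxon,
                              "maturity": maturity.value, "group": "sim"})
            n_clones = int(rng.integers(cfg.clones_per_specimen[0],
                                        cfg.clones_per_specimen[1] + 1))
            clone_pool = [(_copy_noise(seq2, cfg.clone_noise_rate, rng),
                           gaps, lab) for _ in range(n_clones)]
            if m == 0 and k in tangle_map:
                # intra-individual copy polymorphism across lineages: one
                # clone of this specimen descends from another lineage
                src = tangle_map[k]
                foreign = _copy_noise(ancestors2[src], cfg.clone_noise_rate,
                                      rng)
                clone_pool.append((foreign, lineage_gaps[src],
                                   f"SIM{src + 1:02d}"))
            for c, (clone, cgaps, clab) in enumerate(clone_pool, start=1):
                cid = f"{spec}_c{c}"
                many = len(clone_pool) > 1
                rec2.append(SequenceRecord(
                    seq_id=cid, residues=_decode(clone, cgaps),
                    marker=Marker.ITS2, specimen_id=spec,
                    clone_id=f"c{c}" if many else None,
                    morphotaxon=taxon or None, maturity=maturity))
                truth2[cid] = clab
                meta_rows.append({"seq_id": cid, "specimen_id": spec,
                                  "clone_id": f"c{c}", "marker": "ITS2",
                                  "morphotaxon": taxon,
                                  "maturity": maturity.value, "group": "sim"})

    metadata = pd.DataFrame(meta_rows).set_index("seq_id")
    return SimulatedDataset(
        marker1=AlignedSet(rec1, marker=Marker.COI),
        marker2=AlignedSet(rec2, marker=Marker.ITS2),
        truth_marker1=LineagePartition(truth1),
        truth_marker2=LineagePartition(truth2),
        metadata=metadata,
        config=cfg,
    )


# Lineage sizes of a typical regional barcoding survey: many singletons, a
# few dominant taxa, 185 sequences over 41 lineages (1 to 44 per lineage).
SURVEY_LINEAGE_SIZES = (
    1, 6, 1, 1, 5, 1, 44, 4, 4, 4, 5, 3, 1, 1, 3, 1, 22, 5, 1, 5, 5, 5, 1,
    1, 1, 1, 9, 1, 3, 3, 2, 2, 22, 1, 1, 2, 1, 1, 2, 2, 1)

# morphotaxon labels shared across lineages: two unidentifiable immature
# groups (3 lineages each) and three cryptic complexes (4, 5 and 2 lineages)
SURVEY_COMPLEXES = ((0, 1, 2), (8, 9, 10, 11), (13, 14, 15),
                    (16, 17, 18, 19, 20), (38, 39))


def survey_config(seed: int) -> SimConfig:
    """Dataset shaped like a regional oligochaete barcoding survey.

    41 lineages over 185 specimens with the size profile above; tight
    intra-lineage divergence; four lineages carry cryptic sublineages
    diverging just under the 10% threshold; one lineage pair sits just
    above it (and should merge under gap discovery); one lineage pair is
    indistinguishable in the slower marker; one lineage carries foreign
    marker-2 copies in one specimen (intra-individual polymorphism).
    """
    return SimConfig(
        n_lineages=len(SURVEY_LINEAGE_SIZES),
        member_counts=SURVEY_LINEAGE_SIZES,
        intra_divergence=(0.0, 0.01),
        inter_divergence=(0.13, 0.26),
        planted_sublineages=((9, 0.086), (16, 0.081), (32, 0.058),
                             (39, 0.070)),
        close_pairs=((38, 39, 0.104),),
        marker2_merge_pairs=((13, 14),),
        marker2_tangle_pairs=((15, 16),),
        morphotaxon_complexes=SURVEY_COMPLEXES,
        immature_complexes=(0, 2),
        immature_lineages=(30,),
        seed=seed,
    )


def degrade_gap(cfg: SimConfig, n_split_lineages: int = 1,
                divergence: float = 0.08) -> SimConfig:
    """Variant config planting sublineages that straddle two thresholds.

    The first *n_split_lineages* lineages each receive two sublineages
    *divergence* apart with small member offsets, so a 10% partition keeps
    them whole while a 5% scan splits each exactly once.
    """
    if n_split_lineages > cfg.n_lineages:
        raise ValueError("cannot split more lineages than exist")
    plants = tuple((k, divergence) for k in range(n_split_lineages))
    return replace(cfg, planted_sublineages=plants)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write marker FASTAs, metadata TSV and truth TSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "marker1": outdir / "marker1_coi.fasta",
        "marker2": outdir / "marker2_its2.fasta",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(ds.marker1, paths["marker1"])
    write_fasta(ds.marker2, paths["marker2"])
    ds.metadata.to_csv(paths["metadata"], sep="\t", index_label="seq_id")
    truth = pd.concat([
        pd.DataFrame({"seq_id": list(ds.truth_marker1.assignment),
                      "marker": "COI",
                      "true_lineage": list(ds.truth_marker1.assignment.values())}),
        pd.DataFrame({"seq_id": list(ds.truth_marker2.assignment),
                      "marker": "ITS2",
                      "true_lineage": list(ds.truth_marker2.assignment.values())}),
    ])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
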