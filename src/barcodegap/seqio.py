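"""Aligned-FASTA and specimen-metadata input/output.

The pipeline consumes *aligned* multi-FASTA per marker (alignment is an input
contract: unaligned input is refused, never silently aligned) plus a sidecar
metadata table relating sequences to specimens, clones and morphotaxa.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: DNA alphabet accepted after uppercasing: the four bases, IUPAC ambiguity
#: codes, N and the alignment gap symbol.
ALLOWED_CHARS = frozenset("ACGTRYSWKMBDHVN-?")

METADATA_COLUMNS = ("seq_id", "specimen_id", "clone_id", "marker",
                    "morphotaxon", "maturity", "group")


class Marker(str, Enum):
    """Sequenced locus: mitochondrial COI barcode, nuclear ITS2, or other."""

    COI = "COI"
    ITS2 = "ITS2"
    OTHER = "other"


class Maturity(str, Enum):
    IDENTIFIED = "identified"
    IMMATURE = "immature"


class UnalignedInputError(ValueError):
    """Input sequences have unequal lengths — align them before running."""


class IllegalCharacterError(ValueError):
    """A residue outside the accepted DNA/gap alphabet was found."""


class DuplicateIdError(ValueError):
    """The same seq_id occurs more than once."""


@dataclass
class SequenceRecord:
    """One aligned sequence with its specimen-level bookkeeping.

    ``clone_id`` distinguishes multiple cloned copies sequenced from the same
    specimen (relevant for multi-copy nuclear markers such as ITS2).
    ``morphotaxon`` is the morphological determination, or a group label such
    as "with hair setae" for specimens unidentifiable in an immature state.
    """

    seq_id: str
    residues: str
    marker: Marker = Marker.OTHER
    specimen_id: str | None = None
    clone_id: str | None = None
    morphotaxon: str | None = None
    maturity: Maturity = Maturity.IMMATURE
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.seq_id!r} has an empty sequence")
        self.residues = self.residues.upper()
        for col, ch in enumerate(self.residues):
            if ch not in ALLOWED_CHARS:
                raise IllegalCharacterError(
                    f"record {self.seq_id!r}: illegal character {ch!r} "
                    f"at alignment column {col}"
                )
        if self.specimen_id is None:
            self.specimen_id = self.seq_id

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignedSet:
    """An ordered collection of equal-length sequence records for one marker."""

    records: list[SequenceRecord]
    marker: Marker = Marker.OTHER

    def __post_init__(self) -> None:
        if self.records:
            lengths = {len(r) for r in self.records}
            if len(lengths) > 1:
                raise UnalignedInputError(
                    f"sequences have unequal lengths {sorted(lengths)}; "
                    "this pipeline consumes aligned input — run an aligner "
                    "(e.g. MUSCLE or MAFFT) first"
                )
        seen: set[str] = set()
        for r in self.records:
            if r.seq_id in seen:
                raise DuplicateIdError(f"duplicate seq_id {r.seq_id!r}")
            seen.add(r.seq_id)

    @property
    def length(self) -> int:
        """Number of alignment columns (0 for an empty set)."""
        return len(self.records[0]) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [r.seq_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def get(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.seq_id == seq_id:
                return r
        raise KeyError(seq_id)

    def subset(self, ids: Iterable[str]) -> "AlignedSet":
        wanted = list(ids)
        by_id = {r.seq_id: r for r in self.records}
        missing = [i for i in wanted if i not in by_id]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        return AlignedSet([by_id[i] for i in wanted], marker=self.marker)


def read_fasta(path: str | Path, marker: Marker | str = Marker.OTHER) -> AlignedSet:
    """Read an aligned multi-FASTA.

    The seq_id is the first whitespace-delimited token of the header; the
    remainder is kept as a free-text description.  Unequal sequence lengths
    raise :class:`UnalignedInputError`.
    """
    marker = Marker(marker)
    records = []
    for bio in SeqIO.parse(str(path), "fasta"):
        desc = bio.description
        if desc.startswith(bio.id):
            desc = desc[len(bio.id):].strip()
        records.append(
            SequenceRecord(seq_id=bio.id, residues=str(bio.seq), marker=marker,
                           description=desc)
        )
    return AlignedSet(records, marker=marker)


def write_fasta(aligned: AlignedSet, path: str | Path) -> None:
    """Write an AlignedSet; read(write(x)) reproduces ids, order and residues."""
    if not aligned.records:
        warnings.warn("writing an empty alignment", stacklevel=2)
    bio_records = [
        _BioSeqRecord(Seq(r.residues), id=r.seq_id, description=r.description)
        for r in aligned.records
    ]
    SeqIO.write(bio_records, str(path), "fasta")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the specimen-metadata table, indexed by seq_id.

    Expected columns: ``seq_id`` (required), then any of ``specimen_id``,
    ``clone_id``, ``marker``, ``morphotaxon``, ``maturity``, ``group``.
    Tab- or comma-separated; missing morphotaxon means immature/unassigned.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    if "seq_id" not in df.columns:
        raise ValueError(f"metadata {path}: missing required column 'seq_id'")
    dupes = df["seq_id"][df["seq_id"].duplicated()].tolist()
    if dupes:
        raise DuplicateIdError(f"metadata {path}: duplicate seq_id rows {dupes}")
    for col in METADATA_COLUMNS[1:]:
        if col not in df.columns:
            df[col] = ""
    df = df.set_index("seq_id")
    df.loc[(df["morphotaxon"] == "") & (df["maturity"] == ""), "maturity"] = \
        Maturity.IMMATURE.value
    df.loc[df["maturity"] == "", "maturity"] = Maturity.IDENTIFIED.value
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=True, index_label="seq_id")


def attach_metadata(aligned: AlignedSet, meta: pd.DataFrame) -> AlignedSet:
    """Return a copy of *aligned* with specimen/clone/morphotaxon fields filled.

    Records absent from the metadata are kept with maturity=immature and a
    logged warning (the common case of unidentifiable specimens).
    """
    out = []
    for r in aligned.records:
        if r.seq_id in meta.index:
            row = meta.loc[r.seq_id]
            out.append(replace(
                r,
                specimen_id=row.get("specimen_id") or r.seq_id,
                clone_id=row.get("clone_id") or None,
                morphotaxon=row.get("morphotaxon") or None,
                maturity=Maturity(row.get("maturity") or "immature"),
            ))
        else:
            logger.warning("seq_id %s absent from metadata; defaulting to "
                           "immature/unassigned", r.seq_id)
            out.append(replace(r, maturity=Maturity.IMMATURE))
    return AlignedSet(out, marker=aligned.marker)
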