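"""Synthetic germline V-gene database on the IMGT scaffold.

The bundled entries are consensus-style scaffolds written for this package
(camelid VHH-like and human VH3-like); they are *synthetic* sequences that
reproduce the structural features relevant to VHH analysis -- Hallmark
motif diversity (FERG/FERF/VEHG/YQRL vs the human-like VGLW), a
germline-encoded non-canonical cysteine at position 55 in the FERG entry,
and the canonical Cys23/Cys104 pair -- without copying any curated
database record.

Occupied scaffold columns follow the typical VH pattern: position 10 is
vacant, CDR1 spans 27-30 + 35-38 (length 8), CDR2 spans 56-59 + 62-65
(length 8), position 73 is vacant, CDR3 is a length-13 placeholder at
105-117 and FR4 occupies 118-128.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import NumberedSequence, Residue
from .errors import FormatError

SPECIES = ("human", "llama", "alpaca", "other")


@dataclass(frozen=True)
class GermlineEntry:
    name: str
    species: str
    numbered: NumberedSequence


@dataclass
class GermlineDB:
    entries: list

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise FormatError("germline names must be unique")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def by_name(self, name: str) -> GermlineEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def humans(self) -> list:
        return [e for e in self.entries if e.species == "human"]

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(e.numbered.sequence), id=e.name, description=f"{e.species}|{e.name}")
            for e in self.entries
        ]
        SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# scaffold construction

_SEGMENTS = [
    # (first position, residue string laid down consecutively over occupied columns)
    (1, "QVQLVESGG"),          # 1-9 (10 vacant)
    (11, "GLVQAGGSLRLSCAVS"),  # 11-26, Cys23, Leu12 (preADA site), Val25
    (27, "GRTF"),              # CDR1 head 27-30
    (35, "SSYA"),              # CDR1 tail 35-38
    (39, "IGWFRQAPGKEREGVAG"),  # 39-55: Ile39, Gly40, Trp41, Hallmark FERG core
    (56, "ISGS"),              # CDR2 head
    (62, "GGST"),              # CDR2 tail
    (66, "YYADSVK"),           # 66-72 (73 vacant)
    (74, "GRFTFSRDNAKNTVYLQMNSLKPEDTAVYYC"),  # 74-104, Phe78, Val87, Cys104
    (105, "AADRSTGWGYDEY"),    # CDR3 placeholder, length 13
    (118, "WGQGTQVTVSS"),      # FR4 118-128, Trp118
]


def scaffold_positions() -> list[int]:
    """Occupied IMGT columns of the consensus scaffold, in order."""
    out = []
    for start, seg in _SEGMENTS:
        out.extend(range(start, start + len(seg)))
    return out


def base_scaffold() -> dict[int, str]:
    """The camelid consensus scaffold as a position -> residue map."""
    table = {}
    for start, seg in _SEGMENTS:
        for i, aa in enumerate(seg):
            table[start + i] = aa
    return table


def _entry(name: str, species: str, overrides: dict[int, str]) -> GermlineEntry:
    table = base_scaffold()
    table.update(overrides)
    residues = [Residue(p, "", table[p]) for p in sorted(table)]
    return GermlineEntry(name, species, NumberedSequence(name, residues))


# Hallmark positions are 42/49/50/52; base scaffold carries F42 E49 R50 G52
# (FERG).  The human VH3-like entry differs from the camelid consensus at
# twelve framework/fringe positions, mirroring the typical humanization gap.
_HUMAN_DIFFS = {
    1: "E", 5: "L", 15: "P", 25: "A", 40: "S",
    42: "V", 49: "G", 50: "L", 52: "W", 55: "S",
    78: "I", 87: "L",
}

_DEFAULT_ENTRIES = [
    ("syncam-VHH-FERG*01", "llama", {55: "C"}),
    ("syncam-VHH-FERF*01", "llama", {52: "F"}),
    ("syncam-VHH-VEHG*01", "llama", {42: "V", 50: "H"}),
    ("syncam-VHH-YQRL*01", "alpaca", {42: "Y", 49: "Q", 52: "L"}),
    ("synhum-VH3-VGLW*01", "human", dict(_HUMAN_DIFFS)),
]


def default_germline_db() -> GermlineDB:
    """The packaged synthetic germline database."""
    return GermlineDB([_entry(*spec) for spec in _DEFAULT_ENTRIES])


def read_germline_fasta(path, reference_db: GermlineDB | None = None) -> GermlineDB:
    """Load a germline DB from FASTA (description carries ``species|allele``).

    Sequences are renumbered by profile transfer against ``reference_db``
    (the packaged scaffolds by default).
    """
    from .annotation import number_sequence

    reference_db = reference_db or default_germline_db()
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description.split(None, 1)
        meta = desc[1] if len(desc) > 1 else ""
        if "|" in meta:
            species, name = meta.split("|", 1)
            species = species.strip().lower()
        else:
            species, name = "other", rec.id
        if species not in SPECIES:
            species = "other"
        ns = number_sequence(str(rec.seq), reference_db, seq_id=name.strip() or rec.id)
        entries.append(GermlineEntry(ns.id, species, ns))
    return GermlineDB(entries)
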