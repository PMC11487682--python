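"""IMGT numbering and feature annotation of VHH sequences.

The central type is :class:`NumberedSequence`: an ordered list of residues
placed on the IMGT 1-128 scaffold, with CDR3 insertions carrying 111.x /
112.x insertion codes.  Numbering of a raw amino-acid string is done by
global alignment against the best-matching germline in a
:class:`~vhhkit.germlines.GermlineDB` (profile transfer), with the three
hypervariable loops renumbered by length according to the IMGT gapping
rules rather than trusting indel placement inside the loops:

* loop residues fill the loop span from both ends, leaving the gap in the
  middle (position 111 vacated first for CDR3);
* CDR3 longer than 13 residues receives insertion codes between 111 and
  112, assigned alternately (111.1, 112.1, 111.2, ...) and ordered
  111, 111.1, 111.2, ..., 112.2, 112.1, 112 within the sequence.

Feature accessors cover the Hallmark motif (positions 42/49/50/52),
region extraction under any scheme, CDR3 length and non-canonical
cysteine/disulfide annotation.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import (
    FormatError,
    MissingPosition,
    UnknownRegion,
    UnnumberableSequence,
)
from .schemes import RegionScheme, IMGT, get_scheme

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
VALID_AA = set(AA20) | {"X"}

# loop spans renumbered by the IMGT gapping rules
_LOOPS = {"cdr1": (27, 38), "cdr2": (56, 65), "cdr3": (105, 117)}


def imgt_key(position: int, insertion: str = "") -> tuple:
    """Sort key implementing IMGT ordering including 111.x/112.x insertions.

    Sequence order around the CDR3 apex is
    ``111 < 111.1 < 111.2 < ... < 112.2 < 112.1 < 112``.
    """
    if not insertion:
        return (position, 0, 0)
    n = int(insertion)
    if position == 111:
        return (111, 1, n)
    if position == 112:
        return (111, 2, -n)
    raise ValueError(f"insertion codes only allowed at 111/112, got {position}.{insertion}")


def format_position(position: int, insertion: str = "") -> str:
    return f"{position}.{insertion}" if insertion else str(position)


def parse_position(key: str) -> tuple[int, str]:
    if "." in key:
        base, ins = key.split(".", 1)
        return int(base), ins
    return int(key), ""


@dataclass(frozen=True)
class Residue:
    position: int
    insertion: str
    amino_acid: str

    @property
    def key(self) -> str:
        return format_position(self.position, self.insertion)


@dataclass
class NumberedSequence:
    """A VHH sequence on the IMGT scaffold."""

    id: str
    residues: list[Residue]
    source: str = ""

    def __post_init__(self):
        keys = [imgt_key(r.position, r.insertion) for r in self.residues]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError(f"{self.id}: residue positions not strictly increasing")
        for r in self.residues:
            if r.amino_acid not in VALID_AA:
                raise ValueError(f"{self.id}: invalid amino acid {r.amino_acid!r}")
        if not self.source:
            self.source = self.sequence

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def get(self, position: int, insertion: str = "") -> str | None:
        for r in self.residues:
            if r.position == position and r.insertion == insertion:
                return r.amino_acid
        return None

    @property
    def positions(self) -> set[int]:
        """Occupied scaffold positions (insertion-coded residues excluded)."""
        return {r.position for r in self.residues if not r.insertion}

    def as_dict(self) -> dict[str, str]:
        return {r.key: r.amino_acid for r in self.residues}

    @classmethod
    def from_position_map(cls, seq_id: str, mapping: dict, source: str = "") -> "NumberedSequence":
        items = []
        for key, aa in mapping.items():
            pos, ins = parse_position(str(key)) if not isinstance(key, tuple) else (key[0], key[1])
            items.append(Residue(pos, ins, aa))
        items.sort(key=lambda r: imgt_key(r.position, r.insertion))
        return cls(seq_id, items, source)


@dataclass(frozen=True)
class DisulfideAnnotation:
    """Non-canonical cysteine content of a sequence.

    ``pairing_class`` is ``interloop_cdr3`` when at least one non-canonical
    Cys lies inside IMGT CDR3 and at least one outside, ``intraloop_cdr3``
    when two or more lie inside CDR3 and none outside, ``unpaired`` when an
    odd cysteine is left over, ``none`` when there are no non-canonical
    cysteines.
    """

    noncanonical_positions: frozenset
    pairing_class: str
    putative_pairs: tuple


# ---------------------------------------------------------------------------
# loop renumbering


def loop_position_keys(loop: str, length: int) -> list[tuple[int, str]]:
    """IMGT (position, insertion) keys for a loop of ``length`` residues."""
    start, end = _LOOPS[loop]
    span = end - start + 1
    if length <= span:
        head = (length + 1) // 2
        tail = length - head
        keys = [(p, "") for p in range(start, start + head)]
        keys += [(p, "") for p in range(end - tail + 1, end + 1)]
        return keys
    if loop != "cdr3":
        raise UnnumberableSequence(
            f"{loop} length {length} exceeds its IMGT span and insertion codes are "
            "only defined for CDR3"
        )
    extra = length - span
    n111 = (extra + 1) // 2
    n112 = extra - n111
    keys = [(p, "") for p in range(start, 112)]            # 105..111
    keys += [(111, str(i)) for i in range(1, n111 + 1)]     # 111.1 ..
    keys += [(112, str(i)) for i in range(n112, 0, -1)]     # .. 112.1
    keys += [(p, "") for p in range(112, end + 1)]          # 112..117
    return keys


# ---------------------------------------------------------------------------
# numbering by germline profile transfer

_ANCHORS = (26, 39, 55, 66, 104, 118)  # conserved flanks of the three loops


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # terminal overhangs (purification tags etc.) are free
    try:
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    except AttributeError:  # older biopython
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


def _aligned_pairs(germ_seq: str, raw: str) -> list[tuple[int, int]]:
    aligner = _make_aligner()
    alignment = aligner.align(germ_seq, raw)[0]
    pairs = []
    for (ts, te), (qs, qe) in zip(*alignment.aligned):
        pairs.extend((ts + i, qs + i) for i in range(te - ts))
    return pairs


def number_sequence(
    raw: str, db, identity_floor: float = 0.40, seq_id: str = "query"
) -> NumberedSequence:
    """Place ``raw`` on the IMGT scaffold using the best-matching germline.

    The germline is chosen by global alignment score over the whole
    database; numbering is transferred from the germline at aligned
    framework columns, while CDR1/CDR2/CDR3 segments (delimited by the
    conserved anchors 26/39, 55/66 and 104/118) are renumbered from their
    length by the IMGT gapping rules.  Raw residues that align outside the
    germline (N/C-terminal tags) are not numbered.

    Raises :class:`UnnumberableSequence` when the identity to the best
    germline falls below ``identity_floor`` or an anchor cannot be placed.
    """
    raw = raw.strip().upper()
    if not 90 <= len(raw) <= 180:
        raise UnnumberableSequence(f"sequence length {len(raw)} outside 90-180")
    bad = set(raw) - VALID_AA
    if bad:
        raise UnnumberableSequence(f"invalid characters in sequence: {sorted(bad)}")

    aligner = _make_aligner()
    best = None
    for entry in db.entries:
        score = aligner.score(entry.numbered.sequence, raw)
        if best is None or score > best[0]:
            best = (score, entry)
    if best is None:
        raise UnnumberableSequence("germline database is empty")
    germ = best[1].numbered
    germ_seq = germ.sequence

    pairs = _aligned_pairs(germ_seq, raw)
    matches = sum(1 for ti, qi in pairs if germ_seq[ti] == raw[qi])
    identity = matches / len(germ_seq)
    if identity < identity_floor:
        raise UnnumberableSequence(
            f"identity {identity:.2f} to best germline {best[1].name} below floor {identity_floor}"
        )

    germ_residues = germ.residues
    t2q = dict(pairs)

    anchor_t = {}
    for pos in _ANCHORS:
        for i, r in enumerate(germ_residues):
            if r.position == pos and not r.insertion:
                anchor_t[pos] = i
                break
        else:
            raise UnnumberableSequence(f"germline {best[1].name} lacks anchor position {pos}")
    anchor_q = {}
    for pos, ti in anchor_t.items():
        if ti not in t2q:
            raise UnnumberableSequence(f"anchor position {pos} could not be placed")
        anchor_q[pos] = t2q[ti]

    loop_bounds = {"cdr1": (26, 39), "cdr2": (55, 66), "cdr3": (104, 118)}
    in_loop_t = set()
    for loop, (a, b) in loop_bounds.items():
        lo, hi = _LOOPS[loop]
        for i, r in enumerate(germ_residues):
            if lo <= r.position <= hi:
                in_loop_t.add(i)

    residues: list[Residue] = []
    # framework columns: direct transfer at aligned pairs
    for ti, qi in pairs:
        if ti in in_loop_t:
            continue
        gr = germ_residues[ti]
        residues.append(Residue(gr.position, gr.insertion, raw[qi]))
    # loops: renumber by length between the anchors
    for loop, (a, b) in loop_bounds.items():
        qa, qb = anchor_q[a], anchor_q[b]
        segment = raw[qa + 1 : qb]
        if not segment and loop != "cdr3":
            continue
        for (pos, ins), aa in zip(loop_position_keys(loop, len(segment)), segment):
            residues.append(Residue(pos, ins, aa))

    residues.sort(key=lambda r: imgt_key(r.position, r.insertion))
    return NumberedSequence(seq_id, residues, source=raw)


# ---------------------------------------------------------------------------
# predicates and accessors


def is_fully_annotated(
    ns: NumberedSequence,
    scheme: RegionScheme = IMGT,
    require_cys: bool = True,
    require_fr4_anchor: bool = True,
) -> bool:
    """True when all four FRs are populated and the conserved anchors hold.

    Default rule: FR1-FR4 each contain at least one residue, positions 23
    and 104 are cysteine, and position 118 (the FR4 W/F anchor) is present.
    The cysteine and anchor requirements can be relaxed for permissive
    pipelines.
    """
    occupied = ns.positions
    for fr in ("fr1", "fr2", "fr3", "fr4"):
        if not (scheme.region(fr) & occupied):
            return False
    if require_cys and (ns.get(23) != "C" or ns.get(104) != "C"):
        return False
    if require_fr4_anchor and 118 not in occupied:
        return False
    return True


def get_region(ns: NumberedSequence, scheme: RegionScheme | str, region: str) -> str:
    """Residues of ``region`` under ``scheme``, concatenated in IMGT order.

    CDR3 insertion-coded residues are included in cdr3 (and excluded from
    the FRs).
    """
    scheme = get_scheme(scheme)
    cols = scheme.region(region)
    return "".join(r.amino_acid for r in ns.residues if r.position in cols)


def hallmark_motif(ns: NumberedSequence) -> str:
    """The 4-residue Hallmark signature at IMGT 42/49/50/52 (e.g. FERG)."""
    out = []
    for pos in (42, 49, 50, 52):
        aa = ns.get(pos)
        if aa is None:
            raise MissingPosition(f"{ns.id}: Hallmark position {pos} absent")
        out.append(aa)
    return "".join(out)


def cdr3_length(ns: NumberedSequence) -> int:
    """Number of residues in IMGT CDR3 (105-117), insertions included."""
    n = sum(1 for r in ns.residues if 105 <= r.position <= 117)
    if n == 0:
        warnings.warn(f"{ns.id}: empty CDR3", stacklevel=2)
    return n


def noncanonical_cysteines(
    ns: NumberedSequence, scheme: RegionScheme | str = IMGT
) -> DisulfideAnnotation:
    """Annotate cysteines beyond the conserved Cys23-Cys104 pair.

    Putative pairs are assigned greedily: each CDR3 cysteine is paired with
    the nearest available non-CDR3 non-canonical cysteine; leftovers inside
    CDR3 are paired with each other (intraloop).
    """
    scheme = get_scheme(scheme)
    cdr3_cols = scheme.cdr3
    noncanon = [
        r for r in ns.residues if r.amino_acid == "C" and r.position not in (23, 104)
    ]
    inside = [r for r in noncanon if r.position in cdr3_cols]
    outside = [r for r in noncanon if r.position not in cdr3_cols]

    pairs = []
    free_outside = list(outside)
    unpaired_inside = []
    for r in inside:
        if free_outside:
            partner = min(free_outside, key=lambda o: abs(o.position - r.position))
            free_outside.remove(partner)
            pairs.append((partner.key, r.key))
        else:
            unpaired_inside.append(r)
    while len(unpaired_inside) >= 2:
        a = unpaired_inside.pop(0)
        b = unpaired_inside.pop(0)
        pairs.append((a.key, b.key))

    if not noncanon:
        cls = "none"
    elif inside and outside:
        cls = "interloop_cdr3"
    elif len(inside) >= 2 and not outside:
        cls = "intraloop_cdr3"
    elif len(noncanon) % 2 == 1 or not inside:
        cls = "unpaired" if len(noncanon) % 2 == 1 else "other"
    else:
        cls = "other"

    return DisulfideAnnotation(
        noncanonical_positions=frozenset(r.key for r in noncanon),
        pairing_class=cls,
        putative_pairs=tuple(pairs),
    )


# ---------------------------------------------------------------------------
# numbering-table I/O (one column per IMGT key, '-' for gap)


def _scaffold_columns(extra_keys: Iterable[str] = ()) -> list[str]:
    cols = [str(p) for p in range(1, 129)]
    extras = sorted(set(extra_keys), key=lambda k: imgt_key(*parse_position(k)))
    merged = [format_position(p, i) for p, i in sorted(
        {parse_position(c) for c in cols} | {parse_position(k) for k in extras},
        key=lambda t: imgt_key(*t),
    )]
    return merged


def write_numbering_table(path, seqs: Sequence[NumberedSequence]) -> None:
    extra = [r.key for ns in seqs for r in ns.residues if r.insertion]
    columns = _scaffold_columns(extra)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id"] + columns)
        for ns in seqs:
            d = ns.as_dict()
            writer.writerow([ns.id] + [d.get(c, "-") for c in columns])


def read_numbering_table(path) -> list[NumberedSequence]:
    """Read an IMGT numbering table (one column per position key).

    Rows that fail :func:`is_fully_annotated` are still returned; callers
    filter with the predicate.  Raises :class:`FormatError` when the
    scaffold columns are missing.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            logger.warning("numbering table %s is empty", path)
            return []
        if not header or header[0] != "id":
            raise FormatError(f"{path}: first column must be 'id'")
        keys = []
        for col in header[1:]:
            try:
                keys.append(parse_position(col))
            except ValueError:
                raise FormatError(f"{path}: bad position column {col!r}") from None
        present = {p for p, ins in keys if not ins}
        required = {23, 104, 118}
        if not required <= present:
            raise FormatError(f"{path}: missing scaffold columns {sorted(required - present)}")
        out = []
        for row in reader:
            if not row:
                continue
            seq_id, cells = row[0], row[1:]
            residues = [
                Residue(p, ins, aa)
                for (p, ins), aa in zip(keys, cells)
                if aa and aa != "-"
            ]
            residues.sort(key=lambda r: imgt_key(r.position, r.insertion))
            ns = NumberedSequence(seq_id, residues)
            if not is_fully_annotated(ns):
                logger.info("sequence %s is not fully annotated", seq_id)
            out.append(ns)
        if not out:
            logger.warning("numbering table %s contains no sequences", path)
        return out
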