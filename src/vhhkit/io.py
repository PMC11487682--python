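"""FASTA input/output helpers."""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import NumberedSequence
from .errors import EmptyInput


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, items) -> None:
    """Write ``(id, sequence)`` pairs or numbered sequences to FASTA."""
    records = []
    for item in items:
        if isinstance(item, NumberedSequence):
            records.append(SeqRecord(Seq(item.sequence), id=item.id, description=""))
        else:
            seq_id, seq = item
            records.append(SeqRecord(Seq(seq), id=seq_id, description=""))
    if not records:
        raise EmptyInput("nothing to write")
    SeqIO.write(records, str(path), "fasta")
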