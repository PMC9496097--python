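"""Small sequence / file helpers shared across modules.

FASTA/FASTQ parsing is delegated to Biopython; paths ending in ``.gz`` are
transparently decompressed.
"""

from __future__ import annotations

import gzip
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_RC = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def translate(nt: str) -> str:
    return str(Seq(nt).translate())


def open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[tuple[str, str]]:
    with open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records, path) -> None:
    """records: iterable of (id, sequence)."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open_text(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    with open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fastq")]


def write_fastq(records, path) -> None:
    """records: iterable of (id, sequence, quality-string)."""
    with open_text(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
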