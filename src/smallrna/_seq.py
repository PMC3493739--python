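"""Shared sequence utilities: complementing, FASTA I/O."""

from __future__ import annotations

from typing import Dict, Iterable, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def dna(seq: str) -> str:
    """Uppercase and map U->T so RNA-style input can be handled as DNA."""
    return seq.upper().replace("U", "T")


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[Tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta-2line",
    )
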