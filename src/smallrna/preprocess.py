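"""Raw-read cleaning and tag collapsing.

Small-RNA sequencing reads are the cDNA insert followed by the 3' sequencing
adapter (and occasionally a 5'-adapter ligation artifact at the read start).
This module turns raw FASTQ reads into "clean reads" and collapses identical
inserts into unique tags with counts, the unit every downstream stage works on.

Cleaning applies, in order: a base-quality filter, rejection of 5'-adapter
contaminants, 3'-adapter trimming, and an inclusive length window (default
18-30 nt).  Each rejected read is attributed to exactly the first rule it
fails, so raw read counts are conserved across kept + rejected.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO

# Rejection reasons, in the order the rules are applied.
REASON_QUALITY = "quality"
REASON_ADAPTER5 = "adapter5_contaminant"
REASON_NO_ADAPTER3 = "no_adapter3"
REASON_LENGTH = "length"
KEPT = "kept"

REASONS = (REASON_QUALITY, REASON_ADAPTER5, REASON_NO_ADAPTER3, REASON_LENGTH)


@dataclass(frozen=True, order=True)
class Tag:
    """A unique small-RNA insert sequence with its read count in one library."""

    sequence: str
    count: int

    def __post_init__(self):
        if not self.sequence or self.sequence != self.sequence.upper():
            raise ValueError("tag sequence must be a non-empty uppercase string")
        if self.count < 1:
            raise ValueError("tag count must be >= 1")


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def quality_ok(sequence: str, qualities: Optional[Sequence[int]], min_mean_phred: float = 20.0) -> bool:
    """Mean Phred >= threshold and no ambiguous base.

    Reads without quality strings (e.g. FASTA input) pass the Phred part.
    """
    if "N" in sequence.upper():
        return False
    if qualities is not None and len(qualities) > 0:
        if sum(qualities) / len(qualities) < min_mean_phred:
            return False
    return True


def trim_3prime_adapter(
    read: str,
    adapter: str,
    min_overlap: int = 6,
    mismatch_per_10: int = 1,
    require_adapter: bool = True,
) -> Optional[str]:
    """Return the insert before the left-most 3'-adapter match, or None.

    The adapter may be truncated at the read end; an overlap of at least
    ``min_overlap`` bases is required, allowing ``mismatch_per_10`` mismatches
    per 10 compared adapter bases (floor).  A match at position 0 means the
    read is pure adapter: the empty insert is returned (and later length-
    rejected).  With ``require_adapter`` (default) reads without any adapter
    occurrence are rejected (None); otherwise they pass through untrimmed.
    """
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    read = read.upper()
    adapter = adapter.upper()
    if not read:
        return None
    for pos in range(0, len(read) - min_overlap + 1):
        overlap = min(len(adapter), len(read) - pos)
        allowed = (overlap // 10) * mismatch_per_10
        if _mismatches(read[pos : pos + overlap], adapter[:overlap]) <= allowed:
            return read[:pos]
    return None if require_adapter else read


def is_5prime_contaminant(read: str, adapter5: str, min_overlap: int = 8, max_mismatches: int = 1) -> bool:
    """True if the read starts with the 5' adapter (ligation artifact).

    Only a prefix match counts: the adapter occurring internally is part of a
    legitimate insert and leaves the read untouched.
    """
    read = read.upper()
    adapter5 = adapter5.upper()
    overlap = min(len(read), len(adapter5))
    if overlap < min_overlap:
        return False
    return _mismatches(read[:overlap], adapter5[:overlap]) <= max_mismatches


def remove_5prime_contaminant(read: str, adapter5: str, **kw) -> Optional[str]:
    """Reject (None) 5'-adapter contaminants; otherwise return the read unchanged."""
    return None if is_5prime_contaminant(read, adapter5, **kw) else read


def length_filter(insert: str, min_len: int = 18, max_len: int = 30) -> bool:
    """Keep inserts with min_len <= length <= max_len (inclusive bounds)."""
    return min_len <= len(insert) <= max_len


def collapse(inserts: Iterable[str]) -> List[Tag]:
    """Collapse identical inserts into unique tags; sum of counts is conserved."""
    counts = Counter(s.upper() for s in inserts)
    return [Tag(seq, n) for seq, n in sorted(counts.items())]


@dataclass
class CleanResult:
    tags: List[Tag]
    rejections: Counter = field(default_factory=Counter)

    @property
    def kept_reads(self) -> int:
        return sum(t.count for t in self.tags)

    @property
    def total_reads(self) -> int:
        return self.kept_reads + sum(self.rejections.values())


def clean_reads(
    reads: Iterable[Tuple[str, Optional[Sequence[int]]]],
    adapter3: str,
    adapter5: Optional[str] = None,
    min_len: int = 18,
    max_len: int = 30,
    min_overlap: int = 6,
    min_mean_phred: float = 20.0,
    require_adapter: bool = True,
) -> CleanResult:
    """Run the full cleaning cascade over (sequence, qualities) pairs.

    Each read is kept or attributed to exactly one rejection reason, the first
    failing rule in order: quality, 5' contaminant, no 3' adapter, length.
    """
    inserts: List[str] = []
    rejections: Counter = Counter()
    for seq, quals in reads:
        if not quality_ok(seq, quals, min_mean_phred):
            rejections[REASON_QUALITY] += 1
            continue
        if adapter5 is not None and is_5prime_contaminant(seq, adapter5):
            rejections[REASON_ADAPTER5] += 1
            continue
        insert = trim_3prime_adapter(seq, adapter3, min_overlap=min_overlap, require_adapter=require_adapter)
        if insert is None:
            rejections[REASON_NO_ADAPTER3] += 1
            continue
        if not length_filter(insert, min_len, max_len):
            rejections[REASON_LENGTH] += 1
            continue
        inserts.append(insert)
    return CleanResult(tags=collapse(inserts), rejections=rejections)


def clean_fastq(path, **kw) -> CleanResult:
    """Clean a FASTQ (Phred+33) file into tags."""
    def _iter():
        for rec in SeqIO.parse(str(path), "fastq"):
            yield str(rec.seq), rec.letter_annotations["phred_quality"]

    return clean_reads(_iter(), **kw)


def write_tag_fasta(tags: Sequence[Tag], path) -> None:
    """Write tags as FASTA with the common ``>tagN_xCOUNT`` header convention."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags, start=1):
            fh.write(f">tag{i}_x{tag.count}\n{tag.sequence}\n")


def read_tag_fasta(path) -> List[Tag]:
    tags = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = int(rec.id.rsplit("_x", 1)[1])
        tags.append(Tag(str(rec.seq).upper(), count))
    return tags
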