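"""Exact genome mapping and the small-RNA category cascade.

Tags are mapped to the genome requiring a perfect full-length match on either
strand (minus-strand hits are reported in plus-strand coordinates of the match
span).  Each genome-matched tag then receives exactly one category: the first
class in the priority cascade rRNA > scRNA > snoRNA > snRNA > piRNA > tRNA >
repeat > exon_intron whose annotation interval overlaps any hit by >= 1 base
on the same strand; failing that, an exact sequence match against known mature
miRNAs gives known_miRNA; everything else is unannotated.  Unannotated tags
are the input to novel-miRNA discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from ._seq import DNA_ALPHABET, revcomp
from .preprocess import Tag

CATEGORY_PRIORITY: Tuple[str, ...] = (
    "rRNA",
    "scRNA",
    "snoRNA",
    "snRNA",
    "piRNA",
    "tRNA",
    "repeat",
    "exon_intron",
)
KNOWN_MIRNA = "known_miRNA"
UNANNOTATED = "unannotated"


@dataclass(frozen=True, order=True)
class GenomeHit:
    """A perfect full-length match span, 1-based inclusive, plus-strand coords."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid hit span {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class Interval:
    """An annotation interval, 1-based inclusive (converted from BED on read)."""

    chrom: str
    start: int
    end: int
    strand: str
    category: str


@dataclass
class CategoryAssignment:
    tag: Tag
    hits: List[GenomeHit]
    category: Optional[str]  # None for tags with no genome hit


class GenomeIndex:
    """k-mer seed-and-verify index returning all and only perfect matches.

    Seeds of length k (default 12) anchor candidate offsets; each candidate is
    verified by direct comparison, so the hit set equals a naive scan.
    """

    def __init__(self, chromosomes: Mapping[str, str], k: int = 12):
        self.chromosomes = {name: seq.upper() for name, seq in chromosomes.items()}
        self.k = k
        self._index: Dict[str, List[Tuple[str, int]]] = {}
        for name, seq in self.chromosomes.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((name, i))

    def _find_forward(self, query: str) -> List[Tuple[str, int]]:
        k = self.k
        if len(query) < k:
            # rare path: query shorter than the seed, fall back to scanning
            out = []
            for name, seq in self.chromosomes.items():
                start = seq.find(query)
                while start != -1:
                    out.append((name, start))
                    start = seq.find(query, start + 1)
            return out
        seed = query[:k]
        out = []
        for name, offset in self._index.get(seed, ()):
            if self.chromosomes[name][offset : offset + len(query)] == query:
                out.append((name, offset))
        return out

    def find(self, sequence: str) -> List[GenomeHit]:
        """All perfect full-length hits of ``sequence`` on both strands."""
        sequence = sequence.upper()
        if not sequence or not set(sequence) <= DNA_ALPHABET:
            return []
        hits = set()
        for name, off in self._find_forward(sequence):
            hits.add(GenomeHit(name, off + 1, off + len(sequence), "+"))
        for name, off in self._find_forward(revcomp(sequence)):
            hits.add(GenomeHit(name, off + 1, off + len(sequence), "-"))
        return sorted(hits)


def map_exact(tags: Sequence[Tag], genome: Mapping[str, str], k: int = 12) -> Dict[str, List[GenomeHit]]:
    """Map each tag sequence to its perfect-match hits (empty list if none)."""
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, k=k)
    return {tag.sequence: index.find(tag.sequence) for tag in tags}


def genome_match_percentage(matched: int, total: int) -> float:
    """100*matched/total, rounded half-up to two decimals."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= matched <= total:
        raise ValueError("matched must lie in [0, total]")
    pct = Decimal(100 * matched) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def read_bed(path) -> List[Interval]:
    """Read annotation intervals from BED (0-based half-open; name=category).

    Columns: chrom, start, end, category, score, strand.  Converted to 1-based
    inclusive coordinates internally.
    """
    intervals = []
    allowed = set(CATEGORY_PRIORITY)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, start, end, category, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start_i < 0 or end_i <= start_i:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}..{end}")
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            if category not in allowed:
                raise ValueError(f"{path}:{lineno}: unknown category {category!r}")
            intervals.append(Interval(chrom, start_i + 1, end_i, strand, category))
    return intervals


def _overlaps(hit: GenomeHit, iv: Interval) -> bool:
    return (
        hit.chrom == iv.chrom
        and hit.strand == iv.strand
        and hit.start <= iv.end
        and iv.start <= hit.end
    )


def assign_category(
    tag: Tag,
    hits: Sequence[GenomeHit],
    intervals: Sequence[Interval],
    known_matures: Mapping[str, str],
    priority: Sequence[str] = CATEGORY_PRIORITY,
) -> CategoryAssignment:
    """One category per genome-matched tag via the priority cascade.

    ``known_matures`` maps mature miRNA sequence -> name; membership is an
    exact sequence match.  Tags with no genome hit carry no category (None).
    """
    hits = list(hits)
    if not hits:
        return CategoryAssignment(tag, [], None)
    by_cat: Dict[str, bool] = {}
    for iv in intervals:
        if iv.category in by_cat:
            continue
        if any(_overlaps(h, iv) for h in hits):
            by_cat[iv.category] = True
    for cat in priority:
        if by_cat.get(cat):
            return CategoryAssignment(tag, hits, cat)
    if tag.sequence in known_matures:
        return CategoryAssignment(tag, hits, KNOWN_MIRNA)
    return CategoryAssignment(tag, hits, UNANNOTATED)


def annotate(
    tags: Sequence[Tag],
    genome: Mapping[str, str],
    intervals: Sequence[Interval],
    known_matures: Mapping[str, str],
    priority: Sequence[str] = CATEGORY_PRIORITY,
) -> List[CategoryAssignment]:
    """Map and categorize a whole tag set."""
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    return [
        assign_category(tag, index.find(tag.sequence), intervals, known_matures, priority)
        for tag in tags
    ]


def summarize(assignments: Iterable[CategoryAssignment]) -> pd.DataFrame:
    """Per-category unique-tag and total-read counts (plus 'unmatched').

    Read counts are conserved: the column sums equal the input totals.
    """
    rows: Dict[str, List[int]] = {}
    for a in assignments:
        cat = a.category if a.category is not None else "unmatched"
        entry = rows.setdefault(cat, [0, 0])
        entry[0] += 1
        entry[1] += a.tag.count
    order = list(CATEGORY_PRIORITY) + [KNOWN_MIRNA, UNANNOTATED, "unmatched"]
    data = [(cat, *rows[cat]) for cat in order if cat in rows]
    data += [(cat, *v) for cat, v in sorted(rows.items()) if cat not in order]
    return pd.DataFrame(data, columns=["category", "unique_tags", "total_reads"])


def known_mirna_counts(
    assignments: Iterable[CategoryAssignment], known_matures: Mapping[str, str]
) -> Dict[str, int]:
    """Read counts per known mature miRNA name (0 for matures never seen)."""
    counts = {name: 0 for name in known_matures.values()}
    for a in assignments:
        if a.category == KNOWN_MIRNA:
            counts[known_matures[a.tag.sequence]] += a.tag.count
    return counts
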