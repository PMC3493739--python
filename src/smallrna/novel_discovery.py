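"""Novel miRNA candidate calling from stem-loop (hairpin) evidence.

Unannotated, genome-matched tags are tested for residing on one arm of a
foldable hairpin precursor, the classic evidentiary criterion for a novel
miRNA.  The folding engine is a deliberately small nearest-neighbor model:

* pair strengths (kcal/mol): G:C 3.3, A:U 0.9, G:U 1.0;
* a stack of two adjacent pairs contributes minus the mean of the two pair
  strengths (so a GC/GC stack is -3.3, an AU/AU stack -0.9, GU/GU -1.0);
* linear loop penalties (hairpin loop: 1.0 + 0.1/nt; bulge/interior loop:
  1.0 + 0.5 per unpaired nt, capped at 6 nt per side);
* no multibranch loops - the folder targets single stem-loops, which is
  exactly the geometry a pre-miRNA must have.

Absolute energies from this model are not comparable to full Turner-rule
folders; candidate calling only relies on relative stability and geometry
(precursor 60-100 nt, MFE <= -18 kcal/mol, mature fully inside one arm with
>= 14 of its bases paired, terminal loop 3-20 nt).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from ._seq import dna, revcomp
from .annotation import GenomeHit
from .preprocess import Tag

# --- energy model constants -------------------------------------------------

PAIR_STRENGTH: Dict[Tuple[str, str], float] = {
    ("G", "C"): 3.3,
    ("C", "G"): 3.3,
    ("A", "T"): 0.9,
    ("T", "A"): 0.9,
    ("G", "T"): 1.0,
    ("T", "G"): 1.0,
}
MIN_LOOP = 3  # minimum unpaired bases closed by a pair
HAIRPIN_A, HAIRPIN_B = 1.0, 0.1  # hairpin loop penalty: A + B*size
INTERIOR_A, INTERIOR_B = 1.0, 0.5  # interior/bulge penalty: A + B*(unpaired nt)
MAX_INTERIOR_SIDE = 6  # max unpaired nt on either side of an interior loop


def stack_energy(p1: Tuple[str, str], p2: Tuple[str, str]) -> float:
    return -(PAIR_STRENGTH[p1] + PAIR_STRENGTH[p2]) / 2.0


# --- Table-I-style records --------------------------------------------------


@dataclass(frozen=True, order=True)
class Locus:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"locus start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def overlaps(self, other: "Locus") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start <= other.end
            and other.start <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}:{self.end}:{self.strand}"


@dataclass(frozen=True)
class HairpinCandidate:
    """A novel-miRNA candidate: mature tag + the hairpin precursor hosting it."""

    name: str
    sequence: str
    arm: str  # "5p" | "3p"
    locus: Locus  # precursor span, 1-based inclusive
    precursor_length: int
    mfe: float
    count: int

    def __post_init__(self):
        if self.precursor_length != self.locus.end - self.locus.start + 1:
            raise ValueError("precursor_length inconsistent with locus span")
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"invalid arm {self.arm!r}")
        if self.mfe >= 0:
            raise ValueError("hairpin MFE must be negative")
        if self.count < 1:
            raise ValueError("count must be >= 1")

    @property
    def mature_length(self) -> int:
        return len(self.sequence)


_DASHES = {"−": "-", "–": "-", "—": "-"}  # unicode minus/dashes


def parse_location(text: str) -> Locus:
    """Parse ``chrN:start:end:strand``; tolerates unicode minus and stray spaces."""
    norm = text
    for uni, ascii_ in _DASHES.items():
        norm = norm.replace(uni, ascii_)
    fields = [f.strip() for f in norm.split(":")]
    if len(fields) != 4:
        raise ValueError(f"location {text!r}: expected 4 colon-separated fields")
    chrom, start_s, end_s, strand = fields
    if not chrom:
        raise ValueError(f"location {text!r}: empty chromosome field")
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(f"location {text!r}: non-integer coordinate") from exc
    if strand not in "+-":
        raise ValueError(f"location {text!r}: invalid strand field {strand!r}")
    return Locus(chrom, start, end, strand)


def precursor_length(locus: Locus) -> int:
    """Length in nt of a 1-based inclusive span: end - start + 1."""
    return locus.end - locus.start + 1


# --- folding ----------------------------------------------------------------


@dataclass
class Fold:
    sequence: str
    pairs: List[Tuple[int, int]]  # 0-based (i, j) pairs, outermost first
    mfe: float

    @property
    def structure(self) -> str:
        chars = ["."] * len(self.sequence)
        for i, j in self.pairs:
            chars[i], chars[j] = "(", ")"
        return "".join(chars)


def fold_hairpin(sequence: str) -> Tuple[str, float]:
    """Fold one RNA/DNA sequence into its best stem-loop.

    Returns (dot-bracket structure, MFE in kcal/mol).  A sequence with no
    stabilizing structure returns all-dots and 0.0.
    """
    fold = _fold(sequence)
    return fold.structure, fold.mfe


def _dp(seq: str) -> Tuple[Dict[Tuple[int, int], float], Dict[Tuple[int, int], Optional[Tuple[int, int]]]]:
    """Fill V[(i,j)] = energy of the best stem-loop closed by pair (i,j)."""
    n = len(seq)
    pairable = PAIR_STRENGTH.__contains__
    V: Dict[Tuple[int, int], float] = {}
    choice: Dict[Tuple[int, int], Optional[Tuple[int, int]]] = {}
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            pij = (seq[i], seq[j])
            if not pairable(pij):
                continue
            best = HAIRPIN_A + HAIRPIN_B * (j - i - 1)
            best_child: Optional[Tuple[int, int]] = None
            pmax = min(i + 1 + MAX_INTERIOR_SIDE, j - 1)
            for p in range(i + 1, pmax + 1):
                qmin = max(j - 1 - MAX_INTERIOR_SIDE, p + 1)
                for q in range(j - 1, qmin - 1, -1):
                    inner = V.get((p, q))
                    if inner is None:
                        continue
                    if p == i + 1 and q == j - 1:
                        e = inner + stack_energy(pij, (seq[p], seq[q]))
                    else:
                        unpaired = (p - i - 1) + (j - q - 1)
                        e = inner + INTERIOR_A + INTERIOR_B * unpaired
                    if e < best:
                        best, best_child = e, (p, q)
            V[(i, j)] = best
            choice[(i, j)] = best_child
    return V, choice


def _traceback(
    choice: Dict[Tuple[int, int], Optional[Tuple[int, int]]], node: Tuple[int, int]
) -> List[Tuple[int, int]]:
    pairs = []
    cur: Optional[Tuple[int, int]] = node
    while cur is not None:
        pairs.append(cur)
        cur = choice[cur]
    return pairs


def _validated(sequence: str) -> str:
    seq = dna(sequence)
    if len(seq) < 2 * MIN_LOOP:
        raise ValueError("sequence too short to fold")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGU characters after T/U mapping: {sorted(bad)}")
    return seq


def _fold(sequence: str) -> Fold:
    seq = _validated(sequence)
    V, choice = _dp(seq)
    if not V:
        return Fold(seq, [], 0.0)
    (i0, j0), mfe = min(V.items(), key=lambda kv: (kv[1], kv[0]))
    if mfe >= 0:
        return Fold(seq, [], 0.0)
    return Fold(seq, _traceback(choice, (i0, j0)), mfe)


# --- candidate calling ------------------------------------------------------


@dataclass
class HairpinCallConfig:
    """Thresholds of the stem-loop caller (all configurable)."""

    flank: int = 80  # nt of genomic context folded on each side of the tag
    min_precursor: int = 60
    max_precursor: int = 100
    max_mfe: float = -18.0  # kcal/mol; candidates must fold at or below this
    min_mature_paired: int = 14
    min_loop: int = 3
    max_loop: int = 20
    min_count: int = 3  # tags below this read count are not folded


def _evaluate_window(
    wseq: str, m0: int, m1: int, cfg: HairpinCallConfig
) -> Optional[Tuple[int, int, str, float]]:
    """Fold a window and test hairpin geometry around the mature at [m0, m1].

    The precursor is the minimum-energy stem-loop whose closing pair encloses
    the mature within the allowed precursor length; this trims incidental
    base-pairing of the flanking genomic context out of the precursor call.
    Returns (precursor start, precursor end, arm, mfe) in window coordinates,
    or None if any criterion fails.
    """
    V, choice = _dp(_validated(wseq))
    candidates = [
        (energy, ij)
        for ij, energy in V.items()
        if ij[0] <= m0
        and m1 <= ij[1]
        and cfg.min_precursor <= ij[1] - ij[0] + 1 <= cfg.max_precursor
        and energy <= cfg.max_mfe
    ]
    if not candidates:
        return None
    mfe, (outer_i, outer_j) = min(candidates)
    pairs = _traceback(choice, (outer_i, outer_j))
    inner_i, inner_j = pairs[-1]
    loop_len = inner_j - inner_i - 1
    if not cfg.min_loop <= loop_len <= cfg.max_loop:
        return None
    if m1 <= inner_i:
        arm = "5p"
    elif m0 >= inner_j:
        arm = "3p"
    else:
        return None  # mature straddles the terminal loop
    paired = sum(1 for i, j in pairs if m0 <= i <= m1 or m0 <= j <= m1)
    if paired < cfg.min_mature_paired:
        return None
    return outer_i, outer_j, arm, mfe


def call_candidates(
    tags_with_hits: Mapping[str, Tuple[Tag, Sequence[GenomeHit]]] | Sequence[Tuple[Tag, Sequence[GenomeHit]]],
    genome: Mapping[str, str],
    config: Optional[HairpinCallConfig] = None,
) -> List[HairpinCandidate]:
    """Call hairpin candidates for unannotated, genome-matched tags.

    For each tag hit the surrounding window (tag +/- ``flank`` nt, on the
    tag's strand) is folded; a candidate is emitted when the best stem-loop
    satisfies every threshold in ``config``.  The candidate count equals the
    tag's read count.  Deterministic and order-independent: output is sorted
    by (chrom, start, sequence) and named novel-mir-N in that order.
    """
    cfg = config or HairpinCallConfig()
    if isinstance(tags_with_hits, Mapping):
        items = list(tags_with_hits.values())
    else:
        items = list(tags_with_hits)

    found: Dict[Tuple[str, Locus], Tuple[str, str, float, int]] = {}
    for tag, hits in sorted(items, key=lambda th: th[0].sequence):
        if tag.count < cfg.min_count:
            continue
        for hit in hits:
            chrom_seq = genome[hit.chrom]
            ws = max(0, hit.start - 1 - cfg.flank)
            we = min(len(chrom_seq), hit.end + cfg.flank)
            window = chrom_seq[ws:we]
            if len(window) < cfg.min_precursor:
                continue
            if hit.strand == "+":
                wseq = window
                m0 = hit.start - 1 - ws
            else:
                wseq = revcomp(window)
                m0 = we - hit.end
            m1 = m0 + len(tag.sequence) - 1
            result = _evaluate_window(wseq, m0, m1, cfg)
            if result is None:
                continue
            oi, oj, arm, mfe = result
            if hit.strand == "+":
                locus = Locus(hit.chrom, ws + oi + 1, ws + oj + 1, "+")
            else:
                length = len(wseq)
                locus = Locus(hit.chrom, ws + length - oj, ws + length - oi, "-")
            key = (tag.sequence, locus)
            if key not in found:
                found[key] = (tag.sequence, arm, mfe, tag.count)

    ordered = sorted(found.items(), key=lambda kv: (kv[0][1], kv[0][0]))
    candidates = []
    for idx, ((seq, locus), (_, arm, mfe, count)) in enumerate(ordered, start=1):
        candidates.append(
            HairpinCandidate(
                name=f"novel-mir-{idx:02d}",
                sequence=seq,
                arm=arm,
                locus=locus,
                precursor_length=precursor_length(locus),
                mfe=round(mfe, 2),
                count=count,
            )
        )
    return candidates


def intersect_candidates(
    a: Sequence[HairpinCandidate], b: Sequence[HairpinCandidate]
) -> List[Tuple[HairpinCandidate, HairpinCandidate]]:
    """Candidates shared between two libraries: identical mature sequence and
    overlapping precursor loci."""
    shared = []
    for ca in a:
        for cb in b:
            if ca.sequence == cb.sequence and ca.locus.overlaps(cb.locus):
                shared.append((ca, cb))
                break
    return shared


TABLE_COLUMNS = [
    "Name",
    "Sequence",
    "Arm",
    "Length",
    "Location",
    "Precursor length (nt)",
    "MFE",
    "Count",
]


def candidates_table(candidates: Sequence[HairpinCandidate]) -> pd.DataFrame:
    """Candidates as a report table (one row per candidate)."""
    rows = [
        (
            c.name,
            c.sequence,
            "5′" if c.arm == "5p" else "3′",
            c.mature_length,
            str(c.locus),
            c.precursor_length,
            c.mfe,
            c.count,
        )
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
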