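"""Synthetic inputs with known ground truth for every pipeline stage.

This module fabricates the complete input bundle of a two-condition small-RNA
sequencing experiment: a toy genome, annotation intervals, known-miRNA mature
sequences, planted novel-miRNA hairpins, FASTQ read libraries for conditions
A and B, a transcriptome with planted target sites, and a gene->GO map with a
planted enriched term.  Every generator is deterministic for a fixed seed and
writes machine-readable truth tables so downstream stages can be tested
without external downloads.

What is emulated: two 18-30 nt small-RNA libraries sequenced as insert +
3' adapter, condition-dependent miRNA abundances (multinomial sampling with
probabilities proportional to expected RPM), uniform per-base sequencing
error, hairpin precursors whose star arm pairs the mature arm except at a few
designed bulges.  What is not: realistic quality-score models, PCR
duplicates, genome-scale repeat structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from ._seq import dna, revcomp
from .annotation import Interval
from .diffexpr import floor_zero
from .novel_discovery import Locus
from .target_prediction import perfect_complement

BASES = np.array(list("ACGT"))

# Illumina-style small-RNA adapters (any sequences work; these are realistic)
DEFAULT_ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


# --- genome -----------------------------------------------------------------


@dataclass
class ToyGenome:
    """Chromosome name -> uppercase DNA; planted features tracked for overlap checks."""

    chromosomes: Dict[str, str]
    features: List[Tuple[str, int, int, str]] = field(default_factory=list)
    # features: (chrom, start0, end0_exclusive, label)

    def __post_init__(self):
        for name, seq in self.chromosomes.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"chromosome {name} contains non-ACGT characters")

    def overlaps_feature(self, chrom: str, start0: int, end0: int) -> bool:
        return any(
            c == chrom and start0 < fe and fs < end0 for c, fs, fe, _ in self.features
        )

    def register(self, chrom: str, start0: int, end0: int, label: str) -> None:
        if self.overlaps_feature(chrom, start0, end0):
            raise ValueError(f"feature {label} overlaps an existing feature on {chrom}")
        if not (0 <= start0 < end0 <= len(self.chromosomes[chrom])):
            raise ValueError(f"feature {label} out of bounds on {chrom}")
        self.features.append((chrom, start0, end0, label))

    def gc_fraction(self) -> float:
        seq = "".join(self.chromosomes.values())
        return (seq.count("G") + seq.count("C")) / len(seq)


def generate_genome(n_chrom: int, length: int, seed: int) -> ToyGenome:
    """Uniform-random genome of ``n_chrom`` chromosomes, ``length`` bases each.

    A chromosome must be able to host a hairpin precursor, hence the
    200-base minimum.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if length < 200:
        raise ValueError("chromosome length must be >= 200 (cannot host a hairpin)")
    rng = np.random.default_rng(seed)
    chroms = {
        f"chr{i + 1}": "".join(rng.choice(BASES, size=length))
        for i in range(n_chrom)
    }
    genome = ToyGenome(chroms)
    assert 0.3 <= genome.gc_fraction() <= 0.7
    return genome


def _random_free_position(genome: ToyGenome, length: int, rng: np.random.Generator, max_tries: int = 200) -> Tuple[str, int]:
    names = sorted(genome.chromosomes)
    for _ in range(max_tries):
        chrom = names[int(rng.integers(len(names)))]
        limit = len(genome.chromosomes[chrom]) - length
        if limit <= 0:
            continue
        pos = int(rng.integers(limit))
        if not genome.overlaps_feature(chrom, pos, pos + length):
            return chrom, pos
    raise RuntimeError("could not place a feature without overlap")


def embed_sequence(genome: ToyGenome, sequence: str, chrom: str, position: int, label: str) -> Locus:
    """Overwrite genome bases with ``sequence`` at a 0-based position."""
    sequence = dna(sequence)
    genome.register(chrom, position, position + len(sequence), label)
    s = genome.chromosomes[chrom]
    genome.chromosomes[chrom] = s[:position] + sequence + s[position + len(sequence):]
    return Locus(chrom, position + 1, position + len(sequence), "+")


# --- hairpin planting -------------------------------------------------------

DEFAULT_LOOP = "AACAAC"  # non-self-pairing terminal loop


def build_precursor(
    mature: str,
    arm: str,
    precursor_length: int = 80,
    loop: str = DEFAULT_LOOP,
    n_bulges: int = 2,
    seed: int = 0,
) -> str:
    """Design a hairpin precursor hosting ``mature`` on the requested arm.

    The star arm is the reverse complement of the mature arm except at
    ``n_bulges`` designed mismatch positions (<= 3).  One mismatch is placed
    opposite the interior of the mature itself so the mature sequence occurs
    in the genome only once in its sense orientation; the rest fall opposite
    the random padding.
    """
    mature = dna(mature)
    if arm not in ("5p", "3p"):
        raise ValueError("arm must be '5p' or '3p'")
    if not 0 <= n_bulges <= 3:
        raise ValueError("n_bulges must be in 0..3")
    if not 60 <= precursor_length <= 100:
        raise ValueError("precursor length must be 60..100 nt")
    rng = np.random.default_rng(seed)
    stem = precursor_length - len(loop)
    arm_len = stem // 2
    loop = loop + ("A" * (stem - 2 * arm_len))  # absorb odd leftover
    pad_len = arm_len - len(mature)
    if pad_len < max(1, n_bulges - 1):
        raise ValueError("precursor too short for this mature (no room for padding)")
    pad = "".join(rng.choice(BASES, size=pad_len))

    if arm == "5p":
        mature_arm = mature + pad  # mature at precursor 5' end
    else:
        mature_arm = pad + mature  # mature at precursor 3' end
    star = list(revcomp(mature_arm))
    # star index j pairs mature_arm index arm_len-1-j
    if arm == "5p":
        pad_star = list(range(0, pad_len))
        mat_star = list(range(pad_len, arm_len))
    else:
        pad_star = list(range(len(mature), arm_len))
        mat_star = list(range(0, len(mature)))
    targets: List[int] = []
    if n_bulges >= 1 and len(mature) > 8:
        interior = mat_star[4:-4]  # keep mature ends cleanly paired
        targets.append(interior[int(rng.integers(len(interior)))])
    extra = [int(i) for i in rng.choice(pad_star, size=min(len(pad_star), max(0, n_bulges - len(targets))), replace=False)]
    targets.extend(extra)
    for j in targets:
        partner = mature_arm[arm_len - 1 - j]
        current = star[j]
        choices = [
            b
            for b in "ACGT"
            if b != current
            and (partner, b) not in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
        ]
        star[j] = choices[int(rng.integers(len(choices)))]
    star_arm = "".join(star)
    if arm == "5p":
        precursor = mature_arm + loop + star_arm
    else:
        precursor = star_arm + loop + mature_arm
    assert mature in precursor and len(precursor) == precursor_length
    return precursor


def plant_hairpin(
    genome: ToyGenome,
    mature: str,
    arm: str,
    position: int,
    chrom: Optional[str] = None,
    precursor_length: int = 80,
    n_bulges: int = 2,
    seed: int = 0,
    label: str = "hairpin",
) -> Locus:
    """Plant a hairpin precursor at a 0-based genomic position (in place).

    Returns the 1-based inclusive precursor locus.  Raises if the precursor
    does not fit or overlaps a previously planted feature.
    """
    chrom = chrom or sorted(genome.chromosomes)[0]
    precursor = build_precursor(mature, arm, precursor_length, n_bulges=n_bulges, seed=seed)
    if position + len(precursor) > len(genome.chromosomes[chrom]):
        raise ValueError("precursor does not fit at the requested position")
    return embed_sequence(genome, precursor, chrom, position, label)


# --- library simulation -----------------------------------------------------


@dataclass(frozen=True)
class SpikeIn:
    """One designed small RNA with condition-dependent expected abundance."""

    name: str
    sequence: str
    rpm_a: float
    rpm_b: float
    kind: str = "known_mirna"  # known_mirna | novel_mirna | fragment

    def __post_init__(self):
        if self.rpm_a < 0 or self.rpm_b < 0:
            raise ValueError("expected RPM must be >= 0")


@dataclass
class SpikeInDesign:
    """The experimental design: spike-ins plus planted hairpin loci."""

    spikeins: List[SpikeIn]
    hairpin_loci: Dict[str, Locus] = field(default_factory=dict)

    def __post_init__(self):
        names = [s.name for s in self.spikeins]
        if len(names) != len(set(names)):
            raise ValueError("spike-in names must be unique")

    def expected_rpm(self, condition: str) -> Dict[str, float]:
        idx = _condition_index(condition)
        return {s.name: (s.rpm_a, s.rpm_b)[idx] for s in self.spikeins}

    def true_de(self) -> Set[str]:
        """Names whose floored expected-RPM log2 ratio has magnitude >= 1."""
        out = set()
        for s in self.spikeins:
            a = float(floor_zero(s.rpm_a))
            b = float(floor_zero(s.rpm_b))
            if abs(np.log2(b / a)) >= 1.0:
                out.add(s.name)
        return out


@dataclass
class ReadSimConfig:
    total_reads: int = 100_000
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    read_length: int = 36
    error_rate: float = 0.001  # per base
    protected_prefix: int = 18  # spike-in bases never mutated (keeps counting exact)
    insert_len_range: Tuple[int, int] = (18, 30)
    contaminant_fraction: float = 0.0  # reads that are 5'-adapter ligation artifacts
    low_quality_fraction: float = 0.0  # reads emitted with junk quality strings
    seed: int = 0

    def __post_init__(self):
        if self.total_reads <= 0:
            raise ValueError("total_reads must be > 0")
        lo, hi = self.insert_len_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid insert length range")


def _condition_index(condition: str) -> int:
    try:
        return {"A": 0, "B": 1}[condition]
    except KeyError:
        raise ValueError("condition must be 'A' or 'B'") from None


def _mutate(seq: str, rng: np.random.Generator, error_rate: float, start: int = 0) -> str:
    if error_rate <= 0 or start >= len(seq):
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(seq) - start) < error_rate)[0]
    for off in hits:
        i = start + int(off)
        chars[i] = str(rng.choice(BASES[BASES != chars[i]]))
    return "".join(chars)


def simulate_library(
    genome: ToyGenome,
    design: SpikeInDesign,
    cfg: ReadSimConfig,
    condition: str,
) -> Tuple[List[Tuple[str, str, str]], pd.DataFrame]:
    """Simulate one library: (read id, sequence, quality) triples + truth table.

    Per-read composition is insert + 3' adapter, truncated to the read
    length, so adapter trimming downstream has real work to do.  Spike-in
    read counts are one multinomial draw with probabilities proportional to
    expected RPM; leftover probability mass becomes background fragments
    sampled uniformly from the genome.  Byte-identical for a fixed seed.
    """
    idx = _condition_index(condition)
    rng = np.random.default_rng([cfg.seed, idx])
    rpms = design.expected_rpm(condition)
    names = [s.name for s in design.spikeins]
    probs = np.array([rpms[n] for n in names]) / 1e6
    background_p = 1.0 - probs.sum()
    if background_p < -1e-9:
        raise ValueError("expected RPM values exceed one million reads per million")
    background_p = max(background_p, 0.0)
    counts = rng.multinomial(cfg.total_reads, np.append(probs, background_p) / (probs.sum() + background_p))

    n_background = int(counts[-1])
    n_contam = min(n_background, int(round(cfg.contaminant_fraction * cfg.total_reads)))
    n_lowq = min(n_background - n_contam, int(round(cfg.low_quality_fraction * cfg.total_reads)))
    n_background -= n_contam + n_lowq

    seq_by_name = {s.name: dna(s.sequence) for s in design.spikeins}
    reads: List[Tuple[str, str]] = []  # (sequence, quality)
    for name, count in zip(names, counts[:-1]):
        insert = seq_by_name[name]
        for _ in range(int(count)):
            mutated = _mutate(insert, rng, cfg.error_rate, start=cfg.protected_prefix)
            reads.append((_assemble(mutated, cfg), "high"))

    lo, hi = cfg.insert_len_range
    chrom_names = sorted(genome.chromosomes)
    def _background_insert() -> str:
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        seq = genome.chromosomes[chrom]
        length = int(rng.integers(lo, hi + 1))
        pos = int(rng.integers(len(seq) - length))
        frag = seq[pos : pos + length]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        return _mutate(frag, rng, cfg.error_rate)

    for _ in range(n_background):
        reads.append((_assemble(_background_insert(), cfg), "high"))
    for _ in range(n_contam):
        contam = (cfg.adapter5 + _background_insert())[: cfg.read_length]
        reads.append((contam, "high"))
    for _ in range(n_lowq):
        reads.append((_assemble(_background_insert(), cfg), "low"))

    order = rng.permutation(len(reads))
    out = []
    for rank, i in enumerate(order):
        seq, qual_kind = reads[int(i)]
        qual = ("I" if qual_kind == "high" else "#") * len(seq)
        out.append((f"{condition}_{rank:07d}", seq, qual))

    truth_rows = [
        {
            "name": name,
            "sequence": seq_by_name[name],
            "kind": next(s.kind for s in design.spikeins if s.name == name),
            "condition": condition,
            "count": int(count),
            "expected_rpm": rpms[name],
        }
        for name, count in zip(names, counts[:-1])
    ]
    for name, count in (
        ("background", n_background),
        ("contaminant", n_contam),
        ("low_quality", n_lowq),
    ):
        truth_rows.append(
            {"name": name, "sequence": "", "kind": name, "condition": condition,
             "count": int(count), "expected_rpm": float("nan")}
        )
    truth = pd.DataFrame(truth_rows)
    assert int(truth["count"].sum()) == cfg.total_reads
    return out, truth


def _assemble(insert: str, cfg: ReadSimConfig) -> str:
    read = insert + cfg.adapter3
    while len(read) < cfg.read_length:
        read += cfg.adapter3
    return read[: cfg.read_length]


def write_fastq(reads: Iterable[Tuple[str, str, str]], path) -> None:
    """Write (id, seq, qual) triples as Phred+33 FASTQ (byte-deterministic)."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# --- annotation intervals ---------------------------------------------------


def generate_annotation(
    genome: ToyGenome,
    categories: Sequence[str] = ("rRNA", "snoRNA", "snRNA", "piRNA", "tRNA", "repeat", "exon_intron"),
    interval_length: int = 90,
    seed: int = 0,
) -> List[Interval]:
    """Plant one annotation interval per category at random free loci."""
    rng = np.random.default_rng(seed)
    intervals = []
    for cat in categories:
        chrom, pos = _random_free_position(genome, interval_length, rng)
        genome.register(chrom, pos, pos + interval_length, f"annotation:{cat}")
        strand = "+" if rng.random() < 0.5 else "-"
        intervals.append(Interval(chrom, pos + 1, pos + interval_length, strand, cat))
    return intervals


def interval_fragment(genome: ToyGenome, interval: Interval, length: int = 22, offset: int = 5) -> str:
    """A small-RNA-sized fragment from inside an interval, on its strand."""
    seq = genome.chromosomes[interval.chrom][interval.start - 1 + offset : interval.start - 1 + offset + length]
    return revcomp(seq) if interval.strand == "-" else seq


def write_bed(intervals: Sequence[Interval], path) -> None:
    """Write intervals as 6-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.category}\t0\t{iv.strand}\n")


# --- transcriptome with planted target sites --------------------------------


def make_transcriptome(
    mirnas: Mapping[str, str],
    seed: int = 0,
    flank: int = 50,
    n_decoys: int = 4,
    decoy_length: int = 180,
) -> Tuple[Dict[str, str], Dict[str, str], Dict[str, int]]:
    """One transcript per miRNA carrying a perfect antisense site, plus decoys.

    Returns (transcripts, tx2gene, planted site 1-based offsets).
    """
    rng = np.random.default_rng(seed)
    transcripts: Dict[str, str] = {}
    tx2gene: Dict[str, str] = {}
    sites: Dict[str, int] = {}
    for name in sorted(mirnas):
        site = perfect_complement(mirnas[name])
        left = "".join(rng.choice(BASES, size=flank))
        right = "".join(rng.choice(BASES, size=flank))
        tx = f"tx_{name}"
        transcripts[tx] = left + site + right
        tx2gene[tx] = f"gene_{name}"
        sites[tx] = flank + 1
    for i in range(n_decoys):
        tx = f"tx_decoy{i + 1:02d}"
        transcripts[tx] = "".join(rng.choice(BASES, size=decoy_length))
        tx2gene[tx] = f"gene_decoy{i + 1:02d}"
    return transcripts, tx2gene, sites


# --- gene -> GO map ---------------------------------------------------------


def generate_go_map(
    n_genes: int,
    n_terms: int,
    enriched_term: str,
    target_genes: Iterable[str],
    seed: int = 0,
    base_rate: float = 0.05,
    elevated_rate: float = 0.9,
) -> pd.DataFrame:
    """Two-column gene/term table with one term enriched in the target genes.

    Target genes receive ``enriched_term`` at ``elevated_rate``; every other
    gene/term combination is annotated at ``base_rate``.  Gene ids are
    g0001..gN; extra target gene names are appended to the universe.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    targets = sorted(set(target_genes))
    genes.extend(g for g in targets if g not in genes)
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    if enriched_term not in terms:
        terms.append(enriched_term)
    target_set = set(targets)
    rows = []
    for gene in genes:
        for term in terms:
            if term == enriched_term and gene in target_set:
                rate = elevated_rate
            else:
                rate = base_rate
            if rng.random() < rate:
                rows.append((gene, term))
    return pd.DataFrame(rows, columns=["gene", "term"])


def write_go_map(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False)


# --- target-rule fixture ----------------------------------------------------

# Designed miRNAs for the rule fixture: one GC-rich (strong stacks survive a
# few mismatches) and one U-rich (many wobble-capable positions).
FIXTURE_MIRNA_GC = "GCGGCGCCGCGGCCGCGGCCGG"
FIXTURE_MIRNA_AU = "TGTTGATTGTTCATTGTTAGTT"


def modified_site(mirna: str, gu: Sequence[int] = (), mm: Sequence[int] = ()) -> str:
    """Perfect-complement site with wobbles/mismatches at 1-based miRNA positions.

    A wobble position requires the miRNA base to be G or T there; the site
    base becomes its wobble partner.  A mismatch sets the site base equal to
    the miRNA base (never pairs).
    """
    mirna = dna(mirna)
    L = len(mirna)
    site = list(perfect_complement(mirna))
    for pos in gu:
        base = mirna[pos - 1]
        if base == "T":
            site[L - pos] = "G"
        elif base == "G":
            site[L - pos] = "T"
        else:
            raise ValueError(f"position {pos}: base {base} cannot form a G:U wobble")
    for pos in mm:
        site[L - pos] = mirna[pos - 1]
    return "".join(site)


@dataclass
class TargetFixture:
    mirnas: Dict[str, str]
    transcripts: Dict[str, str]
    tx2gene: Dict[str, str]
    expected: Set[Tuple[str, str, int]]  # (mirna, transcript, 1-based offset)
    violated_rule: Dict[str, str]  # transcript -> the single rule its site breaks


def build_target_fixture(seed: int = 11, flank: int = 40) -> TargetFixture:
    """Ten compliant planted sites and ten sites each violating a single rule.

    Site designs (miRNA positions, 1-based from the 5' end):

    * rule i:  nine G:U wobbles (score 4.5 > 4) while positions 1-12 carry
      exactly 2.5, so rule v still passes and no mismatch exists at all;
    * rule ii: a run of three mismatches outside positions 2-12;
    * rule iii: two adjacent mismatches inside positions 2-12 (not 10-11);
    * rule iv: a lone mismatch at position 10 or 11;
    * rule v:  six wobbles inside positions 1-12 (3.0 > 2.5, total <= 4);
    * rule vi: four isolated mismatches in the weak-stack 3' half of the
      U-rich miRNA, wrecking the energy ratio while every count rule passes.
    """
    gc, au = FIXTURE_MIRNA_GC, FIXTURE_MIRNA_AU
    mirnas = {"mir-gc": gc, "mir-au": au}
    compliant = {
        "c01": (gc, perfect_complement(gc)),
        "c02": (gc, perfect_complement(gc)),
        "c03": (au, perfect_complement(au)),
        "c04": (au, perfect_complement(au)),
        "c05": (gc, modified_site(gc, gu=[18])),
        "c06": (gc, modified_site(gc, mm=[21])),
        "c07": (au, modified_site(au, gu=[2, 16])),
        "c08": (au, modified_site(au, mm=[20])),
        "c09": (gc, modified_site(gc, mm=[5])),
        "c10": (au, modified_site(au, gu=[1], mm=[14])),
    }
    violators = {
        "v01": (au, modified_site(au, gu=[1, 3, 4, 7, 8, 14, 15, 17, 18]), "i"),
        "v02": (gc, modified_site(gc, mm=[17, 18, 19]), "ii"),
        "v03": (gc, modified_site(gc, mm=[5, 6]), "iii"),
        "v04": (gc, modified_site(gc, mm=[10]), "iv"),
        "v05": (au, modified_site(au, gu=[1, 3, 4, 7, 8, 10]), "v"),
        "v06": (au, modified_site(au, mm=[13, 15, 17, 19]), "vi"),
        "v07": (gc, modified_site(gc, mm=[14, 15, 16]), "ii"),
        "v08": (gc, modified_site(gc, mm=[7, 8]), "iii"),
        "v09": (gc, modified_site(gc, mm=[11]), "iv"),
        "v10": (au, modified_site(au, mm=[13, 15, 18, 20]), "vi"),
    }
    rng = np.random.default_rng(seed)
    transcripts: Dict[str, str] = {}
    tx2gene: Dict[str, str] = {}
    expected: Set[Tuple[str, str, int]] = set()
    violated: Dict[str, str] = {}
    mirna_name = {gc: "mir-gc", au: "mir-au"}
    for tx, (mirna, site) in sorted(compliant.items()):
        left = "".join(rng.choice(BASES, size=flank))
        right = "".join(rng.choice(BASES, size=flank))
        transcripts[tx] = left + site + right
        tx2gene[tx] = f"gene_{tx}"
        expected.add((mirna_name[mirna], tx, flank + 1))
    for tx, (mirna, site, rule) in sorted(violators.items()):
        left = "".join(rng.choice(BASES, size=flank))
        right = "".join(rng.choice(BASES, size=flank))
        transcripts[tx] = left + site + right
        tx2gene[tx] = f"gene_{tx}"
        violated[tx] = rule
    return TargetFixture(mirnas, transcripts, tx2gene, expected, violated)
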