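"""Exact mapping, the category cascade, and the annotation summary."""

import random

import pytest

from smallrna import annotation as ann
from smallrna._seq import revcomp
from smallrna.preprocess import Tag


def naive_scan(tags, chromosomes):
    """O(n*m) oracle: compare every offset on both strands by slicing."""
    hits = {t.sequence: set() for t in tags}
    for tag in tags:
        for strand, query in (("+", tag.sequence), ("-", revcomp(tag.sequence))):
            L = len(query)
            for chrom, seq in chromosomes.items():
                for off in range(len(seq) - L + 1):
                    if seq[off : off + L] == query:
                        hits[tag.sequence].add(ann.GenomeHit(chrom, off + 1, off + L, strand))
    return {k: sorted(v) for k, v in hits.items()}


class TestMapExact:
    def test_plus_strand_coordinates(self, toy_genome):
        seq = toy_genome.chromosomes["chr1"][100:122]
        hits = ann.map_exact([Tag(seq, 1)], toy_genome.chromosomes)[seq]
        assert ann.GenomeHit("chr1", 101, 122, "+") in hits

    def test_minus_strand_reported_in_plus_coordinates(self, toy_genome):
        seq = revcomp(toy_genome.chromosomes["chr1"][100:122])
        hits = ann.map_exact([Tag(seq, 1)], toy_genome.chromosomes)[seq]
        assert ann.GenomeHit("chr1", 101, 122, "-") in hits

    def test_non_acgt_tag_gets_no_hits(self, toy_genome):
        assert ann.map_exact([Tag("ACGTNACGTNACGTNACGTN", 1)], toy_genome.chromosomes) == {
            "ACGTNACGTNACGTNACGTN": []
        }

    def test_agrees_with_naive_scan(self, toy_genome):
        rng = random.Random(5)
        genome = toy_genome.chromosomes
        tags = []
        for _ in range(250):
            if rng.random() < 0.5:  # half sampled from the genome (guaranteed hits)
                off = rng.randrange(len(genome["chr1"]) - 22)
                seq = genome["chr1"][off : off + 22]
                if rng.random() < 0.5:
                    seq = revcomp(seq)
            else:
                seq = "".join(rng.choice("ACGT") for _ in range(22))
            tags.append(Tag(seq, 1))
        assert ann.map_exact(tags, genome) == naive_scan(tags, genome)


class TestGenomeMatchPercentage:
    def test_published_library_percentages(self):
        assert ann.genome_match_percentage(8014466, 9772392) == 82.01
        assert ann.genome_match_percentage(8104423, 9717633) == 83.40

    def test_zero_matched(self):
        assert ann.genome_match_percentage(0, 10) == 0.00

    def test_half_up_rounding(self):
        assert ann.genome_match_percentage(125, 1000) == 12.50
        assert ann.genome_match_percentage(1005, 100000) == 1.01

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ann.genome_match_percentage(5, 0)
        with pytest.raises(ValueError):
            ann.genome_match_percentage(11, 10)


def bed_line(chrom, start0, end0, cat, strand):
    return f"{chrom}\t{start0}\t{end0}\t{cat}\t0\t{strand}"


class TestReadBed:
    def test_round_trip_coordinates(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text(bed_line("chr1", 10, 20, "tRNA", "+") + "\n")
        (iv,) = ann.read_bed(p)
        assert (iv.start, iv.end, iv.category, iv.strand) == (11, 20, "tRNA", "+")

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "b.bed"
        p.write_text(bed_line("chr1", 10, 20, "tRNA", "+") + "\nchr1\tx\ty\ttRNA\t0\t+\n")
        with pytest.raises(ValueError, match=":2:"):
            ann.read_bed(p)

    def test_unknown_category_rejected(self, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text(bed_line("chr1", 10, 20, "lncRNA", "+") + "\n")
        with pytest.raises(ValueError, match="lncRNA"):
            ann.read_bed(p)


class TestAssignCategory:
    HIT = ann.GenomeHit("chr1", 101, 122, "+")

    def test_priority_order_trna_beats_exon(self):
        ivs = [
            ann.Interval("chr1", 90, 130, "+", "exon_intron"),
            ann.Interval("chr1", 110, 140, "+", "tRNA"),
        ]
        a = ann.assign_category(Tag("A" * 22, 1), [self.HIT], ivs, {})
        assert a.category == "tRNA"

    def test_strand_aware_overlap(self):
        ivs = [ann.Interval("chr1", 90, 130, "-", "tRNA")]
        a = ann.assign_category(Tag("A" * 22, 1), [self.HIT], ivs, {})
        assert a.category == ann.UNANNOTATED

    def test_known_mirna_by_exact_sequence(self):
        seq = "ACGTACGTAGCTAGCTAGGATC"
        a = ann.assign_category(Tag(seq, 1), [self.HIT], [], {seq: "mir-x"})
        assert a.category == ann.KNOWN_MIRNA

    def test_unmatched_tag_has_no_category(self):
        a = ann.assign_category(Tag("A" * 22, 1), [], [], {})
        assert a.category is None

    def test_single_base_overlap_suffices(self):
        ivs = [ann.Interval("chr1", 122, 140, "+", "rRNA")]
        a = ann.assign_category(Tag("A" * 22, 1), [self.HIT], ivs, {})
        assert a.category == "rRNA"

    def test_matches_brute_force_rederivation(self, toy_genome):
        rng = random.Random(9)
        genome = toy_genome.chromosomes
        ivs = []
        for cat in ann.CATEGORY_PRIORITY:
            for _ in range(3):
                s = rng.randrange(1, 9_800)
                ivs.append(ann.Interval("chr1", s, s + rng.randrange(30, 200), rng.choice("+-"), cat))
        tags = []
        for _ in range(120):
            off = rng.randrange(len(genome["chr1"]) - 22)
            seq = genome["chr1"][off : off + 22]
            tags.append(Tag(seq if rng.random() < 0.5 else revcomp(seq), 1))
        index = ann.GenomeIndex(genome)
        for tag in tags:
            hits = index.find(tag.sequence)
            got = ann.assign_category(tag, hits, ivs, {}).category
            # brute force: collect every overlapping category, take priority min
            cats = {
                iv.category
                for iv in ivs
                for h in hits
                if h.chrom == iv.chrom and h.strand == iv.strand
                and max(h.start, iv.start) <= min(h.end, iv.end)
            }
            expected = None
            if hits:
                expected = next((c for c in ann.CATEGORY_PRIORITY if c in cats), ann.UNANNOTATED)
            assert got == expected


class TestSummarize:
    def test_counts_and_conservation(self):
        hit = ann.GenomeHit("chr1", 1, 22, "+")
        asn = [
            ann.CategoryAssignment(Tag("A" * 22, 3), [hit], "tRNA"),
            ann.CategoryAssignment(Tag("C" * 22, 5), [hit], "tRNA"),
            ann.CategoryAssignment(Tag("G" * 22, 2), [], None),
        ]
        df = ann.summarize(asn)
        row = df[df["category"] == "tRNA"].iloc[0]
        assert (row["unique_tags"], row["total_reads"]) == (2, 8)
        assert int(df["total_reads"].sum()) == 10

    def test_empty_input(self):
        assert ann.summarize([]).empty
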