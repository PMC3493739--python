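"""Generators: determinism, conservation, and planted ground truth."""

import numpy as np
import pytest

from smallrna import novel_discovery as nd
from smallrna import synthetic_data as sim
from smallrna._seq import revcomp


class TestGenerateGenome:
    def test_deterministic_for_fixed_seed(self):
        a = sim.generate_genome(1, 10_000, seed=7)
        b = sim.generate_genome(1, 10_000, seed=7)
        assert a.chromosomes == b.chromosomes

    def test_shape(self):
        g = sim.generate_genome(2, 500, seed=1)
        assert sorted(g.chromosomes) == ["chr1", "chr2"]
        assert all(len(s) == 500 for s in g.chromosomes.values())

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sim.generate_genome(1, 100, seed=7)

    def test_gc_fraction_reasonable(self):
        assert 0.3 <= sim.generate_genome(1, 5000, seed=3).gc_fraction() <= 0.7


MATURE = "ACGTACGTAGCTAGCTAGGATC"


class TestPlantHairpin:
    def test_locus_length_bookkeeping(self):
        g = sim.generate_genome(1, 2000, seed=1)
        locus = sim.plant_hairpin(g, MATURE, "5p", position=500, precursor_length=80)
        assert locus.end - locus.start + 1 == 80

    def test_precursor_contains_mature_exactly(self):
        for arm in ("5p", "3p"):
            g = sim.generate_genome(1, 2000, seed=1)
            locus = sim.plant_hairpin(g, MATURE, arm, position=500)
            prec = g.chromosomes["chr1"][locus.start - 1 : locus.end]
            assert MATURE in prec
            if arm == "5p":
                assert prec.startswith(MATURE)
            else:
                assert prec.endswith(MATURE)

    def test_planted_precursor_folds_into_hairpin(self):
        g = sim.generate_genome(1, 2000, seed=1)
        locus = sim.plant_hairpin(g, MATURE, "5p", position=500)
        prec = g.chromosomes["chr1"][locus.start - 1 : locus.end]
        structure, mfe = nd.fold_hairpin(prec)
        assert mfe < 0
        assert "(" in structure

    def test_overlap_with_existing_feature_rejected(self):
        g = sim.generate_genome(1, 2000, seed=1)
        sim.plant_hairpin(g, MATURE, "5p", position=500)
        with pytest.raises(ValueError, match="overlap"):
            sim.plant_hairpin(g, MATURE, "5p", position=530)

    def test_out_of_bounds_rejected(self):
        g = sim.generate_genome(1, 300, seed=1)
        with pytest.raises(ValueError):
            sim.plant_hairpin(g, MATURE, "5p", position=290)

    def test_star_arm_mismatches_bounded(self):
        prec = sim.build_precursor(MATURE, "5p", 80, n_bulges=3, seed=2)
        stem = (80 - 6) // 2
        arm5, arm3 = prec[:stem], prec[stem + 6 :]
        pairs = sum(
            (a, b) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
            for a, b in zip(arm5, reversed(arm3))
        )
        assert stem - pairs <= 3


def _degenerate_design():
    return sim.SpikeInDesign(
        [sim.SpikeIn("only", MATURE, 1_000_000.0, 1_000_000.0, "known_mirna")]
    )


class TestSimulateLibrary:
    def test_degenerate_multinomial_all_reads_one_mirna(self, toy_genome):
        cfg = sim.ReadSimConfig(total_reads=1000, error_rate=0.0, seed=1)
        reads, truth = sim.simulate_library(toy_genome, _degenerate_design(), cfg, "A")
        assert len(reads) == 1000
        assert all(seq.startswith(MATURE) for _, seq, _ in reads)
        assert truth.loc[truth["name"] == "only", "count"].item() == 1000

    def test_fixed_seed_byte_identical_fastq(self, toy_genome, tmp_path):
        design = _degenerate_design()
        cfg = sim.ReadSimConfig(total_reads=200, seed=5)
        out = []
        for name in ("a.fq", "b.fq"):
            reads, _ = sim.simulate_library(toy_genome, design, cfg, "A")
            path = tmp_path / name
            sim.write_fastq(reads, path)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_conditions_differ_but_truth_conserves_totals(self, toy_genome):
        design = sim.SpikeInDesign(
            [sim.SpikeIn("m1", MATURE, 5_000.0, 20_000.0, "known_mirna")]
        )
        cfg = sim.ReadSimConfig(total_reads=5000, seed=5)
        for cond in ("A", "B"):
            _, truth = sim.simulate_library(toy_genome, design, cfg, cond)
            assert int(truth["count"].sum()) == 5000

    def test_realized_counts_track_expected_rpm(self, toy_genome):
        # multinomial sampling: mean absolute relative deviation across
        # spike-ins at RPM >= 1000, averaged over seeds, stays under 5%
        rpms = [1000.0, 3000.0, 10_000.0, 30_000.0, 100_000.0]
        design = sim.SpikeInDesign(
            [sim.SpikeIn(f"m{i}", MATURE[:18] + "ACGT"[i % 4] * 4, r, r, "known_mirna")
             for i, r in enumerate(rpms)]
        )
        devs = []
        for seed in range(20):
            cfg = sim.ReadSimConfig(total_reads=100_000, error_rate=0.0, seed=seed)
            _, truth = sim.simulate_library(toy_genome, design, cfg, "A")
            for name, rpm in zip([f"m{i}" for i in range(5)], rpms):
                realized = truth.loc[truth["name"] == name, "count"].item()
                expected = rpm / 1e6 * 100_000
                devs.append(abs(realized - expected) / expected)
        assert np.mean(devs) < 0.05

    def test_contaminant_and_low_quality_reads_emitted(self, toy_genome):
        cfg = sim.ReadSimConfig(
            total_reads=1000, seed=2, contaminant_fraction=0.05, low_quality_fraction=0.05
        )
        design = sim.SpikeInDesign([sim.SpikeIn("m", MATURE, 100_000.0, 100_000.0)])
        reads, truth = sim.simulate_library(toy_genome, design, cfg, "A")
        t = dict(zip(truth["name"], truth["count"]))
        assert t["contaminant"] == 50 and t["low_quality"] == 50
        assert sum(1 for _, seq, _ in reads if seq.startswith(cfg.adapter5[:12])) >= 50
        assert sum(1 for _, _, q in reads if set(q) == {"#"}) == 50


class TestGenerateGoMap:
    def test_deterministic(self):
        a = sim.generate_go_map(20, 4, "GO:0000001", ["g0001"], seed=9)
        b = sim.generate_go_map(20, 4, "GO:0000001", ["g0001"], seed=9)
        assert a.equals(b)

    def test_single_term_saturated_gives_p_one(self):
        from smallrna import enrichment as enr

        gmap = sim.generate_go_map(10, 1, "GO:0000001", ["g0001", "g0002"],
                                   seed=1, base_rate=1.0, elevated_rate=1.0)
        gene2go = {g: set(t["term"]) for g, t in gmap.groupby("gene")}
        df = enr.enrich(["g0001", "g0002"], gene2go)
        assert (df["pvalue"] == 1.0).all()


class TestTranscriptome:
    def test_planted_sites_are_antisense(self):
        mirnas = {"m1": MATURE}
        tx, tx2gene, sites = sim.make_transcriptome(mirnas, seed=3)
        offset = sites["tx_m1"]
        window = tx["tx_m1"][offset - 1 : offset - 1 + len(MATURE)]
        assert window == revcomp(MATURE)
        assert tx2gene["tx_m1"] == "gene_m1"
        assert sum(1 for t in tx if t.startswith("tx_decoy")) == 4
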