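"""Duplex alignment, the six target rules, and transcript scanning."""

import itertools
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from smallrna import target_prediction as tp
from smallrna._seq import revcomp

from _oracles import oracle_report
from smallrna.synthetic_data import FIXTURE_MIRNA_AU, FIXTURE_MIRNA_GC, modified_site

mirna_strategy = st.text(alphabet="ACGT", min_size=18, max_size=24)


class TestAlignAndScore:
    def test_perfect_complement_all_wc(self):
        m = FIXTURE_MIRNA_GC
        d = tp.align(m, tp.perfect_complement(m))
        assert set(d.states) == {tp.WC}
        assert tp.score_mismatches(d) == 0.0

    def test_single_wobble_scores_half(self):
        d = tp.align(FIXTURE_MIRNA_AU, modified_site(FIXTURE_MIRNA_AU, gu=[3]))
        assert tp.score_mismatches(d) == 0.5
        assert d.states[2] == tp.GU

    def test_three_mismatches_two_wobbles(self):
        site = modified_site(FIXTURE_MIRNA_AU, gu=[1, 3], mm=[14, 16, 20])
        d = tp.align(FIXTURE_MIRNA_AU, site)
        assert tp.score_mismatches(d) == 4.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tp.align("ACGT" * 5, "ACGT" * 6)

    def test_position_indexing_from_mirna_5prime(self):
        # a mismatch injected at miRNA position 10 lands at states[9]
        d = tp.align(FIXTURE_MIRNA_GC, modified_site(FIXTURE_MIRNA_GC, mm=[10]))
        assert d.states[9] == tp.MM
        assert all(s == tp.WC for i, s in enumerate(d.states) if i != 9)


class TestRules:
    def test_perfect_complement_passes_everything(self):
        rep = tp.check_rules(FIXTURE_MIRNA_GC, tp.perfect_complement(FIXTURE_MIRNA_GC))
        assert rep.passed
        assert rep.mfe_ratio == 1.0

    def test_mismatches_at_10_and_11_fail_rule_iv(self):
        rep = tp.check_rules(FIXTURE_MIRNA_GC, modified_site(FIXTURE_MIRNA_GC, mm=[10, 11]))
        assert not rep.rules["iv"]

    def test_five_isolated_mismatches_fail_rules_i_and_v(self):
        site = modified_site(FIXTURE_MIRNA_GC, mm=[1, 3, 5, 7, 9])
        rep = tp.check_rules(FIXTURE_MIRNA_GC, site)
        assert rep.mismatch_score == 5.0
        assert not rep.rules["i"]
        assert not rep.rules["v"]

    def test_wobble_not_an_adjacency_mismatch_by_default(self):
        site = modified_site(FIXTURE_MIRNA_AU, gu=[3, 4])
        rep = tp.check_rules(FIXTURE_MIRNA_AU, site)
        assert rep.rules["ii"] and rep.rules["iii"]
        strict = tp.check_rules(FIXTURE_MIRNA_AU, site, gu_as_mismatch=True)
        assert not strict.rules["iii"]

    def test_single_rule_violators(self, target_fixture):
        fx = target_fixture
        name_of = {v: k for k, v in fx.mirnas.items()}
        for tx, rule in sorted(fx.violated_rule.items()):
            site = fx.transcripts[tx][40 : 40 + 22]
            mirna = fx.mirnas["mir-au"] if tx in ("v01", "v05", "v06", "v10") else fx.mirnas["mir-gc"]
            rep = tp.check_rules(mirna, site)
            failed = [k for k, v in rep.rules.items() if not v]
            assert failed == [rule], f"{tx}: expected only rule {rule} to fail, got {failed}"

    def test_mismatch_monotonicity(self):
        # adding one more mismatch never rescues a failing count/position rule
        rng = random.Random(2)
        m = FIXTURE_MIRNA_GC
        for _ in range(100):
            positions = rng.sample(range(1, 23), rng.randint(0, 5))
            base = tp.check_rules(m, modified_site(m, mm=positions))
            extra = rng.choice([p for p in range(1, 23) if p not in positions])
            more = tp.check_rules(m, modified_site(m, mm=positions + [extra]))
            for rule in ("i", "ii", "iii", "iv", "v"):
                if not base.rules[rule]:
                    assert not more.rules[rule]


class TestDuplexMfe:
    def test_zero_pair_duplex_is_zero(self):
        assert tp.duplex_mfe("AAAAAAAAAAAAAAAAAAAAA", "AAAAAAAAAAAAAAAAAAAAA") == 0.0

    def test_central_mismatches_destabilize(self):
        m = FIXTURE_MIRNA_GC
        perfect = tp.duplex_mfe(m, tp.perfect_complement(m))
        damaged = tp.duplex_mfe(m, modified_site(m, mm=[10, 11]))
        assert perfect < damaged <= 0.0

    def test_energy_is_a_stack_sum(self):
        # two adjacent GC pairs -> one GC/GC stack
        assert tp.duplex_mfe("GG", "CC") == pytest.approx(-3.3)
        assert tp.duplex_mfe("GGG", "CCC") == pytest.approx(-6.6)

    def test_orientation_bookkeeping(self):
        # reversing both strands preserves the stack multiset, hence the energy
        m = FIXTURE_MIRNA_AU
        site = modified_site(m, mm=[5], gu=[8])
        assert tp.duplex_mfe(m, site) == pytest.approx(tp.duplex_mfe(m[::-1], site[::-1]))


class TestMfeRatio:
    @given(mirna_strategy)
    def test_perfect_complement_ratio_is_one(self, mirna):
        assert tp.mfe_ratio(mirna, tp.perfect_complement(mirna)) == pytest.approx(1.0)

    def test_random_sites_fail_the_ratio(self):
        rng = random.Random(7)
        m = FIXTURE_MIRNA_AU
        failures = 0
        for _ in range(100):
            site = "".join(rng.choice("ACGT") for _ in range(len(m)))
            if tp.mfe_ratio(m, site) < 0.75:
                failures += 1
        assert failures >= 99

    def test_exact_threshold_inclusive(self):
        rep = tp.check_rules("GG", "CC")
        assert rep.mfe_ratio == 1.0 and rep.rules["vi"]


class TestPredictTargets:
    def test_planted_antisense_site_found_at_offset(self, target_fixture):
        fx = target_fixture
        hits = tp.predict_targets(fx.mirnas, fx.transcripts, fx.tx2gene)
        got = {(r.mirna, r.transcript, r.offset) for r in hits.itertuples()}
        assert got == fx.expected
        assert set(hits["gene"]) == {f"gene_{tx}" for _, tx, _ in fx.expected}

    def test_sense_embedding_is_not_a_site(self):
        m = FIXTURE_MIRNA_GC
        hits = tp.predict_targets({"m": m}, {"tx": "ACGTACGT" + m + "ACGTACGT"})
        assert len(hits) == 0

    def test_antisense_embedding_is_a_site(self):
        m = FIXTURE_MIRNA_GC
        hits = tp.predict_targets({"m": m}, {"tx": "ACGTACGT" + revcomp(m) + "ACGTACGT"})
        assert list(hits["offset"]) == [9]

    def test_empty_transcriptome_rejected(self):
        with pytest.raises(ValueError):
            tp.predict_targets({"m": FIXTURE_MIRNA_GC}, {})




def test_rule_checker_agrees_with_oracle_on_small_duplexes():
    """Exhaustive per-position states over short duplexes; the full sweep to
    length 12 runs in the acceptance suite."""
    realize = {"WC": ("G", "C"), "GU": ("G", "T"), "MM": ("C", "C")}
    for L in range(2, 8):
        for states in itertools.product(("WC", "GU", "MM"), repeat=L):
            mirna = "".join(realize[s][0] for s in states)
            site = "".join(realize[s][1] for s in reversed(states))
            rep = tp.check_rules(mirna, site)
            rules, score, ratio = oracle_report(mirna, site)
            assert rep.rules == rules, (mirna, site)
            assert rep.mismatch_score == score
            assert rep.mfe_ratio == pytest.approx(ratio, abs=1e-9)
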