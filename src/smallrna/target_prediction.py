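"""Rule-based miRNA target prediction with a duplex-MFE criterion.

A candidate site is an ungapped, antiparallel duplex between the miRNA
(positions 1..L counted from its 5' end) and a same-length transcript window.
Each miRNA position pairs the site position L+1-i; per position the state is
a Watson-Crick pair, a G:U wobble, or a mismatch.  Six rules decide a hit:

  i)   mismatch score <= 4, where a G:U wobble counts 0.5;
  ii)  no run of more than two adjacent mismatches anywhere;
  iii) no two adjacent mismatches within positions 2-12;
  iv)  no mismatch at positions 10-11;
  v)   mismatch score over positions 1-12 <= 2.5;
  vi)  duplex MFE >= 75% of the MFE of the miRNA bound to its perfect
       complement (ratio of two negative numbers, pass at >= 0.75 inclusive).

By default a G:U wobble contributes to the numeric caps (i, v) but is a pair,
not a mismatch, for the adjacency rules (ii-iv); set ``gu_as_mismatch`` to
treat wobbles as mismatches there too.

Duplex energies reuse the pair-strength stack model of ``novel_discovery``
(GC 3.3, AU 0.9, GU 1.0; stack = mean of the two pair strengths); each
interior mismatch run destabilizes by +0.5.  Rule vi uses only the *ratio*
of two energies under the same model, so the absolute scale drops out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from ._seq import dna, revcomp
from .novel_discovery import PAIR_STRENGTH

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "T"), ("T", "G")}

WC, GU, MM = "WC", "GU", "MM"


@dataclass(frozen=True)
class DuplexAlignment:
    """Ungapped duplex; ``states[i-1]`` is the state at miRNA position i."""

    mirna: str
    site: str
    states: Tuple[str, ...]

    def __len__(self) -> int:
        return len(self.mirna)

    def partner(self, position: int) -> str:
        """Site base paired with miRNA position (1-based)."""
        return self.site[len(self) - position]


def align(mirna: str, site: str) -> DuplexAlignment:
    """Build the duplex of a miRNA against a same-length target site (both 5'->3')."""
    mirna = dna(mirna)
    site = dna(site)
    if len(mirna) != len(site):
        raise ValueError("site must have the same length as the miRNA (ungapped duplex)")
    if not mirna:
        raise ValueError("empty duplex")
    states = []
    L = len(mirna)
    for i in range(L):
        pair = (mirna[i], site[L - 1 - i])
        if pair in WC_PAIRS:
            states.append(WC)
        elif pair in GU_PAIRS:
            states.append(GU)
        else:
            states.append(MM)
    return DuplexAlignment(mirna, site, tuple(states))


def score_mismatches(duplex: DuplexAlignment) -> float:
    """Mismatch score: 1 per mismatch + 0.5 per G:U wobble."""
    return sum(1.0 for s in duplex.states if s == MM) + 0.5 * sum(
        1 for s in duplex.states if s == GU
    )


def perfect_complement(mirna: str) -> str:
    """The site sequence whose duplex with ``mirna`` is all Watson-Crick."""
    return revcomp(dna(mirna))


def _mismatch_runs(states: Sequence[str], mismatch_states: frozenset) -> List[Tuple[int, int]]:
    """Maximal runs of mismatch positions as (start, end) 1-based inclusive."""
    runs = []
    start = None
    for idx, s in enumerate(states, start=1):
        if s in mismatch_states:
            if start is None:
                start = idx
        elif start is not None:
            runs.append((start, idx - 1))
            start = None
    if start is not None:
        runs.append((start, len(states)))
    return runs


def duplex_mfe(mirna: str, site: str) -> float:
    """Stack-sum energy of the ungapped duplex, kcal/mol (<= 0).

    Adjacent paired positions contribute one stack; interior mismatch runs
    (flanked by pairs on both sides) destabilize by +0.5 each.  A duplex
    whose penalties outweigh its stacks carries no stable structure and is
    reported as 0.
    """
    d = align(mirna, site)
    L = len(d)
    energy = 0.0
    for i in range(L - 1):
        if d.states[i] != MM and d.states[i + 1] != MM:
            p1 = (d.mirna[i], d.site[L - 1 - i])
            p2 = (d.mirna[i + 1], d.site[L - 2 - i])
            energy -= (PAIR_STRENGTH[p1] + PAIR_STRENGTH[p2]) / 2.0
    for start, end in _mismatch_runs(d.states, frozenset({MM})):
        if start > 1 and end < L:  # interior run
            energy += 0.5
    return min(energy, 0.0)


def mfe_ratio(mirna: str, site: str) -> float:
    """MFE(duplex) / MFE(miRNA vs its perfect complement); pass at >= 0.75."""
    perfect = duplex_mfe(mirna, perfect_complement(mirna))
    if perfect >= 0:
        raise ValueError("miRNA has no stable perfect duplex under the energy model")
    return duplex_mfe(mirna, site) / perfect


@dataclass(frozen=True)
class TargetRuleReport:
    """Per-rule outcome for one miRNA:site duplex."""

    mismatch_score: float
    rules: Dict[str, bool]  # keys i..vi
    mfe: float
    perfect_mfe: float
    mfe_ratio: float

    @property
    def passed(self) -> bool:
        return all(self.rules.values())


SEED_REGION = (2, 12)  # rule iii window
CENTRAL = (10, 11)  # rule iv positions
CAP_REGION = (1, 12)  # rule v window


def check_rules(
    mirna: str,
    site: str,
    gu_as_mismatch: bool = False,
    ratio_cut: float = 0.75,
) -> TargetRuleReport:
    """Evaluate all six target rules independently on one duplex."""
    d = align(mirna, site)
    L = len(d)
    score = score_mismatches(d)
    adjacency_mm = frozenset({MM, GU}) if gu_as_mismatch else frozenset({MM})
    runs = _mismatch_runs(d.states, adjacency_mm)

    rule_i = score <= 4.0
    rule_ii = all(end - start + 1 <= 2 for start, end in runs)
    lo, hi = SEED_REGION
    rule_iii = not any(
        d.states[i - 1] in adjacency_mm and d.states[i] in adjacency_mm
        for i in range(lo, min(hi, L))  # adjacent positions (i, i+1) both in window
    )
    rule_iv = all(
        d.states[p - 1] not in adjacency_mm for p in CENTRAL if p <= L
    )
    cap_lo, cap_hi = CAP_REGION
    cap_score = sum(
        1.0 if d.states[p - 1] == MM else 0.5 if d.states[p - 1] == GU else 0.0
        for p in range(cap_lo, min(cap_hi, L) + 1)
    )
    rule_v = cap_score <= 2.5
    mfe = duplex_mfe(mirna, site)
    perfect = duplex_mfe(mirna, perfect_complement(mirna))
    ratio = mfe / perfect if perfect < 0 else 0.0
    rule_vi = ratio >= ratio_cut
    return TargetRuleReport(
        mismatch_score=score,
        rules={"i": rule_i, "ii": rule_ii, "iii": rule_iii, "iv": rule_iv, "v": rule_v, "vi": rule_vi},
        mfe=mfe,
        perfect_mfe=perfect,
        mfe_ratio=ratio,
    )


def predict_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    tx2gene: Optional[Mapping[str, str]] = None,
    gu_as_mismatch: bool = False,
    ratio_cut: float = 0.75,
) -> pd.DataFrame:
    """Scan every same-length transcript window against every miRNA.

    Windows are evaluated in the antisense orientation (the window is the
    target site the miRNA base-pairs with); all windows passing the six rules
    are reported in deterministic (miRNA, transcript, offset) order with
    1-based offsets.
    """
    if not transcripts:
        raise ValueError("no transcripts supplied")
    rows = []
    for mirna_name in sorted(mirnas):
        mirna = dna(mirnas[mirna_name])
        L = len(mirna)
        for tx_name in sorted(transcripts):
            tx = dna(transcripts[tx_name])
            for off in range(0, len(tx) - L + 1):
                site = tx[off : off + L]
                report = check_rules(mirna, site, gu_as_mismatch, ratio_cut)
                if report.passed:
                    rows.append(
                        {
                            "mirna": mirna_name,
                            "gene": (tx2gene or {}).get(tx_name, tx_name),
                            "transcript": tx_name,
                            "offset": off + 1,
                            "mismatch_score": report.mismatch_score,
                            **{f"rule_{k}": v for k, v in report.rules.items()},
                            "mfe": report.mfe,
                            "mfe_ratio": round(report.mfe_ratio, 4),
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna",
            "gene",
            "transcript",
            "offset",
            "mismatch_score",
            "rule_i",
            "rule_ii",
            "rule_iii",
            "rule_iv",
            "rule_v",
            "rule_vi",
            "mfe",
            "mfe_ratio",
        ],
    )
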