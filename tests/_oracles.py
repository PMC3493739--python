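"""Independent brute-force oracles shared across test modules."""

from smallrna._seq import revcomp


def oracle_report(mirna, site):
    """Rule-by-rule brute-force checker for one ungapped duplex.

    Written independently of the library: plain loops over pairing states,
    its own stack-energy walk, and literal transcriptions of the six rules.
    Returns ({rule: passed}, mismatch score, MFE ratio).
    """
    L = len(mirna)
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    gu = {("G", "T"), ("T", "G")}
    states = []
    for i in range(L):
        pair = (mirna[i], site[L - 1 - i])
        states.append("WC" if pair in wc else "GU" if pair in gu else "MM")
    score = sum(1.0 if s == "MM" else 0.5 if s == "GU" else 0.0 for s in states)
    runs, run = [], 0
    for s in states + ["WC"]:
        if s == "MM":
            run += 1
        elif run:
            runs.append(run)
            run = 0
    r1 = score <= 4
    r2 = all(r <= 2 for r in runs)
    r3 = not any(states[i - 1] == "MM" and states[i] == "MM" for i in range(2, min(12, L)))
    r4 = all(states[p - 1] != "MM" for p in (10, 11) if p <= L)
    r5 = (
        sum(
            1.0 if states[p - 1] == "MM" else 0.5 if states[p - 1] == "GU" else 0.0
            for p in range(1, min(12, L) + 1)
        )
        <= 2.5
    )
    strength = {
        ("G", "C"): 3.3, ("C", "G"): 3.3, ("A", "T"): 0.9, ("T", "A"): 0.9,
        ("G", "T"): 1.0, ("T", "G"): 1.0,
    }

    def energy(s):
        e = 0.0
        for i in range(L - 1):
            p1, p2 = (mirna[i], s[L - 1 - i]), (mirna[i + 1], s[L - 2 - i])
            if p1 in strength and p2 in strength:
                e -= (strength[p1] + strength[p2]) / 2
        paired = ["P" if (mirna[i], s[L - 1 - i]) in strength else "M" for i in range(L)]
        i = 0
        while i < L:
            if paired[i] == "M":
                j = i
                while j < L and paired[j] == "M":
                    j += 1
                if i > 0 and j < L:
                    e += 0.5
                i = j
            else:
                i += 1
        return min(e, 0.0)

    perfect = energy(revcomp(mirna))
    ratio = energy(site) / perfect if perfect < 0 else 0.0
    return {"i": r1, "ii": r2, "iii": r3, "iv": r4, "v": r5, "vi": ratio >= 0.75}, score, ratio
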