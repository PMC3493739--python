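"""Hypergeometric GO-term enrichment of predicted target genes.

For each GO term with K annotated genes in a background of N, a target set of
n genes containing k annotated ones is scored by the upper hypergeometric
tail P(X >= k), X ~ Hypergeometric(N, K, n).  Genes lacking any GO annotation
are excluded from both the background and the target set, so N and n count
only annotatable genes.  Raw p-values are reported alongside BH-adjusted
FDRs; the conventional significance flag is raw p < 0.001.  GO-graph
propagation to ancestor terms is not performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Set

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .diffexpr import bh_fdr


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # target genes with the term
    K: int  # background genes with the term
    n: int  # target-set size
    N: int  # background size
    pvalue: float
    fdr: float


def _log_comb(n, r):
    return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), summed exactly in log space."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    if not (0 <= k <= min(n, K)):
        raise ValueError("require 0 <= k <= min(n, K)")
    i = np.arange(k, min(n, K) + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(log_terms).sum()))


def read_gene2go(path) -> Dict[str, Set[str]]:
    """Read a two-column gene<TAB>term TSV into {gene: {terms}}."""
    mapping: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            gene, term = fields
            mapping.setdefault(gene, set()).add(term)
    return mapping


def enrich(
    target_genes: Iterable[str],
    gene2go: Mapping[str, Set[str]],
    background: Optional[Iterable[str]] = None,
    p_cut: float = 0.001,
) -> pd.DataFrame:
    """Enrichment table over all terms hit by >= 1 target gene.

    Background defaults to every annotated gene in the mapping; an explicit
    background list is intersected with the annotated genes.  Raises if no
    target gene carries any annotation.
    """
    annotated = {g for g, terms in gene2go.items() if terms}
    bg = annotated if background is None else set(background) & annotated
    targets = set(target_genes) & bg
    if not targets:
        raise ValueError("no annotated target genes: nothing to enrich")
    N = len(bg)
    n = len(targets)
    term_bg: Dict[str, int] = {}
    term_k: Dict[str, int] = {}
    for gene in bg:
        for term in gene2go[gene]:
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in targets:
                term_k[term] = term_k.get(term, 0) + 1
    rows = []
    for term in sorted(term_k):
        k, K = term_k[term], term_bg[term]
        rows.append((term, k, K, n, N, hypergeom_tail(k, K, n, N)))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "pvalue"])
    df["fdr"] = bh_fdr(df["pvalue"].to_numpy())
    df["significant"] = df["pvalue"] < p_cut
    return df.sort_values(["pvalue", "term"], kind="mergesort").reset_index(drop=True)
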