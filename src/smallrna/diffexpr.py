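"""Between-library differential expression of known miRNAs.

With one pooled library per condition there are no replicates; significance
of a count difference comes from the Audic-Claverie statistic.  Given x reads
for a miRNA in library 1 (total N1) and y in library 2 (total N2), the
probability of y given x is

    p(x|y) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1)

which is the negative-binomial posterior predictive of the second count under
a flat prior on the shared expression rate.  One-sided p-values cumulate this
over the observed-or-more-extreme tail in y at fixed x; the default two-sided
p doubles the smaller tail (capped at 1).  Everything is computed in log
space / via the regularized incomplete beta, so counts in the millions are
fine.

Counts are normalized to reads per million (RPM, the "std" columns of the
report); zero-count RPMs are floored at 0.01 before fold changes so the log2
ratio is always defined.  A miRNA is called up (or down) when |log2 fc| >= 1
and the difference is significant (p <= 0.001 by default; an FDR <= 0.01 gate
is available instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import betainc, gammaln
from statsmodels.stats.multitest import multipletests

RPM_FLOOR = 0.01
DEFAULT_FC_CUT = 1.0
DEFAULT_P_CUT = 0.001
DEFAULT_FDR_CUT = 0.01


@dataclass(frozen=True)
class LibraryTotals:
    """Total small-RNA reads: N1 for x's library, N2 for y's library."""

    n1: int
    n2: int

    def __post_init__(self):
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("library totals must be positive")


def rpm(count, total):
    """Reads per million: count / total * 1e6."""
    total = np.asarray(total)
    if np.any(total <= 0):
        raise ValueError("library total must be > 0")
    return np.asarray(count) / total * 1e6


def floor_zero(std, floor: float = RPM_FLOOR):
    """Floor an RPM value at 0.01 so zero counts have a defined log2 ratio."""
    return np.maximum(std, floor)


def log2_ratio(numerator_std, denominator_std):
    """log2(numerator/denominator); inputs must be positive (floor first)."""
    num = np.asarray(numerator_std, dtype=float)
    den = np.asarray(denominator_std, dtype=float)
    if np.any(num <= 0) or np.any(den <= 0):
        raise ValueError("log2_ratio requires positive inputs; apply floor_zero first")
    return np.log2(num / den)


def _validate_counts(x, y):
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    return x.astype(np.int64), y.astype(np.int64)


def ac_point_prob(x, y, n1, n2):
    """The Audic-Claverie point probability p(x|y), evaluated in log space."""
    x, y = _validate_counts(x, y)
    log_r = np.log(n2) - np.log(n1)
    log_p = (
        y * log_r
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * np.log1p(np.exp(log_r))
    )
    return np.exp(log_p)


def ac_pvalue(x, y, n1, n2, mode: str = "two_sided"):
    """Tail p-value of observing y (library 2) given x (library 1).

    ``less``: P(Y <= y | x); ``greater``: P(Y >= y | x); ``two_sided``:
    min(1, 2*min(less, greater)).  Vectorized over x and y.

    The cumulative tail is the CDF of a negative binomial with x+1 successes
    and success probability N1/(N1+N2), evaluated via the regularized
    incomplete beta function.
    """
    x, y = _validate_counts(x, y)
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    p0 = n1 / (n1 + n2)
    less = betainc(x + 1, y + 1, p0)
    greater = np.where(y == 0, 1.0, 1.0 - betainc(x + 1, np.maximum(y, 1), p0))
    if mode == "less":
        out = less
    elif mode == "greater":
        out = greater
    elif mode == "two_sided":
        out = np.minimum(1.0, 2.0 * np.minimum(less, greater))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out if out.ndim else float(out)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


def classify(
    log2fc,
    pvalue,
    fdr=None,
    fc_cut: float = DEFAULT_FC_CUT,
    p_cut: float = DEFAULT_P_CUT,
    use_fdr: bool = False,
    fdr_cut: float = DEFAULT_FDR_CUT,
):
    """Three-way call: 'up' / 'down' needs |log2fc| >= fc_cut AND significance.

    Significance is p <= p_cut by default, or fdr <= fdr_cut when
    ``use_fdr``.  Vectorized; scalar inputs give a scalar string.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    if use_fdr:
        if fdr is None:
            raise ValueError("use_fdr requires fdr values")
        significant = np.asarray(fdr, dtype=float) <= fdr_cut
    else:
        significant = np.asarray(pvalue, dtype=float) <= p_cut
    out = np.where(
        significant & (log2fc >= fc_cut),
        "up",
        np.where(significant & (log2fc <= -fc_cut), "down", "equal"),
    )
    return out if out.ndim else str(out)


def differential_expression(
    counts_case: Mapping[str, int],
    counts_control: Mapping[str, int],
    totals: LibraryTotals,
    fc_cut: float = DEFAULT_FC_CUT,
    p_cut: float = DEFAULT_P_CUT,
    use_fdr: bool = False,
    fdr_cut: float = DEFAULT_FDR_CUT,
) -> pd.DataFrame:
    """Full DE table for the union of miRNA names in the two count maps.

    The reported ``log2fc`` column follows the published numeric convention
    log2(control/case); the ``class`` column is oriented biologically
    ('up' = higher in the case library).  Raw counts feed the p-value; only
    the RPM values used for the fold change are floored.
    """
    names = sorted(set(counts_case) | set(counts_control))
    x = np.array([counts_case.get(n, 0) for n in names], dtype=np.int64)
    y = np.array([counts_control.get(n, 0) for n in names], dtype=np.int64)
    case_std = rpm(x, totals.n1)
    control_std = rpm(y, totals.n2)
    case_f = floor_zero(case_std)
    control_f = floor_zero(control_std)
    fc_reported = log2_ratio(control_f, case_f)
    fc_case = -fc_reported
    pvals = np.atleast_1d(ac_pvalue(x, y, totals.n1, totals.n2, mode="two_sided"))
    fdr = bh_fdr(pvals)
    cls = classify(fc_case, pvals, fdr, fc_cut, p_cut, use_fdr, fdr_cut)
    return pd.DataFrame(
        {
            "name": names,
            "case_count": x,
            "control_count": y,
            "case_std": np.round(case_std, 4),
            "control_std": np.round(control_std, 4),
            "log2fc": fc_reported,
            "pvalue": pvals,
            "fdr": fdr,
            "class": np.atleast_1d(cls),
        }
    )
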