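"""Small statistical primitives shared by the analysis arms."""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("atrisk")

#: combined-n cutoff below which the rank-sum test is computed exactly
EXACT_RANKSUM_MAX_N = 20


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the combined sample size is at most
    ``EXACT_RANKSUM_MAX_N`` and the data are tie-free; otherwise the
    normal approximation with tie correction. Degenerate all-tied
    input returns p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations tied; rank-sum p set to 1")
        return 0.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_RANKSUM_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_upper_tail(N: int, K: int, n: int, m: int) -> float:
    """P(overlap >= m) when drawing n from a universe of N with K marked."""
    if m == 0:
        return 1.0
    return float(stats.hypergeom.sf(m - 1, N, K, n))


def stable_child_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one by stable hashing."""
    import hashlib

    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)
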