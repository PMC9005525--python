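"""Shared statistical helpers: BH step-up FDR, one-sided Fisher enrichment,
rank-sum testing for markers, and the small-sample paired comparisons."""

from __future__ import annotations

import numpy as np
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .datatypes import SynocloneError


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    Guarantees q >= p elementwise and monotonicity in the p-ranks.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise SynocloneError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def fisher_enrichment_p(shared: int, n_a: int, n_b: int, universe: int) -> float:
    """One-sided (enrichment) Fisher exact p for repertoire overlap.

    2x2 table: [[shared, A-only], [B-only, universe - A-union-B]].  The
    one-sided enrichment p equals the hypergeometric upper tail
    P[X >= shared | N=universe, K=n_a, n=n_b].
    """
    if shared > min(n_a, n_b):
        raise SynocloneError(
            f"shared={shared} exceeds min(|A|={n_a}, |B|={n_b})"
        )
    if n_a > universe or n_b > universe:
        raise SynocloneError("cluster clone count exceeds universe size")
    if shared < max(0, n_a + n_b - universe):
        raise SynocloneError("shared below the feasible minimum for this table")
    # sf(k) = P[X > k], so upper tail including shared is sf(shared - 1)
    return float(st.hypergeom.sf(shared - 1, universe, n_a, n_b))


def ranksum_test(x, y, exact_max_n: int = 8) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both groups are small and tie-free; otherwise
    the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    if no_ties and len(x) <= exact_max_n and len(y) <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    res = st.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def paired_t(before, after):
    """Two-sided paired t test; identical vectors give (0, 1) by contract."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise SynocloneError("paired vectors must have equal length")
    diffs = after - before
    if np.allclose(diffs.std(ddof=1) if diffs.size > 1 else 0.0, 0.0) and np.allclose(
        diffs.mean(), 0.0
    ):
        return 0.0, 1.0
    res = st.ttest_rel(after, before)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(before, after, alternative: str = "less"):
    """One-sided Wilcoxon matched-pairs signed-rank test on after - before.

    Zero differences are dropped (classic Wilcoxon).  Exact p by sign
    enumeration for n <= 15 untied pairs, normal approximation above.
    ``alternative`` refers to the location of ``after`` relative to
    ``before`` ("less" tests for a decrease).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise SynocloneError("paired vectors must have equal length")
    diffs = after - before
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        raise SynocloneError("all paired differences are zero; Wilcoxon undefined")
    if n < 3:
        raise SynocloneError("need >= 3 nonzero paired differences")
    method = "exact" if n <= 15 else "approx"
    res = st.wilcoxon(diffs, alternative=alternative, zero_method="wilcox", method=method)
    return float(res.statistic), float(res.pvalue)


def anova_bonferroni(groups: dict) -> dict:
    """One-way ANOVA across >= 3 groups with Bonferroni pairwise t tests.

    Returns {"f": F, "p": p, "pairwise": {(a, b): adjusted p}}.
    """
    names = sorted(groups)
    if len(names) < 3:
        raise SynocloneError("ANOVA helper expects >= 3 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    f, p = st.f_oneway(*arrays)
    n_pairs = len(names) * (len(names) - 1) // 2
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            raw = st.ttest_ind(arrays[i], arrays[j]).pvalue
            pairwise[(names[i], names[j])] = float(min(1.0, raw * n_pairs))
    return {"f": float(f), "p": float(p), "pairwise": pairwise}
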