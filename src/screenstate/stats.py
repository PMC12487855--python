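"""Shared statistical engines: rank tests, replicate Wald test, BH FDR.

One Mann-Whitney/Wilcoxon rank-sum engine serves both the screen scoring
(gene elements vs non-targeting controls) and the single-cell group
comparisons, so the two halves of the pipeline cannot drift apart in how
they compute p-values.
"""

from __future__ import annotations

import numpy as np
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import InsufficientReplicatesError, ScreenStateError

__all__ = ["rank_test", "mannwhitney_vs_ntc", "wald_test_replicates", "adjust_fdr"]

# Exact enumeration is feasible and exactly matched by scipy's exact method
# only for small tie-free samples; beyond that use the normal approximation
# with continuity and tie corrections.
_EXACT_MAX_N = 12


def rank_test(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Two-sided (by default) Mann-Whitney U / Wilcoxon rank-sum test.

    Exact null distribution when ``len(x) + len(y) <= 12`` and the pooled
    sample is tie-free; otherwise the normal approximation with continuity
    correction and tie-corrected variance.

    Returns
    -------
    (U, p) : the U statistic for ``x`` and the p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ScreenStateError("rank test requires both groups non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if x.size + y.size <= _EXACT_MAX_N and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def mannwhitney_vs_ntc(gene_phenotypes, ntc_phenotypes) -> float:
    """Two-sided Mann-Whitney p-value of a gene's element phenotypes
    against the non-targeting control phenotype distribution."""
    _, p = rank_test(gene_phenotypes, ntc_phenotypes, alternative="two-sided")
    return p


def wald_test_replicates(per_replicate_log2ratios, ntc_mask) -> np.ndarray:
    """Per-element Wald test across replicates.

    For element j with replicate log2 ratios r_1..r_n the statistic is
    z = mean(r) / (s / sqrt(n)) with s the sample SD over replicates.
    Elements with s = 0 use the median replicate SD over non-targeting
    controls as a variance floor (so a constant-but-nonzero element is
    testable).  Two-sided p from the standard normal.

    Parameters
    ----------
    per_replicate_log2ratios : (n_replicates, n_elements) array
    ntc_mask : boolean (n_elements,) array flagging non-targeting controls

    Returns
    -------
    (n_elements,) array of p-values.
    """
    ratios = np.asarray(per_replicate_log2ratios, dtype=float)
    if ratios.ndim != 2:
        raise ScreenStateError("expected a replicates x elements matrix")
    n = ratios.shape[0]
    if n < 2:
        raise InsufficientReplicatesError(
            f"Wald test needs >= 2 replicates, got {n}"
        )
    ntc_mask = np.asarray(ntc_mask, dtype=bool)
    mean = ratios.mean(axis=0)
    sd = ratios.std(axis=0, ddof=1)
    floor = float(np.median(sd[ntc_mask])) if ntc_mask.any() else float(np.median(sd))
    sd = np.where(sd == 0.0, floor, sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    # mean 0 with sd 0 everywhere (floor 0) is a genuine no-signal case
    z = np.where((mean == 0.0), 0.0, z)
    return 2.0 * sps.norm.sf(np.abs(z))


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Guarantees q >= p element-wise and monotonicity in the sorted order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ScreenStateError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
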