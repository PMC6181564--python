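"""Nonparametric population statistics: Wilcoxon signed-rank, Kruskal-Wallis.

The Wilcoxon signed-rank test is implemented with an exact tie-aware null
distribution for n <= 25 (dynamic-programming enumeration over sign
assignments of the midranks) and a normal approximation with continuity and
tie corrections above.  Kruskal-Wallis is delegated to scipy, which applies
average ranks and the tie correction with a chi-squared p-value.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sst

__all__ = ["wilcoxon_signed_rank", "kruskal_wallis"]

EXACT_LIMIT = 25


def _exact_signed_rank_p(ranks2: np.ndarray, w2_obs: int) -> float:
    """Two-sided exact p for W+ given doubled midranks (integers).

    Enumerates the distribution of 2*W+ over all 2**n sign assignments by
    convolution; p = min(1, 2*min(P(W+ <= obs), P(W+ >= obs))).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    p_le = counts[:w2_obs + 1].sum()
    p_ge = counts[w2_obs:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(paired_before, paired_after) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (W+, two-sided p).

    Zero differences are dropped.  Exact null distribution for n <= 25,
    normal approximation with continuity correction beyond.
    """
    before = np.asarray(paired_before, dtype=float)
    after = np.asarray(paired_after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    d = after - before
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; the test is undefined")
    if d.size < 3:
        raise ValueError("need at least 3 non-zero paired differences")
    ranks = sst.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= EXACT_LIMIT:
        ranks2 = np.round(2.0 * ranks).astype(np.intp)
        w2 = int(round(2.0 * w_plus))
        return w_plus, _exact_signed_rank_p(ranks2, w2)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = (n * (n + 1) * (2 * n + 1) / 24.0
           - np.sum(tie_counts ** 3 - tie_counts) / 48.0)
    diff = w_plus - mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    return w_plus, float(2.0 * sst.norm.sf(abs(z)))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H test across independent groups; returns (H, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # scipy rejects the all-identical case; H is 0 by definition
        return 0.0, 1.0
    h, p = sst.kruskal(*groups)
    return float(h), float(p)
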