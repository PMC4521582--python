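"""Nonparametric tests gating the spiking claims.

Only the two tests that gate specific claims are implemented here: the
one-sample Wilcoxon signed-rank test (does a population transmit more than one
spike per train?) and the two-sample F-test for equal variances (is spike
timing jitter wider in one population?).  Everything else is delegated to
scipy/statsmodels by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["wilcoxon_signed_rank", "variance_ratio_test", "TestResult"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    significant: bool
    note: str = ""


def _exact_signed_rank_sf(ranks2: np.ndarray, w2: float) -> tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) under the exact null, by dynamic programming
    over the distribution of the positive-rank sum.  ``ranks2`` are ranks
    doubled to integers so midranks from ties stay exact."""
    total = int(ranks2.sum())
    # counts[s] = number of sign assignments with positive-rank sum s
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2i = int(round(w2))
    p_le = counts[: w2i + 1].sum()
    p_ge = counts[w2i:].sum()
    return float(p_le), float(p_ge)


def wilcoxon_signed_rank(
    x: np.ndarray,
    mu: float = 0.0,
    alpha: float = 0.05,
    exact_max_n: int = 25,
) -> TestResult:
    """Two-sided one-sample Wilcoxon signed-rank test of location ``mu``.

    Zero differences are dropped (standard signed-rank convention); midranks
    are used for ties.  For n <= ``exact_max_n`` the null distribution of the
    positive-rank sum is computed exactly by enumeration-equivalent dynamic
    programming; above that a normal approximation with tie correction and
    continuity correction is used.
    """
    d = np.asarray(x, dtype=float) - mu
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(np.nan, 1.0, False, "all differences zero; test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    if n <= exact_max_n:
        ranks2 = np.round(2 * ranks).astype(int)
        p_le, p_ge = _exact_signed_rank_sf(ranks2, 2 * w_pos)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        # variance with tie correction
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(float(w_pos), float(p), bool(p < alpha))


def variance_ratio_test(
    a: np.ndarray, b: np.ndarray, alpha: float = 0.05
) -> TestResult:
    """Two-sample F-test for equal variances, larger variance in the numerator.

    Symmetric in its arguments by the larger-variance-numerator convention;
    two-sided p from the F distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs n >= 3")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance; F undefined")
    if va >= vb:
        f, dfn, dfd = (va / vb if vb > 0 else np.inf), a.size - 1, b.size - 1
    else:
        f, dfn, dfd = vb / va, b.size - 1, a.size - 1
    p = float(min(1.0, 2.0 * sps.f.sf(f, dfn, dfd)))
    return TestResult(float(f), p, bool(p < alpha))
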