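"""Shared statistical primitives: exact Poisson CIs, Fisher tests, BH, empirical p."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def poisson_ci(k: float, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Garwood) chi-square confidence interval for a Poisson count.

    Returns ``(lo, hi)`` with ``lo = 0.5 * chi2.ppf(alpha/2, 2k)`` (zero when
    ``k == 0``) and ``hi = 0.5 * chi2.ppf(1 - alpha/2, 2k + 2)``.  Divide by
    the exposure to obtain a rate interval.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    lo = 0.0 if k == 0 else 0.5 * sps.chi2.ppf(alpha / 2.0, 2.0 * k)
    hi = 0.5 * sps.chi2.ppf(1.0 - alpha / 2.0, 2.0 * k + 2.0)
    return float(lo), float(hi)


def fisher_exact(table, alternative: str = "two-sided") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table by direct hypergeometric summation.

    The two-sided p sums, over the support of the conditional hypergeometric
    distribution, every table probability not exceeding that of the observed
    table (with a small relative tolerance for floating ties).  Returns
    ``(odds_ratio, p)`` where the odds ratio is the unconditional sample
    estimate ``(a d) / (b c)``.
    """
    (a, b), (c, d) = np.asarray(table, dtype=float)
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    N = a + b + c + d
    K = a + b  # row-1 margin
    n = a + c  # column-1 margin
    if N == 0:
        return np.nan, 1.0
    support = np.arange(max(0, int(K + n - N)), min(int(K), int(n)) + 1)
    pmf = sps.hypergeom.pmf(support, int(N), int(K), int(n))
    p_obs = pmf[support == int(a)][0]
    if alternative == "two-sided":
        p = pmf[pmf <= p_obs * (1.0 + 1e-12)].sum()
    elif alternative == "greater":
        p = pmf[support >= int(a)].sum()
    elif alternative == "less":
        p = pmf[support <= int(a)].sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    return float(odds), float(min(p, 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs are passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[mask] = adj
    return out


def empirical_p_two_tailed(observed: float, null: np.ndarray) -> float:
    """Two-tailed empirical p: twice the smaller tail fraction, ties extreme, clipped at 1."""
    null = np.asarray(null, dtype=float)
    null = null[~np.isnan(null)]
    if null.size == 0:
        return np.nan
    upper = np.count_nonzero(null >= observed)
    lower = np.count_nonzero(null <= observed)
    return float(min(1.0, 2.0 * min(upper, lower) / null.size))


def empirical_p_one_sided(observed: float, background: np.ndarray, side: str = "greater") -> float:
    """Fraction of background values at least as extreme as the observation."""
    bg = np.asarray(background, dtype=float)
    bg = bg[~np.isnan(bg)]
    if bg.size == 0:
        return np.nan
    if side == "greater":
        return float(np.count_nonzero(bg >= observed) / bg.size)
    if side == "less":
        return float(np.count_nonzero(bg <= observed) / bg.size)
    if side == "magnitude":
        return float(np.count_nonzero(np.abs(bg) >= abs(observed)) / bg.size)
    raise ValueError(f"unknown side {side!r}")
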