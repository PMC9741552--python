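"""Shared statistical routines.

Fisher's exact test is the workhorse of the tissue-specificity and
binding-overlap analyses, where it can be called tens of thousands of times
on small 2x2 tables.  The implementation here computes the two-sided p-value
from the hypergeometric distribution of the table's top-left cell and caches
the per-margin probability vector, which makes repeated testing over tables
sharing margins essentially free.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats as sps

__all__ = [
    "fisher_two_sided",
    "chi2_2x2",
    "multinomial_gof",
    "percent",
]

# relative tolerance when comparing pmf values for the two-sided tail sum,
# matching the convention used by R's fisher.test and scipy
_REL_EPS = 1e-7


@lru_cache(maxsize=65536)
def _hypergeom_pmf(n: int, r: int, m: int) -> tuple[int, np.ndarray]:
    """Probability vector of the top-left cell for fixed margins.

    n: grand total, r: first-row total, m: first-column total.
    Returns (k_min, pmf over k = k_min .. k_max).
    """
    k_min = max(0, r + m - n)
    k_max = min(r, m)
    ks = np.arange(k_min, k_max + 1)
    pmf = sps.hypergeom.pmf(ks, n, r, m)
    return k_min, pmf


def fisher_two_sided(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (odds_ratio, p).  The p-value sums hypergeometric point
    probabilities not exceeding that of the observed table (the same
    definition scipy and R use).  The odds ratio is the sample (conditional
    MLE-free) cross-product ratio, with np.inf / 0 / nan for degenerate
    tables.
    """
    (a, b), (c, d) = (int(table[0][0]), int(table[0][1])), (
        int(table[1][0]),
        int(table[1][1]),
    )
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count in 2x2 table")
    n = a + b + c + d
    if n == 0:
        return float("nan"), 1.0
    k_min, pmf = _hypergeom_pmf(n, a + b, a + c)
    p_obs = pmf[a - k_min]
    p = float(pmf[pmf <= p_obs * (1.0 + _REL_EPS)].sum())
    p = min(1.0, p)
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return float(odds), p


def chi2_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Chi-squared test of independence on a 2x2 table (no Yates correction
    by default).  Falls back to Fisher's exact test when a margin is zero,
    where the chi-squared statistic is undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        _, p = fisher_two_sided(t.astype(int))
        return float("nan"), p
    chi2, p, _, _ = sps.chi2_contingency(t, correction=correction)
    return float(chi2), float(p)


def multinomial_gof(observed, probs, exact_max_n: int = 300) -> float:
    """Goodness-of-fit p-value for observed class counts under multinomial
    probabilities.

    Uses the exact multinomial test (sum of probabilities of all outcome
    tables at most as probable as the observed one) when the total count is
    <= ``exact_max_n`` and the number of classes is 3 or fewer; otherwise a
    chi-squared goodness-of-fit test.
    """
    obs = np.asarray(observed, dtype=int)
    p = np.asarray(probs, dtype=float)
    if obs.ndim != 1 or obs.shape != p.shape:
        raise ValueError("observed and probs must be 1-D and equal length")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("probabilities must sum to 1")
    n = int(obs.sum())
    if n == 0:
        raise ValueError("no observations")
    if n <= exact_max_n and obs.size <= 3:
        return _exact_multinomial_p(obs, p)
    expected = n * p
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return float(sps.chi2.sf(chi2, df=obs.size - 1))


def _exact_multinomial_p(obs: np.ndarray, p: np.ndarray) -> float:
    n = int(obs.sum())
    k = obs.size
    if k == 1:
        return 1.0
    dist = sps.multinomial(n, p)
    if k == 2:
        xs = np.arange(n + 1)
        tables = np.stack([xs, n - xs], axis=1)
    else:  # k == 3: enumerate all compositions of n
        i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
        mask = i + j <= n
        tables = np.stack([i[mask], j[mask], n - i[mask] - j[mask]], axis=1)
    logpmf = dist.logpmf(tables)
    log_obs = dist.logpmf(obs)
    pv = float(np.exp(logpmf[logpmf <= log_obs + 1e-9]).sum())
    return min(1.0, pv)


def percent(numerator: float, denominator: float, digits: int = 1) -> float:
    """Percentage rounded to ``digits`` decimal places (the reporting
    convention used throughout the summary output)."""
    if denominator == 0:
        raise ZeroDivisionError("percent of an empty denominator")
    return round(100.0 * numerator / denominator, digits)
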