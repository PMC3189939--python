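"""Exact hypergeometric tail probabilities and Benjamini-Hochberg FDR.

This is the shared statistical kernel behind both enrichment directions in
this package: gene-axis over-representation (FGA) and sample-axis coverage
enrichment (CAFET).  Both reduce a 2x2 contingency table to the one-sided
Fisher exact p-value, i.e. the inclusive upper tail of a hypergeometric
distribution:

    P(X >= k) = sum_{i=k}^{min(n, K)} C(K, i) C(N-K, n-i) / C(N, n)

with population size ``N``, ``K`` members of the distinguished class, ``n``
draws and ``k`` the observed overlap.  The sum is evaluated in log space
(log-gamma binomials combined with log-sum-exp) because the binomial
coefficients involved in realistic cohorts, e.g. C(138, 90), overflow any
naive factorial-based evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["TailQuery", "hypergeom_upper_tail", "tail_p", "benjamini_hochberg"]


@dataclass(frozen=True)
class TailQuery:
    """A validated 2x2 overlap query.

    Parameters
    ----------
    population
        Total number of items (N).
    successes
        Number of items in the distinguished class (K).
    draws
        Number of items with the property of interest (n).
    observed
        Overlap between the draws and the distinguished class (k).
    """

    population: int
    successes: int
    draws: int
    observed: int

    def __post_init__(self) -> None:
        N, K, n, k = self.population, self.successes, self.draws, self.observed
        if N < 0 or K < 0 or n < 0 or k < 0:
            raise ValueError("all counts must be non-negative")
        if K > N:
            raise ValueError(f"successes ({K}) exceed population ({N})")
        if n > N:
            raise ValueError(f"draws ({n}) exceed population ({N})")
        if k > min(K, n):
            raise ValueError(
                f"observed overlap ({k}) exceeds min(successes={K}, draws={n})"
            )


def _log_comb(n: int, k: int) -> float:
    return (
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    )


def hypergeom_upper_tail(query: TailQuery) -> float:
    """Inclusive upper-tail probability P(X >= observed).

    Computed by log-sum-exp over the log-gamma form of each hypergeometric
    point mass, so it stays accurate far into the tail (p ~ 1e-18) where a
    complementary-CDF subtraction would lose all precision.

    Returns a probability in [0, 1]; exactly 1.0 when ``observed`` is 0.
    """
    N, K, n, k = query.population, query.successes, query.draws, query.observed
    hi = min(n, K)
    if k == 0:
        return 1.0
    lo = max(k, n - (N - K))  # overlaps below n-(N-K) are combinatorially impossible
    if lo > hi:
        return 0.0
    log_denom = _log_comb(N, n)
    log_terms = np.array(
        [_log_comb(K, i) + _log_comb(N - K, n - i) for i in range(lo, hi + 1)]
    )
    m = log_terms.max()
    log_p = m + math.log(np.exp(log_terms - m).sum()) - log_denom
    return float(min(1.0, math.exp(log_p)))


def tail_p(population: int, successes: int, draws: int, observed: int) -> float:
    """Convenience wrapper building the :class:`TailQuery` inline."""
    return hypergeom_upper_tail(TailQuery(population, successes, draws, observed))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} ( p_(j) * m / j ) over the ascending-sorted p's,
    capped at 1, then mapped back to the original positions.  ``m`` is the
    length of the input: callers are responsible for passing only the tests
    actually performed (items filtered out before testing must not inflate m).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return np.empty(0)
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q
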