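"""Hypergeometric probability mass function and the clause fitness scale.

The fitness of a conjunctive clause is scored by the hypergeometric PMF:
the probability of drawing ``k`` target-class subjects in a sample of
``n`` clause-matching subjects from a population of ``N`` subjects of
which ``K`` belong to the target class,

    P(k; N, K, n) = C(K, k) * C(N - K, n - k) / C(N, n).

A small PMF means the observed class enrichment of the clause's match
set is unlikely under random sampling.  We report fitness on a
decreasing-PMF scale, ``fitness = -log10(PMF)``, so that "higher fitness"
means "less likely by chance" and the quantity is numerically stable for
very small probabilities.  The PMF is a descriptive enrichment score
here, not a p-value.

For population sizes up to a couple of thousand the PMF is computed with
exact integer binomials (correctly rounded to double precision); beyond
that a log-gamma evaluation takes over.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

__all__ = ["hypergeom_pmf", "hypergeom_logpmf", "fitness_from_counts", "fitness_table"]

_EXACT_LIMIT = 2000  # exact big-int binomials stay fast up to here

_LOG10 = math.log(10.0)


def _check_support(k: int, N: int, K: int, n: int) -> None:
    if not (0 <= K <= N):
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    lo, hi = max(0, n - (N - K)), min(n, K)
    if not (lo <= k <= hi):
        raise ValueError(
            f"k={k} outside hypergeometric support [{lo}, {hi}] for N={N}, K={K}, n={n}"
        )


@lru_cache(maxsize=200_000)
def _exact_pmf_fraction(k: int, N: int, K: int, n: int) -> Fraction:
    return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """Exact hypergeometric PMF P(k matches in class | N, K, n).

    Raises :class:`ValueError` when the arguments fall outside the
    distribution's support.
    """
    k, N, K, n = int(k), int(N), int(K), int(n)
    _check_support(k, N, K, n)
    if N <= _EXACT_LIMIT:
        # Fraction -> float is correctly rounded even for huge numerators.
        return float(_exact_pmf_fraction(k, N, K, n))
    return math.exp(hypergeom_logpmf(k, N, K, n))


def hypergeom_logpmf(k: int, N: int, K: int, n: int) -> float:
    """Natural log of the hypergeometric PMF via log-gamma (no overflow)."""
    k, N, K, n = int(k), int(N), int(K), int(n)
    _check_support(k, N, K, n)

    def lchoose(a: int, b: int) -> float:
        return float(gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1))

    return lchoose(K, k) + lchoose(N - K, n - k) - lchoose(N, n)


def fitness_from_counts(k: int, N: int, K: int, n: int) -> float:
    """Clause fitness, ``-log10`` of the hypergeometric PMF.

    By convention a clause matching no subjects (n = 0) has PMF 1 and
    fitness 0: it carries no information about the outcome.
    """
    if n == 0:
        return 0.0
    pmf = hypergeom_pmf(k, N, K, n)
    if pmf > 0.0:
        return -math.log10(pmf)
    return -hypergeom_logpmf(k, N, K, n) / _LOG10


def fitness_table(N: int, K: int) -> np.ndarray:
    """Precomputed fitness for every (n, k): shape (N+1, K+1), NaN off-support.

    Lets inner evolutionary loops score a clause with one array lookup.
    """
    tab = np.full((N + 1, K + 1), np.nan)
    for n in range(N + 1):
        lo, hi = max(0, n - (N - K)), min(n, K)
        for k in range(lo, hi + 1):
            tab[n, k] = fitness_from_counts(k, N, K, n)
    return tab
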