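"""Rank-based matching of a query gene set against drug signatures.

Each drug signature is a full ranking of the gene universe by
perturbation-induced expression change (rank 1 = most up-regulated).  The
query's ranks are compared to all remaining genes' ranks with a
Mann-Whitney U test; the signed z statistic is positive when the query
sits near the top (the drug up-regulates the query set), negative near the
bottom.  p-values use the exact U null distribution for small universes
and the continuity-corrected normal approximation otherwise; BH correction
runs across the drug library.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["DrugScore", "score_signature", "rank_drug_candidates"]

_EXACT_MAX_N = 60  # exact U distribution for universes up to this size


@dataclass
class DrugScore:
    drug: str
    u: float              # Mann-Whitney U of the query group
    z: float              # signed: positive = query near top = up-regulating
    p: float              # two-sided
    q: float = float("nan")
    direction: str = ""   # "Up" or "Down"


@lru_cache(maxsize=256)
def _u_pmf(m: int, n: int) -> np.ndarray:
    """Exact null pmf of the Mann-Whitney U for group sizes (m, n), no ties.

    Recurrence over which group holds the largest rank:
    N(m, n, u) = N(m-1, n, u-n) + N(m, n-1, u).
    """
    if m == 0 or n == 0:
        return np.ones(1)
    a = _u_pmf(m - 1, n)      # largest rank is a query item: U gains n
    b = _u_pmf(m, n - 1)      # largest rank is a rest item
    arr = np.zeros(m * n + 1)
    arr[n:n + a.size] += a * _comb_frac(m - 1, n)
    arr[:b.size] += b * _comb_frac(m, n - 1)
    return arr / arr.sum()


def _comb_frac(m: int, n: int) -> float:
    from math import comb
    return float(comb(m + n, m))


def _exact_two_sided_p(u: float, m: int, n: int) -> float:
    """Exact two-sided p for U: doubled smaller tail, capped at 1."""
    pmf = _u_pmf(m, n)
    u_int = int(round(u))
    lower = pmf[: u_int + 1].sum()
    upper = pmf[u_int:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def score_signature(query: set[str], ranking: list[str],
                    drug: str = "drug") -> DrugScore:
    """Mann-Whitney comparison of the query's ranks vs all remaining genes.

    ``ranking`` must be a permutation of the gene universe (rank 1 first).
    """
    universe = list(ranking)
    if len(set(universe)) != len(universe):
        raise ValueError("ranking is not a permutation (duplicate genes)")
    query = set(query)
    if not query:
        raise ValueError("query is empty")
    if not query <= set(universe):
        raise ValueError("query contains genes outside the ranking")
    if query == set(universe):
        raise ValueError("query equals the whole universe")
    N = len(universe)
    m = len(query)
    n = N - m
    in_query = np.fromiter((g in query for g in universe), dtype=bool, count=N)
    ranks = np.arange(1, N + 1)
    r_query = ranks[in_query].sum()
    # U counts (query, rest) pairs where the query gene ranks better
    # (smaller rank number); the all-top placement gives the maximum m*n
    u = m * n - (r_query - m * (m + 1) / 2.0)
    mu = m * n / 2.0
    sigma = np.sqrt(m * n * (N + 1) / 12.0)  # no ties in a permutation
    diff = u - mu
    cc = 0.5 * np.sign(diff)
    z = float((diff - cc) / sigma) if sigma > 0 else 0.0
    if N <= _EXACT_MAX_N:
        p = _exact_two_sided_p(u, m, n)
    else:
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    direction = "Up" if z > 0 else "Down"
    return DrugScore(drug=drug, u=float(u), z=z, p=p, direction=direction)


def rank_drug_candidates(query: set[str], signature_library: dict[str, list[str]],
                         alpha: float = 0.05) -> list[DrugScore]:
    """Score every drug, BH-correct across the library, sort by |z| desc.

    Ties in |z| are broken by drug id; significance is q < alpha.
    """
    if not signature_library:
        raise ValueError("signature library is empty")
    scores = [score_signature(query, ranking, drug=drug)
              for drug, ranking in signature_library.items()]
    q = multipletests([s.p for s in scores], method="fdr_bh")[1]
    for s, qi in zip(scores, q):
        s.q = float(qi)
    scores.sort(key=lambda s: (-abs(s.z), s.drug))
    return scores
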