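"""Over-representation analysis, kappa term clustering, cell-type enrichment.

ORA is an upper-tail hypergeometric test of a query gene set against each
term of an ontology (GMT), with Benjamini-Hochberg correction.  Redundant
enriched terms are grouped by average-linkage clustering of Cohen's kappa
agreement between their membership patterns on the query set, cut at kappa
0.3, with the lowest-p term representing each cluster.  Cell-type
enrichment follows the expression-weighted bootstrap scheme: the query's
mean specificity per cell type is compared to random same-size gene sets,
with delta the number of bootstrap standard deviations above the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichedTerm",
    "CellTypeResult",
    "ora_hypergeometric",
    "cluster_terms_kappa",
    "celltype_enrichment",
]


@dataclass
class EnrichedTerm:
    term: str
    overlap: int          # k: query genes in the term
    term_size: int        # K: term genes in the background
    query_size: int       # n
    background_size: int  # N
    p: float
    q: float = float("nan")
    cluster: int = -1
    is_representative: bool = False
    overlap_genes: tuple[str, ...] = ()


@dataclass
class CellTypeResult:
    celltype: str
    observed: float
    boot_mean: float
    boot_sd: float
    delta: float
    p: float
    q: float = float("nan")


def ora_hypergeometric(query: set[str], term_sets: dict[str, list[str]],
                       background: set[str]) -> list[EnrichedTerm]:
    """Upper-tail hypergeometric ORA with BH correction across terms.

    Terms are intersected with the background; p = P(X >= k) for drawing
    ``n`` genes from ``N`` with ``K`` marked.
    """
    query = set(query)
    background = set(background)
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    N = len(background)
    n = len(query)
    results = []
    for term, genes in term_sets.items():
        term_genes = set(genes) & background
        K = len(term_genes)
        overlap_genes = tuple(sorted(query & term_genes))
        k = len(overlap_genes)
        # P(X >= k) == sf(k-1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichedTerm(term=term, overlap=k, term_size=K,
                                    query_size=n, background_size=N,
                                    p=min(p, 1.0),
                                    overlap_genes=overlap_genes))
    if results:
        q = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, qi in zip(results, q):
            r.q = float(qi)
    return results


def _cohen_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's kappa between two binary membership vectors."""
    n = a.size
    po = np.mean(a == b)
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1.0 - pe))


def cluster_terms_kappa(terms: list[EnrichedTerm], query: set[str],
                        threshold: float = 0.3) -> list[EnrichedTerm]:
    """Cluster enriched terms by kappa agreement on the query gene set.

    Membership indicator vectors over the (sorted) query genes are compared
    pairwise with Cohen's kappa; average-linkage hierarchical clustering on
    1 - kappa is cut so that merged clusters have linkage kappa >= threshold.
    Per cluster, the lowest-p term (ties: lexicographically smaller term id)
    is flagged as representative.  Terms are annotated in place and returned.
    """
    if not terms:
        raise ValueError("need at least one enriched term")
    genes = sorted(query)
    M = np.array([[g in set(t.overlap_genes) for g in genes] for t in terms],
                 dtype=float)
    m = len(terms)
    if m == 1:
        terms[0].cluster = 0
        terms[0].is_representative = True
        return terms
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dist[i, j] = dist[j, i] = 1.0 - _cohen_kappa(M[i], M[j])
    condensed = dist[np.triu_indices(m, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    labels = hierarchy.fcluster(Z, t=1.0 - threshold, criterion="distance")
    for t, lab in zip(terms, labels):
        t.cluster = int(lab) - 1
        t.is_representative = False
    for lab in np.unique(labels):
        members = [t for t in terms if t.cluster == lab - 1]
        rep = min(members, key=lambda t: (t.p, t.term))
        rep.is_representative = True
    return terms


def celltype_enrichment(query: set[str], specificity: pd.DataFrame,
                        n_boot: int = 100_000, seed: int = 0,
                        ) -> list[CellTypeResult]:
    """Bootstrap cell-type enrichment of a query gene set.

    ``specificity``: genes x cell-types matrix with rows summing to 1.
    Per cell type, the query's mean specificity is compared to ``n_boot``
    random gene sets of the same size drawn without replacement from the
    background (all rows); p uses the add-one correction
    (1 + #{boot >= obs}) / (n_boot + 1), and q is BH across cell types.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    query = set(query)
    missing = query - set(specificity.index)
    if missing:
        raise ValueError(f"query genes missing from the specificity matrix: "
                         f"{sorted(missing)[:5]}")
    m = len(query)
    N = specificity.shape[0]
    if m > N:
        raise ValueError("query larger than the background")
    S = specificity.to_numpy(float)
    obs = specificity.loc[sorted(query)].to_numpy(float).mean(axis=0)

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, S.shape[1]))
    for b in range(n_boot):
        idx = rng.choice(N, size=m, replace=False)
        boot[b] = S[idx].mean(axis=0)

    boot_mean = boot.mean(axis=0)
    boot_sd = boot.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(boot_sd > 0, (obs - boot_mean) / boot_sd, 0.0)
    p = (1.0 + (boot >= obs[None, :]).sum(axis=0)) / (n_boot + 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    return [
        CellTypeResult(celltype=str(ct), observed=float(obs[j]),
                       boot_mean=float(boot_mean[j]), boot_sd=float(boot_sd[j]),
                       delta=float(delta[j]), p=float(p[j]), q=float(q[j]))
        for j, ct in enumerate(specificity.columns)
    ]
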