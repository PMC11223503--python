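"""Imaging-transcriptomics: probe selection and spatial gene associations.

Genes whose regional expression tracks a spatial alteration pattern are
found by Spearman correlation with a bootstrap confidence interval over
regions; a gene is selected (a "molecular associate") when the CI at the
requested level excludes zero.  For microarray data with multiple probes
per gene, a representative probe is chosen by leave-one-out Gaussian
kernel regression accuracy over the tissue-sample coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneAssociation",
    "select_representative_probe",
    "gene_association",
    "select_associates",
]


@dataclass
class GeneAssociation:
    gene: str
    rho: float
    ci_lower: float
    ci_upper: float
    selected: bool
    n_bootstrap: int


def select_representative_probe(probe_table: pd.DataFrame,
                                coordinates: np.ndarray,
                                bandwidth: float = 10.0):
    """Pick each gene's representative probe by leave-one-out prediction.

    ``probe_table`` has columns gene, probe, then one column per tissue
    sample; ``coordinates`` is samples x 3 (mm).  Each sample's intensity is
    predicted as the Gaussian-kernel-weighted (exp(-d^2 / 2 sigma^2),
    sigma = bandwidth) average of all other samples; a probe's accuracy is
    the Pearson r between predictions and observations, and the
    highest-accuracy probe wins per gene (ties broken by probe-id order).

    Returns (gene -> probe mapping, probe -> accuracy mapping).
    """
    coords = np.asarray(coordinates, dtype=float)
    n_samples = coords.shape[0]
    if n_samples < 3:
        raise ValueError("need at least 3 tissue samples")
    sample_cols = [c for c in probe_table.columns if c not in ("gene", "probe")]
    if len(sample_cols) != n_samples:
        raise ValueError("probe table sample columns do not match coordinates")

    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    W = np.exp(-d2 / (2.0 * bandwidth ** 2))
    np.fill_diagonal(W, 0.0)
    mass = W.sum(axis=1)
    usable = mass > 0
    if not np.all(usable):
        import warnings
        warnings.warn(f"{(~usable).sum()} samples have zero kernel mass and "
                      "are excluded from accuracy", RuntimeWarning,
                      stacklevel=2)

    intensities = probe_table[sample_cols].to_numpy(float)
    # leave-one-out prediction for all probes at once
    pred = (intensities @ W.T)[:, usable] / mass[usable]
    obs = intensities[:, usable]
    pc = pred - pred.mean(axis=1, keepdims=True)
    oc = obs - obs.mean(axis=1, keepdims=True)
    denom = np.sqrt((pc ** 2).sum(axis=1) * (oc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.where(denom > 0, (pc * oc).sum(axis=1) / denom, -np.inf)

    table = probe_table[["gene", "probe"]].copy()
    table["accuracy"] = acc
    accuracy = dict(zip(table["probe"], table["accuracy"]))
    # max accuracy per gene; ties resolved to the lexicographically first probe
    best = (table.sort_values(["gene", "accuracy", "probe"],
                              ascending=[True, False, True])
            .groupby("gene", sort=False).first()["probe"])
    return dict(best), accuracy


def _spearman_rows(pattern_ranks: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Row-wise Spearman of ``values`` (m x n) against fixed pattern ranks."""
    vranks = stats.rankdata(values, axis=1)
    pc = pattern_ranks - pattern_ranks.mean()
    vc = vranks - vranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((pc ** 2).sum() * (vc ** 2).sum(axis=1))
    out = np.zeros(values.shape[0])
    ok = denom > 0
    out[ok] = (vc[ok] @ pc) / denom[ok]
    return out


def gene_association(pattern: np.ndarray, expression_row: np.ndarray,
                     gene: str = "gene", n_boot: int = 100_000,
                     level: float = 0.99, seed: int = 0) -> GeneAssociation:
    """Spearman rho with a percentile bootstrap CI over regions.

    Region pairs are resampled with replacement; degenerate resamples
    (constant pattern or expression) contribute rho = 0.  The gene is
    selected when the CI at ``level`` excludes zero.
    """
    pattern = np.asarray(pattern, dtype=float)
    x = np.asarray(expression_row, dtype=float)
    n = pattern.size
    if n < 8:
        raise ValueError("need at least 8 regions")
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    if np.all(pattern == pattern[0]) or np.all(x == x[0]):
        raise ValueError("constant pattern or expression vector")

    rho = float(stats.spearmanr(pattern, x).statistic)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    bp = pattern[idx]
    bx = x[idx]
    # rank both resampled vectors per draw; constant draws give rho 0
    bpr = stats.rankdata(bp, axis=1)
    bxr = stats.rankdata(bx, axis=1)
    bpc = bpr - bpr.mean(axis=1, keepdims=True)
    bxc = bxr - bxr.mean(axis=1, keepdims=True)
    denom = np.sqrt((bpc ** 2).sum(axis=1) * (bxc ** 2).sum(axis=1))
    rhos = np.zeros(n_boot)
    ok = denom > 0
    rhos[ok] = (bpc[ok] * bxc[ok]).sum(axis=1) / denom[ok]

    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(rhos, [alpha, 1.0 - alpha])
    return GeneAssociation(gene=gene, rho=rho, ci_lower=float(lo),
                           ci_upper=float(hi),
                           selected=bool(lo > 0 or hi < 0),
                           n_bootstrap=n_boot)


def select_associates(pattern: np.ndarray, expression_matrix: np.ndarray,
                      gene_ids: list[str], n_boot: int = 100_000,
                      level: float = 0.99, seed: int = 0,
                      ) -> list[GeneAssociation]:
    """Apply :func:`gene_association` to every gene of a genes x regions matrix.

    Bootstrap streams are drawn per gene from independent children of
    ``seed`` so results do not depend on gene order.
    """
    X = np.atleast_2d(np.asarray(expression_matrix, dtype=float))
    if X.shape[0] == 0:
        return []
    if len(gene_ids) != X.shape[0]:
        raise ValueError("gene_ids length must match the expression matrix")
    child_seeds = np.random.SeedSequence(seed).spawn(X.shape[0])
    out = []
    for row, gene, ss in zip(X, gene_ids, child_seeds):
        out.append(gene_association(pattern, row, gene=gene, n_boot=n_boot,
                                    level=level,
                                    seed=np.random.default_rng(ss)))
    return out
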