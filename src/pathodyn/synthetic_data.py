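"""Generators for every input the pipeline consumes, with known ground truth.

Analyses of this kind normally consume a clinical neuroimaging cohort, a
structural-connectome average, a regional brain transcriptome, a
single-cell specificity background and a drug-perturbation rank library.
These generators emulate the *shapes and statistical structure* of those
inputs — a sparse nonnegative symmetric
connectome; cognitively-unimpaired (CU) vs Alzheimer's (AD) cohorts with
spatially structured pathology and nonzero true weights in AD; fALFF
observations produced by the package's own forward model plus noise; an
expression matrix with a planted spatially-correlated gene subset; cell-type
specificity with a planted enriched type; and drug rankings with planted
up/down regulators — so every downstream stage can be tested against a known
answer without any download.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .fitting import ModelConfig, forward_falff, subject_profile
from .io import Connectome, SubjectRecord
from .neurodynamics import ThetaTriplet

__all__ = [
    "GroundTruth",
    "generate_connectome",
    "generate_cohort",
    "generate_observed_falff",
    "generate_expression_matrix",
    "generate_probe_table",
    "generate_celltype_specificity",
    "generate_drug_signature_library",
]


@dataclass
class GroundTruth:
    """Everything planted by the generators, for downstream validation."""

    true_thetas: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    planted_genes: list[str] = field(default_factory=list)
    planted_celltypes: list[str] = field(default_factory=list)
    planted_drugs: dict[str, str] = field(default_factory=dict)  # drug -> up/down
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["true_thetas"] = {k: tuple(v) for k, v in d["true_thetas"].items()}
        return cls(**d)


def generate_connectome(n_regions: int, density: float = 0.3,
                        seed: int = 0) -> Connectome:
    """Sparse symmetric nonnegative connectome, guaranteed connected.

    Off-diagonal entries are connection densities in [0, 1]; the fraction of
    nonzero off-diagonal pairs is ~``density``.  Disconnected draws are
    resampled (fresh entropy from the same seed sequence).
    """
    if n_regions < 2:
        raise ValueError("n_regions must be at least 2")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n_pairs = n_regions * (n_regions - 1) // 2
    iu = np.triu_indices(n_regions, k=1)
    for _ in range(1000):
        mask = rng.random(n_pairs) < density
        if density == 1.0:
            mask[:] = True
        weights = np.where(mask, rng.uniform(0.05, 1.0, n_pairs), 0.0)
        C = np.zeros((n_regions, n_regions))
        C[iu] = weights
        C += C.T
        n_comp, _ = connected_components(sparse.csr_matrix(C > 0),
                                         directed=False)
        if n_comp == 1:
            labels = [f"R{k:03d}" for k in range(n_regions)]
            return Connectome(labels=labels, matrix=C)
    raise RuntimeError("failed to draw a connected connectome; "
                       "increase density")


def _neighbor_smooth(x: np.ndarray, C: np.ndarray, rounds: int = 2) -> np.ndarray:
    """Average each region with its connectome neighbors (row-normalized)."""
    rowsum = C.sum(axis=1, keepdims=True)
    W = np.divide(C, rowsum, out=np.zeros_like(C), where=rowsum > 0)
    for _ in range(rounds):
        x = 0.5 * (x + W @ x)
    return x


def generate_cohort(connectome: Connectome, n_cu: int = 47, n_ad: int = 16,
                    theta_scale: float = 0.8, seed: int = 0,
                    ) -> tuple[list[SubjectRecord], GroundTruth]:
    """CU and AD pathology profiles plus the true theta triplets.

    CU subjects carry low, spatially unstructured SUVR near the reference
    value 1 and true thetas of exactly zero.  AD subjects carry elevated
    gamma-distributed regional loads smoothed by two rounds of
    connectome-neighbor averaging (emulating the spatially contiguous
    deposition PET shows) and true weights with magnitude in
    [0.3, 1] * theta_scale and random sign.
    """
    if n_cu < 1 or n_ad < 1:
        raise ValueError("need at least one subject per group")
    if theta_scale < 0:
        raise ValueError("theta_scale must be nonnegative")
    rng = np.random.default_rng(seed)
    C = connectome.matrix
    n = connectome.n_regions
    records: list[SubjectRecord] = []
    truth = GroundTruth(seed=seed)

    def draw_thetas(ad: bool) -> tuple[float, float, float]:
        if not ad or theta_scale == 0:
            return (0.0, 0.0, 0.0)
        mag = rng.uniform(0.3, 1.0, size=3) * theta_scale
        sign = rng.choice([-1.0, 1.0], size=3)
        return tuple(mag * sign)

    for i in range(n_cu + n_ad):
        ad = i >= n_cu
        sid = f"{'AD' if ad else 'CU'}{i - n_cu if ad else i:03d}"
        if ad:
            ab = 1.0 + _neighbor_smooth(rng.gamma(2.0, 0.35, size=n), C)
            tau = 1.0 + _neighbor_smooth(rng.gamma(2.0, 0.30, size=n), C)
        else:
            ab = 1.0 + rng.gamma(2.0, 0.05, size=n)
            tau = 1.0 + rng.gamma(2.0, 0.05, size=n)
        thetas = draw_thetas(ad)
        records.append(SubjectRecord(subject_id=sid, group="AD" if ad else "CU",
                                     abeta_suvr=ab, tau_suvr=tau,
                                     true_thetas=thetas))
        truth.true_thetas[sid] = thetas
    return records, truth


def generate_observed_falff(cohort: list[SubjectRecord], connectome: Connectome,
                            model_config: ModelConfig, noise_sd: float = 0.01,
                            seed: int = 0) -> list[SubjectRecord]:
    """Attach observed fALFF = forward-model fALFF(true thetas) + noise.

    Noise is additive iid Gaussian on the fALFF vector (sd ``noise_sd``),
    clipped to [0, 1].  Simulation failures are reported with the subject id.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    out = []
    for rec in cohort:
        if rec.true_thetas is None:
            raise ValueError(f"subject {rec.subject_id} has no true thetas")
        try:
            fal = forward_falff(ThetaTriplet(*rec.true_thetas),
                                subject_profile(rec), connectome, model_config)
        except Exception as exc:  # noqa: BLE001 - annotate with subject id
            raise RuntimeError(
                f"forward simulation failed for subject {rec.subject_id}: {exc}"
            ) from exc
        if noise_sd > 0:
            fal = fal + rng.normal(0.0, noise_sd, size=fal.size)
        rec.falff = np.clip(fal, 0.0, 1.0)
        out.append(rec)
    return out


def _pearson_for_spearman(rho_s: float) -> float:
    """Mixing coefficient giving expected Spearman rho_s for Gaussian pairs.

    Uses the bivariate-normal relation rho_s = (6/pi) * arcsin(rho_p / 2),
    inverted in closed form.
    """
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def generate_expression_matrix(n_genes: int, n_regions: int,
                               target_pattern: np.ndarray, n_planted: int,
                               planted_rho: float = 0.9, seed: int = 0,
                               ) -> tuple[np.ndarray, list[str], list[str]]:
    """Genes x regions expression with a planted spatially-correlated subset.

    Planted genes are standardized mixtures a*pattern + sqrt(1-a^2)*noise
    with ``a`` calibrated so the expected Spearman correlation with the
    target pattern is ~``planted_rho``; remaining genes are iid noise.
    Returns (matrix, gene_ids, planted_gene_ids).
    """
    if not 0 < planted_rho < 1:
        raise ValueError("planted_rho must lie in (0, 1)")
    if n_planted > n_genes:
        raise ValueError("n_planted cannot exceed n_genes")
    target_pattern = np.asarray(target_pattern, dtype=float)
    if target_pattern.size != n_regions:
        raise ValueError("target_pattern length must equal n_regions")
    rng = np.random.default_rng(seed)
    z = (target_pattern - target_pattern.mean()) / target_pattern.std()
    a = _pearson_for_spearman(planted_rho)
    X = rng.standard_normal((n_genes, n_regions))
    X[:n_planted] = a * z + np.sqrt(1.0 - a * a) * X[:n_planted]
    gene_ids = [f"G{g:05d}" for g in range(n_genes)]
    return X, gene_ids, gene_ids[:n_planted]


def _smooth_field(coords: np.ndarray, rng: np.random.Generator,
                  n_centers: int = 8, length: float = 40.0) -> np.ndarray:
    """Smooth random spatial field: a sum of Gaussian bumps over 3-D space."""
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    centers = rng.uniform(lo, hi, size=(n_centers, coords.shape[1]))
    amps = rng.normal(0.0, 1.0, size=n_centers)
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return (np.exp(-d2 / (2 * length ** 2)) * amps).sum(axis=1)


def generate_probe_table(n_genes: int, probes_per_gene: int, n_samples: int,
                         noise_per_probe: np.ndarray, seed: int = 0):
    """Probe intensities over 3-D tissue-sample coordinates.

    Each gene's probes measure the same smooth spatial field with
    probe-specific Gaussian noise; probe 0 of the noise vector's minimum is
    the planted best probe.  Returns (intensity DataFrame-like dict of
    arrays, coordinates, best_probe ids).
    """
    import pandas as pd

    if probes_per_gene < 2:
        raise ValueError("probes_per_gene must be at least 2")
    noise_per_probe = np.asarray(noise_per_probe, dtype=float)
    if noise_per_probe.size != probes_per_gene:
        raise ValueError("noise_per_probe length must equal probes_per_gene")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 100.0, size=(n_samples, 3))
    rows = []
    best: dict[str, str] = {}
    for g in range(n_genes):
        gene = f"G{g:05d}"
        fieldvals = _smooth_field(coords, rng)
        for p in range(probes_per_gene):
            probe = f"{gene}_P{p}"
            intensity = fieldvals + rng.normal(0.0, noise_per_probe[p],
                                               size=n_samples)
            rows.append((gene, probe, *intensity))
        best[gene] = f"{gene}_P{int(np.argmin(noise_per_probe))}"
    table = pd.DataFrame(
        rows, columns=["gene", "probe", *[f"S{s:04d}" for s in range(n_samples)]]
    )
    return table, coords, best


def generate_celltype_specificity(n_genes: int, n_celltypes: int,
                                  planted_set: list[str], planted_type: str,
                                  boost: float = 5.0, seed: int = 0):
    """Genes x cell-types specificity (rows sum to 1) with a planted type.

    Planted genes have their specificity for ``planted_type`` multiplied by
    ``boost`` before renormalization; boost=1 leaves the rows unchanged.
    Returns (matrix, gene_ids, celltype_ids).
    """
    if boost <= 0:
        raise ValueError("boost must be positive")
    gene_ids = [f"G{g:05d}" for g in range(n_genes)]
    celltype_ids = [f"CT{c:02d}" for c in range(n_celltypes)]
    missing = set(planted_set) - set(gene_ids)
    if missing:
        raise ValueError(f"planted genes not in universe: {sorted(missing)[:5]}")
    if planted_type not in celltype_ids:
        raise ValueError(f"unknown planted cell type {planted_type!r}")
    rng = np.random.default_rng(seed)
    expr = rng.gamma(2.0, 1.0, size=(n_genes, n_celltypes))
    col = celltype_ids.index(planted_type)
    planted_idx = [gene_ids.index(g) for g in planted_set]
    expr[planted_idx, col] *= boost
    spec = expr / expr.sum(axis=1, keepdims=True)
    return spec, gene_ids, celltype_ids


def generate_term_sets(gene_ids: list[str], planted_set: list[str],
                       n_terms: int = 30, term_size: int = 40,
                       seed: int = 0) -> dict[str, list[str]]:
    """Synthetic ontology for ORA: one term enriched for the planted genes.

    Term T000 contains the planted set padded with random genes; the
    remaining terms are random draws from the universe.
    """
    rng = np.random.default_rng(seed)
    universe = np.asarray(gene_ids)
    terms: dict[str, list[str]] = {}
    pad = max(0, term_size - len(planted_set))
    others = [g for g in gene_ids if g not in set(planted_set)]
    filler = list(rng.choice(others, size=min(pad, len(others)),
                             replace=False))
    terms["T000"] = list(planted_set) + filler
    for t in range(1, n_terms):
        size = min(term_size, universe.size)
        terms[f"T{t:03d}"] = list(rng.choice(universe, size=size,
                                             replace=False))
    return terms


def generate_drug_signature_library(gene_universe: list[str], n_drugs: int,
                                    planted_up: list[str], planted_down: list[str],
                                    query_set: list[str], strength: float = 0.9,
                                    seed: int = 0) -> dict[str, list[str]]:
    """Per-drug full gene rankings with planted up/down regulators.

    Rank 1 = most up-regulated.  For an up-planted drug, each query gene's
    sort key is shrunk toward 0 by ``strength`` (at strength=1 the query set
    occupies exactly the top ranks); down-planted drugs mirror this at the
    bottom; all other drugs are uniform random permutations.
    """
    if not 0 < strength <= 1:
        raise ValueError("strength must lie in (0, 1]")
    overlap = set(planted_up) & set(planted_down)
    if overlap:
        raise ValueError(f"drugs planted both up and down: {sorted(overlap)}")
    missing = set(query_set) - set(gene_universe)
    if missing:
        raise ValueError(f"query genes outside universe: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    universe = np.asarray(gene_universe)
    in_query = np.isin(universe, list(query_set))
    planted = set(planted_up) | set(planted_down)
    drug_ids = [f"D{d:03d}" for d in range(n_drugs)]
    # planted ids outside the default roster are appended to it
    drug_ids += sorted(planted - set(drug_ids))
    library: dict[str, list[str]] = {}
    for drug in drug_ids:
        u = rng.random(universe.size)
        if drug in planted_up:
            key = np.where(in_query, u * (1.0 - strength), u)
        elif drug in planted_down:
            key = np.where(in_query, 1.0 - u * (1.0 - strength), u)
        else:
            key = u
        order = np.argsort(key, kind="stable")
        library[drug] = list(universe[order])
    return library
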