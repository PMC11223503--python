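"""Normalized factor contributions and AD-vs-CU spatial alteration patterns.

Each pathological factor's regional perturbation of the excitatory threshold
is normalized by the total threshold shift, so the three contributions sum
to +/-1 per region.  Group contrasts are per-region two-sample Wilcoxon
rank-sum tests (AD vs CU), reported as signed standardized z statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .neurodynamics import PathologyProfile, ThetaTriplet

__all__ = [
    "SpatialPattern",
    "factor_contributions",
    "group_spatial_pattern",
    "FACTORS",
]

FACTORS = ("abeta", "tau", "interaction")


@dataclass
class SpatialPattern:
    """Per-region group-difference statistic for one pathological factor."""

    factor: str
    z: np.ndarray        # signed standardized rank-sum statistic, AD>CU positive
    p: np.ndarray        # two-sided p-values


def factor_contributions(thetas: ThetaTriplet, profile: PathologyProfile,
                         theta0: float):
    """Normalized per-region contribution of each factor to the threshold shift.

    For factor f with regional term t_f(k), the contribution is
    t_f(k) / |theta_k - theta0|; regions whose effective threshold equals
    the baseline get contribution 0 for every factor and are flagged.
    Regions with cancellation so extreme that the +/-1 conservation
    identity is not representable in double precision are likewise flagged
    as degenerate (contributions 0) — see :func:`_exact_closure`.

    Returns (contributions dict factor -> region vector, flagged bool vector).
    """
    terms = {
        "abeta": thetas.theta_abeta * profile.abeta,
        "tau": thetas.theta_tau * profile.tau,
        "interaction": thetas.theta_interaction * profile.abeta * profile.tau,
    }
    shift = terms["abeta"] + terms["tau"] + terms["interaction"]
    flagged = shift == 0.0
    denom = np.where(flagged, 1.0, np.abs(shift))
    c_ab = np.where(flagged, 0.0, terms["abeta"] / denom)
    c_tau = np.where(flagged, 0.0, terms["tau"] / denom)
    # closure: shares are rounded (within a few ulp) so the conservation
    # identity (c_ab + c_tau) + c_int == sign(shift) holds exactly
    sign = np.where(flagged, 0.0, np.sign(shift))
    c_ab, c_tau, c_int, solved = _exact_closure(c_ab, c_tau, sign)
    flagged = flagged | ~solved
    for c in (c_ab, c_tau, c_int):
        c[~solved] = 0.0
    contributions = {"abeta": c_ab, "tau": c_tau, "interaction": c_int}
    return contributions, flagged


def _neighbors(x0: float, width: int) -> list[float]:
    out, lo, hi = [x0], x0, x0
    for _ in range(width):
        lo = np.nextafter(lo, -np.inf)
        hi = np.nextafter(hi, np.inf)
        out += [lo, hi]
    return out


def _exact_closure(c_ab: np.ndarray, c_tau: np.ndarray, sign: np.ndarray):
    """Round the three shares so (c_ab + c_tau) + c_int == sign *exactly*.

    c_int is the closure sign - (c_ab + c_tau); when no rounding of it
    alone satisfies the identity (the addends live on different ulp grids),
    c_ab and c_tau are nudged by up to 2 ulp as well.  Adjustments this
    small are far below any scientific meaning but make the conservation
    identity a hard floating-point guarantee.
    """
    c_ab = c_ab.copy()
    c_tau = c_tau.copy()
    c_int = np.zeros_like(sign)
    solved = np.zeros(sign.size, dtype=bool)
    for k in range(sign.size):
        s = sign[k]
        if s == 0.0:
            solved[k] = True  # flagged region, all shares zero
            continue
        for a_try in _neighbors(c_ab[k], 3):
            for t_try in _neighbors(c_tau[k], 3):
                u = a_try + t_try
                for w in _neighbors(s - u, 6):
                    if (u + w) == s:
                        c_ab[k], c_tau[k], c_int[k] = a_try, t_try, w
                        solved[k] = True
                        break
                if solved[k]:
                    break
            if solved[k]:
                break
        # when every share sits on a ulp grid coarser than sign's, the
        # identity can be unrepresentable: the caller flags such regions
    return c_ab, c_tau, c_int, solved


def _ranksum_z(ad: np.ndarray, cu: np.ndarray) -> tuple[float, float]:
    """Signed standardized Wilcoxon rank-sum statistic (AD>CU positive).

    Normal approximation with average-rank tie correction and a 0.5
    continuity correction; returns (z, two-sided p).
    """
    ad = np.asarray(ad, float)
    cu = np.asarray(cu, float)
    n1, n2 = ad.size, cu.size
    pooled = np.concatenate([ad, cu])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()                      # rank sum of the AD group
    mu = n1 * (n1 + n2 + 1) / 2.0
    # tie-corrected variance: Var(W) = n1 n2 / 12 * [(n+1) - sum(t^3-t)/(n(n-1))]
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    var = n1 * n2 / 12.0 * ((n + 1) - (counts ** 3 - counts).sum() / (n * (n - 1.0)))
    if var <= 0:
        return 0.0, 1.0
    diff = w - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def group_spatial_pattern(contributions: np.ndarray, groups: np.ndarray,
                          factor: str, absolute: bool = False) -> SpatialPattern:
    """Per-region AD-vs-CU rank-sum contrast of factor contributions.

    ``contributions``: subjects x regions matrix of the factor's normalized
    contributions; ``groups``: array of 'CU'/'AD' labels per subject.  The
    returned z vector is signed (AD>CU positive) unless ``absolute``.
    """
    contributions = np.asarray(contributions, dtype=float)
    groups = np.asarray(groups)
    is_ad = groups == "AD"
    is_cu = groups == "CU"
    if is_ad.sum() < 2 or is_cu.sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    n_regions = contributions.shape[1]
    z = np.empty(n_regions)
    p = np.empty(n_regions)
    for k in range(n_regions):
        z[k], p[k] = _ranksum_z(contributions[is_ad, k], contributions[is_cu, k])
    if absolute:
        z = np.abs(z)
    return SpatialPattern(factor=factor, z=z, p=p)
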