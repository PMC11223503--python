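"""Subject-specific estimation of pathology weights on neuronal activity.

For each participant the three brain-wide weights (amyloid, tau and their
interaction) perturb the regional excitatory firing thresholds.  The weights
are estimated by derivative-free global search minimizing the correlation
distance (1 - Pearson r) between the subject's observed regional fALFF
vector and the fALFF of the simulated BOLD under candidate weights.

The forward simulation uses one stochastic realization with a fixed internal
noise seed so the objective is deterministic — a requirement of surrogate /
population-based optimizers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .falff import SpectralBands, compute_falff
from .hemodynamics import HemoParams, resample_to_tr, simulate_bold
from .io import Connectome, SubjectRecord
from .neurodynamics import (PathologyProfile, ThetaTriplet, WCParams,
                            effective_threshold, multisine_input,
                            simulate_network)

__all__ = [
    "ModelConfig",
    "ThetaEstimate",
    "normalize_suvr",
    "forward_falff",
    "fit_objective",
    "fit_subject",
    "NonIdentifiableWarning",
]


class NonIdentifiableWarning(UserWarning):
    """The pathology fields carry no information about the weights."""


@dataclass
class ModelConfig:
    """Forward-model configuration shared by generation and fitting.

    The Wilson–Cowan operating point here differs from the classical
    oscillatory defaults: a shallower excitatory sigmoid (a_e=0.85), slower
    population time constants (0.35 s) and lower external input (P=0.8)
    place every region at a stable, noise-free fixed point whose
    susceptibility corner frequency sweeps through the fALFF band as the
    effective threshold moves.  Combined with a deterministic seeded
    multisine input spanning the band, the simulated fALFF becomes a smooth
    monotone function of the regional thresholds — which is what makes the
    three pathology weights identifiable from a single spatial fALFF vector.

    ``duration``/``burn_in`` are simulation seconds (the retained window is
    their difference); ``tr`` the fMRI-like sampling interval the BOLD is
    decimated to; ``sim_seed`` fixes the multisine phases (and any state
    noise) so repeated forward evaluations are identical.
    """

    wc: WCParams = field(default_factory=lambda: WCParams(
        a_e=0.85, tau_e=0.35, tau_i=0.35, P=0.8))
    hemo: HemoParams = field(default_factory=lambda: HemoParams(epsilon_n=0.03))
    bands: SpectralBands = field(default_factory=SpectralBands)
    dt: float = 0.01
    duration: float = 595.0
    burn_in: float = 10.0
    tr: float = 0.681
    sim_seed: int = 1234
    falff_mode: str = "power"
    input_amplitude: float = 0.4
    input_band: tuple[float, float] = (0.01, 0.30)
    input_components: int = 24

    def small_test_profile(self) -> "ModelConfig":
        """Short-simulation variant (200 s retained) for fast runs."""
        return replace(self, duration=215.0, burn_in=15.0)


def normalize_suvr(raw: np.ndarray) -> np.ndarray:
    """Within-subject min–max normalization of a regional SUVR vector to [0, 1]."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("SUVR vector contains non-finite values")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        raise ValueError("degenerate SUVR vector: all values equal")
    return (raw - lo) / (hi - lo)


def subject_profile(subject: SubjectRecord) -> PathologyProfile:
    """Normalized pathology profile (per tracer, within subject).

    A tracer with a flat regional field carries no spatial information; its
    normalized field is set to zero and a non-identifiability warning raised.
    """
    fields = {}
    for name, raw in (("abeta", subject.abeta_suvr), ("tau", subject.tau_suvr)):
        try:
            fields[name] = normalize_suvr(raw)
        except ValueError:
            warnings.warn(
                f"flat {name} field for subject {subject.subject_id}: the "
                "corresponding theta weight is non-identifiable",
                NonIdentifiableWarning, stacklevel=2)
            fields[name] = np.zeros(np.asarray(raw).size)
    return PathologyProfile(**fields)


def forward_falff(thetas: ThetaTriplet, profile: PathologyProfile,
                  connectome: Connectome, config: ModelConfig) -> np.ndarray:
    """Simulated regional fALFF under candidate pathology weights."""
    thresholds = effective_threshold(config.wc, thetas, profile)
    ext = None
    if config.input_amplitude > 0:
        ext = multisine_input(config.duration, config.dt,
                              amplitude=config.input_amplitude,
                              freq_band=config.input_band,
                              n_components=config.input_components,
                              seed=config.sim_seed)
    sim = simulate_network(config.wc, connectome, thresholds,
                           duration=config.duration, dt=config.dt,
                           burn_in=config.burn_in, seed=config.sim_seed,
                           external_input=ext)
    bold = simulate_bold(sim.drive, config.hemo, dt=config.dt)
    bold_tr = resample_to_tr(bold, dt=config.dt, tr=config.tr)
    # the decimation factor is integer, so the achieved sampling interval
    # can differ slightly from the nominal TR
    actual_tr = round(config.tr / config.dt) * config.dt
    return compute_falff(bold_tr, sampling_interval=actual_tr,
                         bands=config.bands, mode=config.falff_mode)


def fit_objective(thetas: ThetaTriplet, subject: SubjectRecord,
                  connectome: Connectome, config: ModelConfig) -> float:
    """Correlation distance 1 - Pearson r(simulated fALFF, observed fALFF)."""
    if subject.falff is None:
        raise ValueError("subject has no observed fALFF")
    sim = forward_falff(thetas, subject_profile(subject), connectome, config)
    obs = np.asarray(subject.falff, dtype=float)
    if np.std(sim) == 0:
        warnings.warn("zero-variance simulated fALFF; distance set to 1",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    if np.std(obs) == 0:
        warnings.warn("zero-variance observed fALFF; distance set to 1",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    r = stats.pearsonr(sim, obs).statistic
    return float(1.0 - r)


@dataclass
class ThetaEstimate:
    """Result of one subject fit (differential-evolution search)."""

    thetas: ThetaTriplet
    objective_value: float
    n_evaluations: int
    bounds: tuple[tuple[float, float], ...]
    seed: int
    method: str = "differential_evolution"
    pathology_field_correlation: float = float("nan")


def fit_subject(subject: SubjectRecord, connectome: Connectome,
                config: ModelConfig,
                bounds: tuple[tuple[float, float], ...] | None = None,
                budget: int = 300, seed: int = 0) -> ThetaEstimate:
    """Estimate the subject's theta triplet by differential evolution.

    ``bounds`` default to [-theta0/2, +theta0/2] per weight, which keeps the
    effective thresholds in a dynamically sane range.  ``budget`` caps the
    number of objective evaluations (>= 30).  Deterministic under ``seed``.
    """
    if budget < 30:
        raise ValueError("budget must be at least 30")
    half = config.wc.theta0 / 2.0
    if bounds is None:
        bounds = ((-half, half),) * 3
    profile = subject_profile(subject)

    # identifiability diagnostic: how collinear are the two pathology fields
    if np.std(profile.abeta) > 0 and np.std(profile.tau) > 0:
        field_r = float(stats.pearsonr(profile.abeta, profile.tau).statistic)
    else:
        field_r = float("nan")
        warnings.warn("at least one pathology field is flat: the theta "
                      "weights are not jointly identifiable",
                      NonIdentifiableWarning, stacklevel=2)

    n_evals = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        return fit_objective(ThetaTriplet(*x), subject, connectome, config)

    # evaluation accounting: popsize*3 individuals per generation, one
    # initialization generation, no polishing; shrink the population for
    # small budgets so the cap is respected
    popsize = max(2, min(24, budget // 2) // 3)
    pop_evals = popsize * 3
    maxiter = max(1, budget // pop_evals - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = optimize.differential_evolution(
            objective, bounds=list(bounds), seed=seed, popsize=popsize,
            maxiter=maxiter, tol=0.0, polish=False, init="latinhypercube",
            updating="deferred",
        )
    if not np.isfinite(result.fun):
        raise RuntimeError("optimization produced no finite objective value")
    return ThetaEstimate(
        thetas=ThetaTriplet(*result.x),
        objective_value=float(result.fun),
        n_evaluations=n_evals,
        bounds=tuple(tuple(b) for b in bounds),
        seed=seed,
        pathology_field_correlation=field_r,
    )
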