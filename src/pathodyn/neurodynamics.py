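"""Wilson–Cowan neural masses on a structural connectome.

Each cortical region holds one excitatory and one inhibitory population with
sigmoidal input integration.  Amyloid-beta and tau burdens perturb the
excitatory firing threshold linearly:

    theta_k = theta0 + th_ab * Ab_k + th_tau * Tau_k + th_int * Ab_k * Tau_k

so pathology shifts regional excitability away from the healthy baseline
``theta0``.  Long-range coupling (the connectome) stimulates the excitatory
populations only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .io import Connectome

__all__ = [
    "WCParams",
    "PathologyProfile",
    "ThetaTriplet",
    "SimulationOutput",
    "SimulationDivergence",
    "effective_threshold",
    "wc_derivatives",
    "simulate_network",
]


@dataclass
class WCParams:
    """Wilson–Cowan constants (standard oscillatory-regime defaults).

    c1..c4 are the local E->E, I->E, E->I, I->I gains; a_e/a_i and
    theta0/theta_i are sigmoid slopes and thresholds; tau_e/tau_i are
    population time constants in seconds; g scales inter-regional coupling;
    P is the constant unspecific input to the excitatory populations;
    noise_sd, when positive, adds seeded state noise (Euler–Maruyama).
    """

    c1: float = 16.0
    c2: float = 12.0
    c3: float = 15.0
    c4: float = 3.0
    a_e: float = 1.3
    theta0: float = 4.0
    a_i: float = 2.0
    theta_i: float = 3.7
    tau_e: float = 0.008
    tau_i: float = 0.008
    g: float = 1.0
    P: float = 1.25
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("time constants must be positive")
        if self.a_e <= 0 or self.a_i <= 0:
            raise ValueError("sigmoid slopes must be positive")
        if self.g < 0:
            raise ValueError("global coupling g must be nonnegative")
        vals = [self.c1, self.c2, self.c3, self.c4, self.a_e, self.theta0,
                self.a_i, self.theta_i, self.tau_e, self.tau_i, self.g,
                self.P, self.noise_sd]
        if not np.all(np.isfinite(vals)):
            raise ValueError("all Wilson–Cowan parameters must be finite")


@dataclass
class PathologyProfile:
    """Regional amyloid-beta and tau burdens, min–max normalized to [0, 1]."""

    abeta: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.abeta = np.asarray(self.abeta, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.abeta.shape != self.tau.shape:
            raise ValueError("abeta and tau must have equal length")
        for name, v in (("abeta", self.abeta), ("tau", self.tau)):
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ThetaTriplet:
    """Brain-wide pathology weights on the excitatory threshold (signed)."""

    theta_abeta: float = 0.0
    theta_tau: float = 0.0
    theta_interaction: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.theta_abeta, self.theta_tau,
                                   self.theta_interaction])):
            raise ValueError("theta weights must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta_abeta, self.theta_tau,
                         self.theta_interaction])


@dataclass
class SimulationOutput:
    """Retained (post burn-in) trajectories on a uniform time grid."""

    time: np.ndarray          # seconds
    E: np.ndarray             # region x time excitatory firing
    I: np.ndarray             # region x time inhibitory firing
    drive: np.ndarray         # region x time total excitatory afferent input


class SimulationDivergence(RuntimeError):
    """Raised when the network state becomes non-finite."""


def effective_threshold(params: WCParams, thetas: ThetaTriplet,
                        profile: PathologyProfile) -> np.ndarray:
    """Regional excitatory thresholds under the linear pathology perturbation."""
    ab, tau = profile.abeta, profile.tau
    theta = (params.theta0
             + thetas.theta_abeta * ab
             + thetas.theta_tau * tau
             + thetas.theta_interaction * ab * tau)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite effective thresholds")
    return theta


def _sigmoid(x: np.ndarray, a: float, theta: np.ndarray | float) -> np.ndarray:
    # offset so that S(0) = 0, keeping rest a fixed point at P = 0
    return 1.0 / (1.0 + np.exp(-a * (x - theta))) - 1.0 / (1.0 + np.exp(a * theta))


def wc_derivatives(E: np.ndarray, I: np.ndarray, params: WCParams,
                   connectome: Connectome | np.ndarray,
                   thresholds: np.ndarray):
    """Time derivatives (dE, dI) and the afferent drive vector.

    The drive is the nonnegative proxy of total incoming action potentials
    feeding the hemodynamic stage: local excitatory input to both
    populations, long-range excitatory input and the external input P.
    """
    C = connectome.matrix if isinstance(connectome, Connectome) else np.asarray(connectome)
    E = np.asarray(E, dtype=float)
    I = np.asarray(I, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    n = C.shape[0]
    if E.shape != (n,) or I.shape != (n,) or thresholds.shape != (n,):
        raise ValueError("state/threshold length does not match the connectome")
    if not (np.all(np.isfinite(E)) and np.all(np.isfinite(I))):
        raise ValueError("non-finite state")
    p = params
    long_range = p.g * (C @ E)
    x_e = p.c1 * E - p.c2 * I + long_range + p.P
    x_i = p.c3 * E - p.c4 * I
    dE = (-E + (1.0 - E) * _sigmoid(x_e, p.a_e, thresholds)) / p.tau_e
    dI = (-I + (1.0 - I) * _sigmoid(x_i, p.a_i, p.theta_i)) / p.tau_i
    drive = p.c1 * E + p.c3 * E + long_range + p.P
    return dE, dI, drive


@njit(cache=True)
def _deriv_kernel(E, I, C, thr, c1, c2, c3, c4, a_e, a_i, theta_i,
                  tau_e, tau_i, g, P, dE, dI):  # pragma: no cover - jitted
    n = E.shape[0]
    for k in range(n):
        lr = 0.0
        for l in range(n):
            lr += C[k, l] * E[l]
        lr *= g
        x_e = c1 * E[k] - c2 * I[k] + lr + P
        x_i = c3 * E[k] - c4 * I[k]
        s_e = 1.0 / (1.0 + np.exp(-a_e * (x_e - thr[k]))) \
            - 1.0 / (1.0 + np.exp(a_e * thr[k]))
        s_i = 1.0 / (1.0 + np.exp(-a_i * (x_i - theta_i))) \
            - 1.0 / (1.0 + np.exp(a_i * theta_i))
        dE[k] = (-E[k] + (1.0 - E[k]) * s_e) / tau_e
        dI[k] = (-I[k] + (1.0 - I[k]) * s_i) / tau_i


@njit(cache=True)
def _integrate_kernel(C, thr, c1, c2, c3, c4, a_e, a_i, theta_i, tau_e, tau_i,
                      g, P, dt, n_burn, n_keep, E0, I0, noise,
                      use_noise, ext):  # pragma: no cover - jitted
    n = C.shape[0]
    E = E0.copy()
    I = I0.copy()
    E_out = np.empty((n, n_keep))
    I_out = np.empty((n, n_keep))
    drive_out = np.empty((n, n_keep))
    k1e = np.empty(n); k1i = np.empty(n)
    k2e = np.empty(n); k2i = np.empty(n)
    k3e = np.empty(n); k3i = np.empty(n)
    k4e = np.empty(n); k4i = np.empty(n)
    tE = np.empty(n); tI = np.empty(n)
    bad_step = -1
    n_total = n_burn + n_keep
    for step in range(n_total):
        Pt = P + ext[step]
        idx = step - n_burn
        if idx >= 0:
            for k in range(n):
                lr = 0.0
                for l in range(n):
                    lr += C[k, l] * E[l]
                E_out[k, idx] = E[k]
                I_out[k, idx] = I[k]
                drive_out[k, idx] = c1 * E[k] + c3 * E[k] + g * lr + Pt
        if idx == n_keep - 1:
            break
        if use_noise:
            # Euler–Maruyama step with additive state noise
            _deriv_kernel(E, I, C, thr, c1, c2, c3, c4, a_e, a_i, theta_i,
                          tau_e, tau_i, g, Pt, k1e, k1i)
            for k in range(n):
                E[k] += dt * k1e[k] + noise[step, k, 0]
                I[k] += dt * k1i[k] + noise[step, k, 1]
        else:
            # classical fixed-step RK4 (external input held over the step)
            _deriv_kernel(E, I, C, thr, c1, c2, c3, c4, a_e, a_i, theta_i,
                          tau_e, tau_i, g, Pt, k1e, k1i)
            for k in range(n):
                tE[k] = E[k] + 0.5 * dt * k1e[k]
                tI[k] = I[k] + 0.5 * dt * k1i[k]
            _deriv_kernel(tE, tI, C, thr, c1, c2, c3, c4, a_e, a_i, theta_i,
                          tau_e, tau_i, g, Pt, k2e, k2i)
            for k in range(n):
                tE[k] = E[k] + 0.5 * dt * k2e[k]
                tI[k] = I[k] + 0.5 * dt * k2i[k]
            _deriv_kernel(tE, tI, C, thr, c1, c2, c3, c4, a_e, a_i, theta_i,
                          tau_e, tau_i, g, Pt, k3e, k3i)
            for k in range(n):
                tE[k] = E[k] + dt * k3e[k]
                tI[k] = I[k] + dt * k3i[k]
            _deriv_kernel(tE, tI, C, thr, c1, c2, c3, c4, a_e, a_i, theta_i,
                          tau_e, tau_i, g, Pt, k4e, k4i)
            for k in range(n):
                E[k] += dt / 6.0 * (k1e[k] + 2.0 * k2e[k] + 2.0 * k3e[k] + k4e[k])
                I[k] += dt / 6.0 * (k1i[k] + 2.0 * k2i[k] + 2.0 * k3i[k] + k4i[k])
        ok = True
        for k in range(n):
            if not (np.isfinite(E[k]) and np.isfinite(I[k])):
                ok = False
        if not ok:
            bad_step = step + 1
            break
    return E_out, I_out, drive_out, bad_step


def multisine_input(duration: float, dt: float, amplitude: float,
                    freq_band: tuple[float, float] = (0.01, 0.30),
                    n_components: int = 24, seed: int = 0) -> np.ndarray:
    """Deterministic broadband external input: a seeded multisine.

    Sum of ``n_components`` equal-amplitude sinusoids with frequencies
    spanning ``freq_band`` and seeded uniform random phases, scaled to the
    requested RMS ``amplitude``.  Used as a spectrally rich, perfectly
    reproducible stimulus so the regional frequency response (and hence
    fALFF) varies smoothly with the excitatory threshold.
    """
    n_steps = int(round(duration / dt))
    t = np.arange(n_steps) * dt
    freqs = np.linspace(freq_band[0], freq_band[1], n_components)
    phases = np.random.default_rng(seed).uniform(0, 2 * np.pi, n_components)
    x = np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
    # RMS of the sum of n unit sinusoids with random phases is sqrt(n/2)
    return amplitude * x / np.sqrt(n_components / 2.0)


def simulate_network(params: WCParams, connectome: Connectome | np.ndarray,
                     thresholds: np.ndarray, duration: float, dt: float = 0.001,
                     burn_in: float = 10.0, seed: int | None = None,
                     initial_state: float | tuple[float, float] = 0.1,
                     external_input: np.ndarray | None = None) -> SimulationOutput:
    """Integrate the coupled Wilson–Cowan network.

    Deterministic runs (``params.noise_sd == 0``) use fixed-step RK4;
    stochastic runs take seeded Euler–Maruyama steps with additive state
    noise of amplitude ``noise_sd`` (per sqrt-second).  ``burn_in`` seconds
    are discarded before the retained grid starts.  ``external_input``, if
    given, is a time series added to the constant input P at every step
    (one value per integration step, burn-in included).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not duration > burn_in >= 0:
        raise ValueError("need duration > burn_in >= 0")
    C = connectome.matrix if isinstance(connectome, Connectome) else np.asarray(connectome, float)
    n = C.shape[0]
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape != (n,):
        raise ValueError("thresholds length does not match the connectome")

    n_burn = int(round(burn_in / dt))
    n_keep = int(round(duration / dt)) - n_burn
    if isinstance(initial_state, tuple):
        e0, i0 = initial_state
    else:
        e0 = i0 = float(initial_state)
    E0 = np.full(n, e0, dtype=float)
    I0 = np.full(n, i0, dtype=float)

    n_total = n_burn + n_keep
    use_noise = params.noise_sd > 0
    if use_noise:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((n_total, n, 2)) \
            * params.noise_sd * np.sqrt(dt)
    else:
        noise = np.zeros((1, n, 2))
    if external_input is None:
        ext = np.zeros(n_total)
    else:
        ext = np.asarray(external_input, dtype=float)
        if ext.shape != (n_total,):
            raise ValueError(
                f"external_input must have one value per step ({n_total})"
            )

    p = params
    E, I, drive, bad_step = _integrate_kernel(
        np.ascontiguousarray(C, dtype=float), thresholds,
        p.c1, p.c2, p.c3, p.c4, p.a_e, p.a_i, p.theta_i, p.tau_e, p.tau_i,
        p.g, p.P, dt, n_burn, n_keep, E0, I0, noise, use_noise, ext,
    )
    if bad_step >= 0:
        raise SimulationDivergence(
            f"network state became non-finite at step {bad_step} "
            f"(t = {bad_step * dt:.4f} s)"
        )
    time = (np.arange(n_keep) + n_burn) * dt
    return SimulationOutput(time=time, E=E, I=I, drive=drive)
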