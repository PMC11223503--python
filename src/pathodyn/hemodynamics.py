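"""Balloon-type hemodynamic forward model: neuronal drive -> BOLD.

Per region, the afferent drive (mean-centered, scaled by a neuronal efficacy
``epsilon_n``) induces a vasodilatory signal s, inflow f, venous volume v and
deoxyhemoglobin content q:

    ds/dt = eps_n * z - kappa * s - gamma * (f - 1)
    df/dt = s
    tau_h * dv/dt = f - v**(1/alpha)
    tau_h * dq/dt = f * (1 - (1 - rho_e)**(1/f)) / rho_e - v**(1/alpha) * q / v

    BOLD = V0 * (k1 * (1 - q) + k2 * (1 - q/v) + k3 * (1 - v))

Mean-centering makes sustained baseline firing map to zero BOLD deviation;
only fluctuations (what fALFF measures) survive the transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["HemoParams", "simulate_bold", "resample_to_tr", "HemoDivergence"]


@dataclass
class HemoParams:
    """Balloon-model constants (canonical literature defaults, all configurable)."""

    kappa: float = 0.65     # signal decay rate, 1/s
    gamma: float = 0.41     # flow-dependent elimination, 1/s
    tau_h: float = 0.98     # hemodynamic transit time, s
    alpha: float = 0.32     # vessel stiffness exponent
    rho_e: float = 0.34     # resting oxygen extraction fraction
    V0: float = 0.02        # resting venous volume fraction
    k1: float = field(default=None)  # type: ignore[assignment]
    k2: float = 2.0
    k3: float = field(default=None)  # type: ignore[assignment]
    epsilon_n: float = 1.0  # neuronal efficacy scaling of the drive

    def __post_init__(self) -> None:
        if self.k1 is None:
            self.k1 = 7.0 * self.rho_e
        if self.k3 is None:
            self.k3 = 2.0 * self.rho_e - 0.2
        for name in ("kappa", "gamma", "tau_h", "rho_e", "V0", "epsilon_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not np.all(np.isfinite([self.k1, self.k2, self.k3])):
            raise ValueError("BOLD weights must be finite")


class HemoDivergence(RuntimeError):
    """Raised when flow or volume become non-positive during integration."""


@njit(cache=True)
def _balloon_kernel(z, dt, kappa, gamma, tau_h, alpha, rho_e, V0,
                    k1, k2, k3):  # pragma: no cover - jitted
    n, T = z.shape
    bold = np.empty((n, T))
    inv_alpha = 1.0 / alpha
    bad_region = -1
    bad_step = -1
    for r in range(n):
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        for t in range(T):
            bold[r, t] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v)
                               + k3 * (1.0 - v))
            if t == T - 1:
                break
            # RK4 on the 4-state balloon system with z held at z[r, t]
            zt = z[r, t]
            s0, f0, v0, q0 = s, f, v, q
            ok = True
            ks = np.empty(4); kf = np.empty(4)
            kv = np.empty(4); kq = np.empty(4)
            for stage in range(4):
                if stage == 0:
                    ss, ff, vv, qq = s0, f0, v0, q0
                elif stage == 1:
                    ss = s0 + 0.5 * dt * ks[0]; ff = f0 + 0.5 * dt * kf[0]
                    vv = v0 + 0.5 * dt * kv[0]; qq = q0 + 0.5 * dt * kq[0]
                elif stage == 2:
                    ss = s0 + 0.5 * dt * ks[1]; ff = f0 + 0.5 * dt * kf[1]
                    vv = v0 + 0.5 * dt * kv[1]; qq = q0 + 0.5 * dt * kq[1]
                else:
                    ss = s0 + dt * ks[2]; ff = f0 + dt * kf[2]
                    vv = v0 + dt * kv[2]; qq = q0 + dt * kq[2]
                if ff <= 0.0 or vv <= 0.0:
                    ok = False
                    break
                vexp = vv ** inv_alpha
                ks[stage] = zt - kappa * ss - gamma * (ff - 1.0)
                kf[stage] = ss
                kv[stage] = (ff - vexp) / tau_h
                kq[stage] = (ff * (1.0 - (1.0 - rho_e) ** (1.0 / ff)) / rho_e
                             - vexp * qq / vv) / tau_h
            if not ok:
                bad_region = r
                bad_step = t
                break
            s = s0 + dt / 6.0 * (ks[0] + 2 * ks[1] + 2 * ks[2] + ks[3])
            f = f0 + dt / 6.0 * (kf[0] + 2 * kf[1] + 2 * kf[2] + kf[3])
            v = v0 + dt / 6.0 * (kv[0] + 2 * kv[1] + 2 * kv[2] + kv[3])
            q = q0 + dt / 6.0 * (kq[0] + 2 * kq[1] + 2 * kq[2] + kq[3])
            if f <= 0.0 or v <= 0.0:
                bad_region = r
                bad_step = t
                break
        if bad_region >= 0:
            break
    return bold, bad_region, bad_step


def simulate_bold(drive: np.ndarray, hemo: HemoParams | None = None,
                  dt: float = 0.001) -> np.ndarray:
    """BOLD signal (region x time) from the afferent drive (region x time).

    The drive is mean-centered per region before entering the balloon
    system, which starts from rest (s=0, f=v=q=1); regions are independent.
    """
    hemo = hemo or HemoParams()
    drive = np.atleast_2d(np.asarray(drive, dtype=float))
    if not np.all(np.isfinite(drive)):
        raise ValueError("drive contains non-finite values")
    if dt <= 0:
        raise ValueError("dt must be positive")
    z = hemo.epsilon_n * (drive - drive.mean(axis=1, keepdims=True))
    bold, bad_region, bad_step = _balloon_kernel(
        np.ascontiguousarray(z), dt, hemo.kappa, hemo.gamma, hemo.tau_h,
        hemo.alpha, hemo.rho_e, hemo.V0, hemo.k1, hemo.k2, hemo.k3,
    )
    if bad_region >= 0:
        raise HemoDivergence(
            f"flow/volume became non-positive in region {bad_region} "
            f"at step {bad_step}"
        )
    return bold


def resample_to_tr(bold: np.ndarray, dt: float, tr: float = 0.681) -> np.ndarray:
    """Decimate to an fMRI-like repetition time by block averaging.

    Consecutive blocks of ``round(tr/dt)`` samples are averaged (a simple
    anti-alias filter) before decimation; a trailing partial block is dropped.
    """
    bold = np.atleast_2d(np.asarray(bold, dtype=float))
    factor = int(round(tr / dt))
    if factor < 1:
        raise ValueError("tr must be >= dt")
    if factor == 1:
        return bold.copy()
    n, T = bold.shape
    n_blocks = T // factor
    if n_blocks < 1:
        raise ValueError("series shorter than one TR")
    return bold[:, : n_blocks * factor].reshape(n, n_blocks, factor).mean(axis=2)
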