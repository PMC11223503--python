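"""Fractional amplitude of low-frequency fluctuations (fALFF).

fALFF is the fraction of a regional BOLD signal's spectral power lying in
the 0.01–0.08 Hz band relative to the full 0–0.25 Hz band — a proxy for
spontaneous neuronal activity.  Series are linearly detrended and a raw
(boxcar) periodogram is used by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["SpectralBands", "compute_falff"]


@dataclass
class SpectralBands:
    """Low band [lo, hi) and full band (0, hi] in Hz."""

    low_band: tuple[float, float] = (0.01, 0.08)
    full_band: tuple[float, float] = (0.0, 0.25)

    def __post_init__(self) -> None:
        lo = self.low_band
        fu = self.full_band
        if not (fu[0] <= lo[0] < lo[1] <= fu[1]):
            raise ValueError("low band must be contained in the full band")


def compute_falff(series: np.ndarray, sampling_interval: float,
                  bands: SpectralBands | None = None, mode: str = "power",
                  welch: bool = False) -> np.ndarray:
    """Per-region fALFF in [0, 1] for a region x time array (or 1-D series).

    The linear trend is removed, the periodogram computed, and power summed
    over the half-open low band [0.01, 0.08) Hz divided by power over the
    DC-excluded full band (0, 0.25] Hz.  ``mode='amplitude'`` sums the
    square roots of the power instead (the classical fALFF variant).
    """
    bands = bands or SpectralBands()
    x = np.atleast_2d(np.asarray(series, dtype=float))
    one_d = np.asarray(series).ndim == 1
    if x.shape[1] < 64:
        raise ValueError("need at least 64 time points")
    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be positive")
    fs = 1.0 / sampling_interval
    if bands.full_band[1] > fs / 2 + 1e-12:
        raise ValueError("full band exceeds the Nyquist frequency")
    if mode not in ("power", "amplitude"):
        raise ValueError("mode must be 'power' or 'amplitude'")

    x = signal.detrend(x, axis=1, type="linear")
    if welch:
        freqs, pxx = signal.welch(x, fs=fs, axis=1,
                                  nperseg=min(x.shape[1], 256))
    else:
        freqs, pxx = signal.periodogram(x, fs=fs, window="boxcar",
                                        detrend=False, axis=1)
    if mode == "amplitude":
        pxx = np.sqrt(pxx)

    lo, hi = bands.low_band
    low_mask = (freqs >= lo) & (freqs < hi)
    full_mask = (freqs > bands.full_band[0]) & (freqs <= bands.full_band[1])
    num = pxx[:, low_mask].sum(axis=1)
    den = pxx[:, full_mask].sum(axis=1)

    out = np.zeros(x.shape[0])
    nonzero = den > 0
    out[nonzero] = num[nonzero] / den[nonzero]
    if not np.all(nonzero):
        warnings.warn("zero full-band power; fALFF set to 0", RuntimeWarning,
                      stacklevel=2)
    out = np.clip(out, 0.0, 1.0)
    return out[0] if one_d else out
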