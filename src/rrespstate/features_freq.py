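"""Spectral features of the windowed RR signal.

Two features per window: the highest band power (``P_max``) over the
0.05-0.5 Hz range at 0.05 Hz resolution, and the frequency of that band
(``f_Pmax``).  A 20 s window makes 0.05 Hz the fundamental, so exactly one
period of the slowest component fits — the low-frequency end of the band is
resolved at the limit of what the window allows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import EvenSeries

__all__ = ["FreqFeatures", "extract_freq", "band_powers"]

FREQ_FEATURE_NAMES = ("P_max", "f_Pmax")


@dataclass(frozen=True)
class FreqFeatures:
    P_max: float  # power in the strongest band (s^2, per-bin)
    f_Pmax: float  # centre frequency of that band (Hz)

    def as_dict(self) -> dict[str, float]:
        return {"P_max": self.P_max, "f_Pmax": self.f_Pmax}


def band_powers(
    rr_grid: EvenSeries,
    f_lo: float = 0.05,
    f_hi: float = 0.5,
    df: float = 0.05,
    estimator: str = "periodogram",
    beat_times: np.ndarray | None = None,
    rr: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Power aggregated into ``df``-wide bands centred at f_lo, f_lo+df, ... f_hi.

    The default estimator is the periodogram of the mean-detrended, evenly
    resampled window with 'spectrum' scaling, so the summed band powers are
    bounded by the window variance (a Parseval-style sanity bound).  The
    ``lombscargle`` estimator works on the raw beats instead and avoids the
    interpolation step.
    """
    centres = np.round(np.arange(f_lo, f_hi + df / 2, df), 10)
    if rr_grid.values.size * rr_grid.dt < 1.0 / f_lo - rr_grid.dt / 2:
        raise ValueError(
            f"window spans {rr_grid.values.size * rr_grid.dt:.1f} s, too short to "
            f"resolve {f_lo:g} Hz (needs {1.0 / f_lo:.0f} s)"
        )
    if estimator == "periodogram":
        x = rr_grid.values - np.mean(rr_grid.values)
        freqs, pxx = signal.periodogram(
            x, fs=rr_grid.fs, detrend=False, scaling="spectrum"
        )
    elif estimator == "lombscargle":
        if beat_times is None or rr is None:
            raise ValueError("lombscargle estimator needs the raw beats")
        x = rr - np.mean(rr)
        freqs = centres
        pxx = signal.lombscargle(
            beat_times, x, 2 * np.pi * freqs, normalize=False
        ) * 2.0 / len(x)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    powers = np.zeros(centres.size)
    for k, fc in enumerate(centres):
        in_band = (freqs > fc - df / 2) & (freqs <= fc + df / 2)
        powers[k] = float(np.sum(pxx[in_band]))
    return centres, powers


def extract_freq(
    rr_grid: EvenSeries,
    f_lo: float = 0.05,
    f_hi: float = 0.5,
    df: float = 0.05,
    estimator: str = "periodogram",
    beat_times: np.ndarray | None = None,
    rr: np.ndarray | None = None,
) -> FreqFeatures:
    """Strongest spectral band of one RR window; ties go to the lowest band."""
    centres, powers = band_powers(
        rr_grid, f_lo, f_hi, df, estimator, beat_times, rr
    )
    # numerically-zero spectra (constant windows) tie-break to the lowest band
    powers = np.where(powers < 1e-30, 0.0, powers)
    best = int(np.argmax(powers))  # argmax returns the first (lowest) maximum
    return FreqFeatures(P_max=float(powers[best]), f_Pmax=float(centres[best]))
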