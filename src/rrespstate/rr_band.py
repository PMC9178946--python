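"""The RR_Band feature: a subject-adaptive 3-level discretization of mean RR.

The span between the absolute minimum and maximum of a subject's whole
(filtered) RR signal is divided into three equal bands.  A window's mean RR
then falls into band 1 (top third — longest intervals, slowest heart:
relaxation), band 2 (middle third: rest/basal) or band 3 (bottom third —
shortest intervals, fastest heart: stress).  Because the boundaries are
derived from the subject's own extrema, the feature adapts to individual
physiology: any increasing affine rescaling of the signal leaves every
window's band unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import DegenerateSignalError

__all__ = ["BandBoundaries", "compute_boundaries", "assign_band"]

#: band code -> mental-state reading of the band
BAND_MEANING = {1: "relaxation", 2: "rest", 3: "stress"}


@dataclass(frozen=True)
class BandBoundaries:
    rr_abs_min: float
    rr_abs_max: float

    def __post_init__(self) -> None:
        if not self.rr_abs_max > self.rr_abs_min:
            raise DegenerateSignalError(
                "band boundaries undefined for a constant RR signal"
            )

    @property
    def b_low(self) -> float:
        return self.rr_abs_min + (self.rr_abs_max - self.rr_abs_min) / 3.0

    @property
    def b_high(self) -> float:
        return self.rr_abs_min + 2.0 * (self.rr_abs_max - self.rr_abs_min) / 3.0


def compute_boundaries(rr_signal: Sequence[float]) -> BandBoundaries:
    """Equal-thirds cut points from the whole-register RR extrema."""
    rr = np.asarray(rr_signal, dtype=float)
    return BandBoundaries(float(np.min(rr)), float(np.max(rr)))


def assign_band(rr_mean: float, bounds: BandBoundaries) -> int:
    """Map a window's mean RR to its band code (1 relax / 2 rest / 3 stress).

    Band 3 is ``[min, b_low)``, band 2 ``[b_low, b_high)`` and band 1
    ``[b_high, max]`` — a boundary value goes to the calmer band.  Values
    outside the register span (possible only when boundaries come from a
    different signal than the means) clamp to the nearest band.
    """
    if rr_mean >= bounds.b_high:
        return 1
    if rr_mean >= bounds.b_low:
        return 2
    return 3
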