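"""Poincaré (lag-1 return map) analysis of an RR beat-interval sequence.

The Poincaré plot scatters each inter-beat interval against its predecessor:
point i is (RR_i, RR_{i+1}).  A healthy sequence draws an ellipse whose minor
axis captures short-term (beat-to-beat, mostly parasympathetic) variability
and whose major axis captures long-term variability.

Nine descriptors are derived per sequence:

* ``SD1c`` / ``SD2c`` — root-mean-square point distances to the centroid along
  the two ellipse axes (semi-minor / semi-major lengths).
* ``SD1b`` — like SD1c but measured from the identity bisector y = x rather
  than the centroid axis; converges to SD1c as the number of points grows.
* ``SD1e`` / ``SD1d`` — the split of SD1b into contributions from points above
  the bisector (decelerations: the heart slowing down) and below it
  (accelerations).  Both partial sums keep SD1b's 1/(2n) normalization over
  *all* n points, which makes SD1e² + SD1d² = SD1b² an exact identity.
* ``n_e`` / ``n_d`` — the deceleration / acceleration point counts.
* ``Ce`` / ``Cd`` — fractional contributions SD1e²/SD1b² and SD1d²/SD1b²,
  summing to 1 whenever SD1b > 0 (NaN for a constant sequence, where the
  ratio is undefined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PoincarePlot", "PoincareDescriptors", "build_plot", "descriptors"]

POINCARE_FEATURE_NAMES = (
    "SD1c", "SD2c", "SD1b", "SD1e", "SD1d", "n_e", "n_d", "Ce", "Cd",
)


@dataclass(frozen=True)
class PoincarePlot:
    x: np.ndarray  # RR_1 .. RR_{n-1}
    y: np.ndarray  # RR_2 .. RR_n

    @property
    def n_points(self) -> int:
        return self.x.size

    @property
    def centroid(self) -> tuple[float, float]:
        return float(np.mean(self.x)), float(np.mean(self.y))

    @property
    def d1(self) -> np.ndarray:
        """Per-point distance to the line through the centroid along y = x."""
        xc, yc = self.centroid
        return np.abs((self.x - xc) - (self.y - yc)) / np.sqrt(2.0)

    @property
    def d2(self) -> np.ndarray:
        """Per-point distance along the perpendicular (major) axis."""
        xc, yc = self.centroid
        return np.abs((self.x - xc) + (self.y - yc)) / np.sqrt(2.0)


@dataclass(frozen=True)
class PoincareDescriptors:
    SD1c: float
    SD2c: float
    SD1b: float
    SD1e: float
    SD1d: float
    n_e: int
    n_d: int
    Ce: float  # NaN when SD1b == 0
    Cd: float  # NaN when SD1b == 0

    def as_dict(self) -> dict[str, float]:
        return {
            "SD1c": self.SD1c,
            "SD2c": self.SD2c,
            "SD1b": self.SD1b,
            "SD1e": self.SD1e,
            "SD1d": self.SD1d,
            "n_e": float(self.n_e),
            "n_d": float(self.n_d),
            "Ce": self.Ce,
            "Cd": self.Cd,
        }


def build_plot(rr: np.ndarray) -> PoincarePlot:
    """Lag-1 embedding of a beat-interval sequence (needs >= 2 beats)."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError(f"Poincaré plot needs >= 2 beats, got {rr.size}")
    return PoincarePlot(x=rr[:-1].copy(), y=rr[1:].copy())


def descriptors(plot: PoincarePlot) -> PoincareDescriptors:
    """The nine ellipse descriptors of one Poincaré plot.

    Points exactly on the bisector contribute zero to every SD1 sum and are
    counted in neither ``n_e`` nor ``n_d``.
    """
    n = plot.n_points
    if n < 1:
        raise ValueError("descriptors need a plot with >= 1 point")
    sd1c = float(np.sqrt(np.mean(plot.d1**2)))
    sd2c = float(np.sqrt(np.mean(plot.d2**2)))

    diff = plot.x - plot.y
    sd1b_sq = float(np.sum(diff**2) / (2 * n))
    above = plot.y > plot.x  # decelerations: the next interval is longer
    below = plot.y < plot.x
    sd1e_sq = float(np.sum(diff[above] ** 2) / (2 * n))
    sd1d_sq = float(np.sum(diff[below] ** 2) / (2 * n))

    if sd1b_sq > 0:
        ce, cd = sd1e_sq / sd1b_sq, sd1d_sq / sd1b_sq
    else:
        ce = cd = float("nan")
    return PoincareDescriptors(
        SD1c=sd1c,
        SD2c=sd2c,
        SD1b=float(np.sqrt(sd1b_sq)),
        SD1e=float(np.sqrt(sd1e_sq)),
        SD1d=float(np.sqrt(sd1d_sq)),
        n_e=int(np.count_nonzero(above)),
        n_d=int(np.count_nonzero(below)),
        Ce=ce,
        Cd=cd,
    )
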