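"""Per-window time-domain features and their four-window rolling statistics.

Thirteen features are computed per window: extrema, range and mean of the
windowed RR signal (raw and min-max normalized against the whole register),
least-squares slopes of RR and EDA, and three "surface" features measuring
how far each signal strays from a straight line.  The surface between a
signal and a regression line is taken as the time-integral of the absolute
residual (a signed surface would cancel to ~0 around the signal's own
regression); when aroused, the higher-frequency content of both signals grows
and these surfaces grow with it.

Each feature then gets a trailing-four-window mean and sample standard
deviation, acting as a short-term memory of recent physiological events:
13 + 26 = 39 time-domain values per window.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .preprocess import EvenSeries, NormalizationParams, normalize_minmax
from .windows import AnalysisWindow

__all__ = [
    "TIME_FEATURE_NAMES",
    "TimeFeatures",
    "extract_time",
    "rolling_stats",
]

#: canonical column order of the 13 per-window time-domain features
TIME_FEATURE_NAMES = (
    "RR_Max",
    "RR_Min",
    "RR_Range",
    "RR_Mean",
    "RR_Norm_Max",
    "RR_Norm_Min",
    "RR_Norm_Range",
    "RR_Norm_Mean",
    "RR_Slope",
    "EDA_Slope",
    "EDA/EDA_SurfDiff",
    "EDA/RR_SurfDiff",
    "RR/RR_SurfDiff",
)

# dataclass field names cannot contain '/', so the three surface features use
# underscores internally and map back to the slashed table names on export
_FIELD_TO_NAME = {
    "RR_Max": "RR_Max",
    "RR_Min": "RR_Min",
    "RR_Range": "RR_Range",
    "RR_Mean": "RR_Mean",
    "RR_Norm_Max": "RR_Norm_Max",
    "RR_Norm_Min": "RR_Norm_Min",
    "RR_Norm_Range": "RR_Norm_Range",
    "RR_Norm_Mean": "RR_Norm_Mean",
    "RR_Slope": "RR_Slope",
    "EDA_Slope": "EDA_Slope",
    "EDA_EDA_SurfDiff": "EDA/EDA_SurfDiff",
    "EDA_RR_SurfDiff": "EDA/RR_SurfDiff",
    "RR_RR_SurfDiff": "RR/RR_SurfDiff",
}


@dataclass(frozen=True)
class TimeFeatures:
    RR_Max: float
    RR_Min: float
    RR_Range: float
    RR_Mean: float
    RR_Norm_Max: float
    RR_Norm_Min: float
    RR_Norm_Range: float
    RR_Norm_Mean: float
    RR_Slope: float
    EDA_Slope: float
    EDA_EDA_SurfDiff: float
    EDA_RR_SurfDiff: float
    RR_RR_SurfDiff: float

    def as_dict(self) -> dict[str, float]:
        """Feature values keyed by their canonical (slashed) table names."""
        return {
            _FIELD_TO_NAME[f.name]: getattr(self, f.name) for f in fields(self)
        }


def ols_line(series: EvenSeries) -> tuple[float, float]:
    """Ordinary-least-squares (slope, intercept) of value vs time."""
    if series.values.size < 2:
        raise ValueError("regression needs at least 2 samples")
    slope, intercept = np.polyfit(series.times, series.values, 1)
    return float(slope), float(intercept)


def surface_diff(series: EvenSeries, slope: float, intercept: float) -> float:
    """Trapezoidal integral of |series - line| over the series' time span."""
    residual = np.abs(series.values - (slope * series.times + intercept))
    return float(np.trapezoid(residual, series.times))


def extract_time(
    window: AnalysisWindow,
    norm: NormalizationParams,
    standardize_mixed: bool = False,
) -> TimeFeatures:
    """Compute the 13 time-domain features of one analysis window.

    The ``_Norm`` variants apply the whole-register min-max normalization, so
    they place the window inside the subject's own RR span.  The mixed-signal
    surface ``EDA/RR_SurfDiff`` evaluates the EDA regression line on the RR
    grid (co-sampling) and integrates the absolute RR residual around it; its
    units mix seconds and microsiemens, so ``standardize_mixed=True`` offers a
    variant where both window signals are z-scored first.
    """
    rr = window.rr_grid
    eda = window.eda_grid
    if rr.values.size < 2 or eda.values.size < 2:
        raise ValueError("degenerate window: needs >= 2 samples of each signal")

    rr_max = float(np.max(rr.values))
    rr_min = float(np.min(rr.values))
    rr_mean = float(np.mean(rr.values))
    rr_norm = normalize_minmax(rr.values, norm)

    rr_slope, rr_icpt = ols_line(rr)
    eda_slope, eda_icpt = ols_line(eda)

    # co-sample: EDA's regression line evaluated on the RR grid
    if standardize_mixed:
        rr_sd = float(np.std(rr.values)) or 1.0
        eda_sd = float(np.std(eda.values)) or 1.0
        rr_z = EvenSeries(rr.t0, rr.dt, (rr.values - rr_mean) / rr_sd)
        eda_z = EvenSeries(
            eda.t0, eda.dt, (eda.values - float(np.mean(eda.values))) / eda_sd
        )
        z_slope, z_icpt = ols_line(eda_z)
        eda_rr_surf = surface_diff(rr_z, z_slope, z_icpt)
    else:
        eda_rr_surf = surface_diff(rr, eda_slope, eda_icpt)

    return TimeFeatures(
        RR_Max=rr_max,
        RR_Min=rr_min,
        RR_Range=rr_max - rr_min,
        RR_Mean=rr_mean,
        RR_Norm_Max=float(np.max(rr_norm)),
        RR_Norm_Min=float(np.min(rr_norm)),
        RR_Norm_Range=float(np.max(rr_norm) - np.min(rr_norm)),
        RR_Norm_Mean=float(np.mean(rr_norm)),
        RR_Slope=rr_slope,
        EDA_Slope=eda_slope,
        EDA_EDA_SurfDiff=surface_diff(eda, eda_slope, eda_icpt),
        EDA_RR_SurfDiff=eda_rr_surf,
        RR_RR_SurfDiff=surface_diff(rr, rr_slope, rr_icpt),
    )


def rolling_stats(
    features: list[TimeFeatures], span: int = 4
) -> list[dict[str, float]]:
    """Trailing mean and sample standard deviation of each feature.

    Window ``i`` aggregates the feature values of windows ``max(0, i-span+1)
    .. i`` — the span expands until ``span`` windows are available.  The
    standard deviation uses the sample (n-1) convention and is defined as 0
    when only one value is available.  Output keys append ``_Avg`` / ``_Std``
    to the canonical feature names (26 values per window).
    """
    mat = np.array(
        [[f for f in tf.as_dict().values()] for tf in features], dtype=float
    )
    names = list(features[0].as_dict().keys()) if features else []
    out: list[dict[str, float]] = []
    for i in range(mat.shape[0]):
        chunk = mat[max(0, i - span + 1) : i + 1]
        avg = chunk.mean(axis=0)
        std = chunk.std(axis=0, ddof=1) if chunk.shape[0] > 1 else np.zeros(len(names))
        row: dict[str, float] = {}
        for j, name in enumerate(names):
            row[f"{name}_Avg"] = float(avg[j])
            row[f"{name}_Std"] = float(std[j])
        out.append(row)
    return out
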