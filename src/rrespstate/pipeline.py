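"""End-to-end feature pipeline: register in, labeled feature table out.

Chains preprocessing (2 Hz zero-phase low-pass on both signals, 4 Hz tachogram
resampling), 20 s / 15 s-stride windowing, the 13 time-domain features with
their 26 rolling statistics, the 2 spectral features, the 9 Poincaré
descriptors and the RR_Band code — 51 columns per labeled window plus the
class label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features_freq import FREQ_FEATURE_NAMES, extract_freq
from .features_time import TIME_FEATURE_NAMES, extract_time, rolling_stats
from .poincare import POINCARE_FEATURE_NAMES, build_plot, descriptors
from .preprocess import (
    EvenSeries,
    NormalizationParams,
    PhysioRegister,
    lowpass_filter,
    resample_rr,
)
from .rr_band import assign_band, compute_boundaries
from .windows import WindowSet, assign_labels, segment

__all__ = ["PipelineConfig", "FEATURE_COLUMNS", "preprocess_register", "build_feature_table"]


@dataclass
class PipelineConfig:
    """Tunable knobs of the feature pipeline (defaults match the method)."""

    filter_cutoff_hz: float = 2.0
    filter_order: int = 4
    rr_grid_hz: float = 4.0
    normalization_mode: str = "whole_register"  # or "causal"
    window_s: float = 20.0
    overlap_s: float = 5.0
    label_min_coverage: float = 0.5
    spectrum_estimator: str = "periodogram"  # or "lombscargle"
    spectrum_f_lo: float = 0.05
    spectrum_f_hi: float = 0.5
    spectrum_df: float = 0.05
    surfdiff_standardize: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build from a (possibly nested) mapping, e.g. parsed YAML.

        Nested keys follow the config-file dialect: ``filter.cutoff_hz``,
        ``rr.grid_hz``, ``normalization.mode``, ``spectrum.estimator`` ...
        """
        flat: dict[str, object] = {}
        for key, value in d.items():
            if isinstance(value, dict):
                for sub, v in value.items():
                    flat[f"{key}_{sub}".replace(".", "_")] = v
            else:
                flat[key.replace(".", "_")] = value
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)  # type: ignore[arg-type]


ROLLING_FEATURE_NAMES = tuple(
    f"{name}{suffix}" for name in TIME_FEATURE_NAMES for suffix in ("_Avg", "_Std")
)

#: canonical order of the 51 feature columns of a full table
FEATURE_COLUMNS = (
    TIME_FEATURE_NAMES + ROLLING_FEATURE_NAMES + FREQ_FEATURE_NAMES
    + POINCARE_FEATURE_NAMES + ("RR_Band",)
)


def _even_eda(register: PhysioRegister) -> EvenSeries:
    """EDA as an even series; interpolates only if the raw grid is uneven."""
    t = register.eda_t
    if t.size < 2:
        raise ValueError("EDA series too short")
    dts = np.diff(t)
    dt = float(np.median(dts))
    if np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
        return EvenSeries(float(t[0]), dt, register.eda)
    n = int(np.floor((t[-1] - t[0]) / dt)) + 1
    grid = t[0] + dt * np.arange(n)
    return EvenSeries(float(t[0]), dt, np.interp(grid, t, register.eda))


def preprocess_register(
    register: PhysioRegister, config: PipelineConfig | None = None
) -> tuple[EvenSeries, EvenSeries]:
    """Filtered even-grid (RR, EDA) signals of a register.

    The tachogram is interpolated at twice the analysis rate so the 2 Hz
    filter has headroom below Nyquist, filtered, then decimated back to the
    analysis grid (default 4 Hz).  EDA is filtered on its own sampling grid.
    """
    config = config or PipelineConfig()
    rr_fine = resample_rr(
        register.beat_times, register.rr, grid_hz=2 * config.rr_grid_hz
    )
    rr_filt = lowpass_filter(rr_fine, config.filter_cutoff_hz, config.filter_order)
    rr_grid = EvenSeries(rr_filt.t0, 2 * rr_filt.dt, rr_filt.values[::2])
    eda_grid = _even_eda(register)
    eda_filt = lowpass_filter(eda_grid, config.filter_cutoff_hz, config.filter_order)
    return rr_grid, eda_filt


def segment_register(
    register: PhysioRegister, config: PipelineConfig | None = None
) -> tuple[WindowSet, EvenSeries]:
    """Preprocess and window a register; returns (windows, filtered RR grid)."""
    config = config or PipelineConfig()
    rr_grid, eda_grid = preprocess_register(register, config)
    window_set = segment(
        register, rr_grid, eda_grid, config.window_s, config.overlap_s
    )
    window_set.register_norm = NormalizationParams.from_signal(rr_grid.values)
    if register.annotations:
        assign_labels(window_set, register.annotations, config.label_min_coverage)
    return window_set, rr_grid


def build_feature_table(
    register: PhysioRegister,
    config: PipelineConfig | None = None,
    keep_unlabeled: bool = False,
) -> pd.DataFrame:
    """One row of 51 features (+ ``label``) per labeled analysis window.

    Rolling statistics are computed over the full consecutive window sequence
    (labeled or not) before unlabeled rows are dropped, so the four-window
    memory never skips a window.
    """
    config = config or PipelineConfig()
    window_set, rr_grid = segment_register(register, config)
    norm_whole = window_set.register_norm
    bounds = compute_boundaries(rr_grid.values)

    time_feats = []
    for w in window_set:
        if config.normalization_mode == "causal":
            seen = rr_grid.slice(rr_grid.t0, w.t_end).values
            lo, hi = float(np.min(seen)), float(np.max(seen))
            norm = NormalizationParams(lo, hi) if hi > lo else norm_whole
        else:
            norm = norm_whole
        time_feats.append(extract_time(w, norm, config.surfdiff_standardize))
    rolling = rolling_stats(time_feats)

    rows = []
    for w, tf, roll in zip(window_set, time_feats, rolling):
        row: dict[str, float | str | None] = {}
        row.update(tf.as_dict())
        row.update(roll)
        row.update(
            extract_freq(
                w.rr_grid,
                config.spectrum_f_lo,
                config.spectrum_f_hi,
                config.spectrum_df,
                config.spectrum_estimator,
                beat_times=w.beat_times
                if config.spectrum_estimator == "lombscargle"
                else None,
                rr=w.rr_beats if config.spectrum_estimator == "lombscargle" else None,
            ).as_dict()
        )
        row.update(descriptors(build_plot(w.rr_beats)).as_dict())
        row["RR_Band"] = assign_band(tf.RR_Mean, bounds)
        row["label"] = w.label
        rows.append(row)

    table = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS) + ["label"])
    if not keep_unlabeled:
        table = table.dropna(subset=["label"]).reset_index(drop=True)
    return table
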