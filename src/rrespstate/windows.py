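"""Sliding-window segmentation of a register into labeled analysis windows.

Each analysis window is a 20 s slice of both signals; consecutive windows
overlap by 5 s (stride 15 s).  The 20 s length matches the slowest dynamics
of interest: the RR spectrum is bounded at 0.05 Hz (one 20 s period) and the
EDA tonic component's upper cutoff sits around the same frequency, so one
window captures tonic drift while keeping several phasic responses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import EvenSeries, NormalizationParams, PhysioRegister

__all__ = ["AnalysisWindow", "WindowSet", "segment", "assign_labels"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisWindow:
    """One half-open [t_start, t_end) slice of a register, carrying both signals."""

    index: int
    t_start: float
    t_end: float
    rr_grid: EvenSeries
    rr_beats: np.ndarray  # raw inter-beat intervals of beats inside the window
    beat_times: np.ndarray  # timestamps of those beats
    eda_grid: EvenSeries
    label: str | None = None

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class WindowSet:
    windows: list[AnalysisWindow] = field(default_factory=list)
    register_norm: NormalizationParams | None = None

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i: int) -> AnalysisWindow:
        return self.windows[i]


def window_starts(duration: float, window_s: float, overlap_s: float) -> np.ndarray:
    """Start offsets of all full windows fitting in ``duration`` seconds."""
    stride = window_s - overlap_s
    n = int(np.floor((duration - window_s) / stride + 1e-9)) + 1
    return stride * np.arange(n)


def segment(
    register: PhysioRegister,
    rr_grid: EvenSeries,
    eda_grid: EvenSeries,
    window_s: float = 20.0,
    overlap_s: float = 5.0,
) -> WindowSet:
    """Chop a register into overlapping analysis windows.

    Windows are half-open ``[t_start, t_end)`` on a time axis anchored at the
    first instant both (gridded) signals cover.  A trailing partial window is
    discarded, never padded.  Windows holding fewer than 2 beats cannot
    support beat-level descriptors and are dropped with a warning.

    Parameters
    ----------
    register
        The raw register; supplies the beat sequence.
    rr_grid, eda_grid
        The preprocessed (filtered, evenly resampled) signals to slice.
    """
    if overlap_s >= window_s:
        raise ValueError("overlap must be smaller than the window length")
    t0 = max(rr_grid.t0, eda_grid.t0)
    t_last = min(rr_grid.t_end, eda_grid.t_end)
    duration = t_last - t0
    if duration < window_s:
        raise ValueError(
            f"register spans {duration:.1f} s, shorter than one {window_s:.0f} s window"
        )
    windows: list[AnalysisWindow] = []
    for i, start in enumerate(window_starts(duration, window_s, overlap_s)):
        t_start = t0 + start
        t_end = t_start + window_s
        in_win = (register.beat_times >= t_start) & (register.beat_times < t_end)
        beats = register.rr[in_win]
        if beats.size < 2:
            logger.warning(
                "dropping window %d [%.1f, %.1f): only %d beat(s)",
                i, t_start, t_end, beats.size,
            )
            continue
        windows.append(
            AnalysisWindow(
                index=i,
                t_start=t_start,
                t_end=t_end,
                rr_grid=rr_grid.slice(t_start, t_end),
                rr_beats=beats,
                beat_times=register.beat_times[in_win],
                eda_grid=eda_grid.slice(t_start, t_end),
            )
        )
    return WindowSet(windows=windows)


def assign_labels(
    window_set: WindowSet,
    annotations: list[tuple[float, float, str]],
    min_coverage: float = 0.5,
) -> WindowSet:
    """Attach ground-truth labels to windows from annotation intervals.

    A window is labeled iff a single annotation covers at least
    ``min_coverage`` of it; when two annotations tie at exactly the threshold
    the window stays unlabeled (and is later excluded from training tables).
    """
    for w in window_set:
        best_label: str | None = None
        best_cov = 0.0
        tie = False
        for t0, t1, label in annotations:
            cov = max(0.0, min(t1, w.t_end) - max(t0, w.t_start)) / w.duration
            if cov > best_cov:
                best_label, best_cov, tie = label, cov, False
            elif cov == best_cov and cov > 0 and label != best_label:
                tie = True
        w.label = best_label if (best_cov >= min_coverage and not tie) else None
    return window_set
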