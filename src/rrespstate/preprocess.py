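"""Register ingestion, low-pass filtering, tachogram resampling and normalization.

A *register* is one subject's recording session: an electrodermal activity
(EDA) series in microsiemens and an RR tachogram (the sequence of inter-beat
intervals, in seconds, stamped at the time of each beat).  Both signals are
low-pass filtered at 2 Hz before any feature extraction: this keeps the whole
RR spectrum (bounded below 0.5 Hz) and the EDA tonic component intact while
discarding measurement noise.

The tachogram is unevenly sampled by construction (one sample per heartbeat),
so slopes, surfaces and spectra need it interpolated onto an even grid; 4 Hz
is the conventional rate for heart-rate-variability analysis and comfortably
supports the 0.05-0.5 Hz band of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import PchipInterpolator, interp1d

__all__ = [
    "PhysioRegister",
    "NormalizationParams",
    "EvenSeries",
    "lowpass_filter",
    "resample_rr",
    "normalize_minmax",
    "read_register",
    "write_register",
]

#: labels a window (and therefore a training instance) may carry
CLASS_LABELS = ("Relax-RResp", "Basal-RResp", "Stress-RResp")


class DegenerateSignalError(ValueError):
    """Raised when an operation is undefined on a constant / too-short signal."""


@dataclass(frozen=True)
class EvenSeries:
    """A signal on an even time grid: value k lives at ``t0 + k * dt``."""

    t0: float
    dt: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if v.ndim != 1 or v.size < 1:
            raise ValueError("values must be a non-empty 1-D array")

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.values.size - 1)

    def slice(self, t_start: float, t_end: float) -> "EvenSeries":
        """Return the sub-series with timestamps in ``[t_start, t_end)``."""
        eps = 1e-9 * self.dt
        i0 = int(np.ceil((t_start - self.t0) / self.dt - eps))
        i1 = int(np.ceil((t_end - self.t0) / self.dt - eps))
        i0 = max(i0, 0)
        i1 = min(i1, self.values.size)
        if i1 <= i0:
            raise ValueError(f"empty slice [{t_start}, {t_end})")
        return EvenSeries(self.t0 + i0 * self.dt, self.dt, self.values[i0:i1])


@dataclass(frozen=True)
class NormalizationParams:
    """Extrema used by the min-max normalization X_norm = (X - min)/(max - min)."""

    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        if not self.x_max > self.x_min:
            raise DegenerateSignalError(
                f"normalization undefined: x_max ({self.x_max}) must exceed "
                f"x_min ({self.x_min})"
            )

    @classmethod
    def from_signal(cls, x: Sequence[float]) -> "NormalizationParams":
        x = np.asarray(x, dtype=float)
        return cls(float(np.min(x)), float(np.max(x)))


@dataclass
class PhysioRegister:
    """One subject's aligned EDA series, RR tachogram and state annotations.

    ``eda_t``/``eda`` hold the conductance series (seconds, microsiemens);
    ``beat_times``/``rr`` hold the tachogram (each inter-beat interval, in
    seconds, stamped at the beat that closes it).  ``annotations`` is a list
    of ``(t_start, t_end, label)`` intervals with labels drawn from
    ``CLASS_LABELS``.
    """

    subject_id: str
    eda_t: np.ndarray
    eda: np.ndarray
    beat_times: np.ndarray
    rr: np.ndarray
    annotations: list[tuple[float, float, str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eda_t = np.asarray(self.eda_t, dtype=float)
        self.eda = np.asarray(self.eda, dtype=float)
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.eda_t.size != self.eda.size:
            raise ValueError("EDA timestamps and values differ in length")
        if self.beat_times.size != self.rr.size:
            raise ValueError("beat times and RR values differ in length")
        if self.eda_t.size > 1 and not np.all(np.diff(self.eda_t) > 0):
            raise ValueError("EDA timestamps must be strictly increasing")
        if self.beat_times.size > 1 and not np.all(np.diff(self.beat_times) > 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(self.rr <= 0):
            raise ValueError("RR intervals must be strictly positive")
        self._check_annotations()

    def _check_annotations(self) -> None:
        prev_end = -np.inf
        for t0, t1, label in sorted(self.annotations):
            if t1 <= t0:
                raise ValueError(f"annotation [{t0}, {t1}] has non-positive length")
            if t0 < prev_end:
                raise ValueError("annotation intervals overlap")
            if label not in CLASS_LABELS:
                raise ValueError(f"unknown label {label!r}")
            prev_end = t1

    @property
    def t_start(self) -> float:
        """First instant covered by both signals (the analysis time origin)."""
        return max(float(self.eda_t[0]), float(self.beat_times[0]))

    @property
    def t_end(self) -> float:
        """Last instant covered by both signals."""
        return min(float(self.eda_t[-1]), float(self.beat_times[-1]))

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _butter_sos(cutoff_hz: float, fs: float, order: int):
    if fs / 2.0 <= cutoff_hz:
        raise ValueError(
            f"Nyquist frequency {fs / 2.0:g} Hz must exceed the cutoff "
            f"{cutoff_hz:g} Hz"
        )
    return signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")


def lowpass_filter(x: EvenSeries, cutoff_hz: float = 2.0, order: int = 4) -> EvenSeries:
    """Zero-phase low-pass filter an even series.

    A forward-backward (zero-phase) Butterworth filter so that filtered
    samples stay aligned with their timestamps; the effective amplitude
    response is the squared magnitude of the one-pass design.

    Raises
    ------
    ValueError
        If the series is too short for the filter's edge padding, or the
        grid's Nyquist frequency does not exceed ``cutoff_hz``.
    """
    sos = _butter_sos(cutoff_hz, x.fs, order)
    # sosfiltfilt default padding: 3 * (2 * n_sections + 1) samples
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.values.size <= padlen:
        raise ValueError(
            f"series of length {x.values.size} too short for the order-{order} "
            f"zero-phase filter (needs > {padlen} samples)"
        )
    filtered = signal.sosfiltfilt(sos, x.values)
    return EvenSeries(x.t0, x.dt, filtered)


def filter_gain(cutoff_hz: float, fs: float, freq_hz: float, order: int = 4) -> float:
    """Amplitude gain of :func:`lowpass_filter` at ``freq_hz`` (squared one-pass
    magnitude, because the filter runs forward and backward)."""
    sos = _butter_sos(cutoff_hz, fs, order)
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]) ** 2)


def resample_rr(
    beat_times: Sequence[float],
    rr: Sequence[float],
    grid_hz: float = 4.0,
    kind: str = "pchip",
) -> EvenSeries:
    """Interpolate the tachogram onto an even grid spanning first to last beat.

    ``kind='pchip'`` (default) uses monotone-preserving cubic interpolation, so
    grid values never overshoot the local beat-to-beat range; ``kind='linear'``
    is available for strict linearity.
    """
    t = np.asarray(beat_times, dtype=float)
    v = np.asarray(rr, dtype=float)
    if t.size < 2:
        raise ValueError("resampling needs at least 2 beats")
    dt = 1.0 / grid_hz
    n = int(np.floor((t[-1] - t[0]) / dt)) + 1
    grid_t = t[0] + dt * np.arange(n)
    if kind == "pchip":
        interp = PchipInterpolator(t, v)
    elif kind == "linear":
        interp = interp1d(t, v)
    else:
        raise ValueError(f"unknown interpolation kind {kind!r}")
    return EvenSeries(float(t[0]), dt, np.asarray(interp(grid_t), dtype=float))


def normalize_minmax(x: Sequence[float], params: NormalizationParams) -> np.ndarray:
    """Linear min-max normalization: register minimum maps to 0, maximum to 1."""
    x = np.asarray(x, dtype=float)
    return (x - params.x_min) / (params.x_max - params.x_min)


def running_extrema_params(x: Sequence[float]) -> list[NormalizationParams]:
    """Causal variant: extrema of ``x[:k+1]`` for each k (no future leakage).

    The default whole-register normalization uses the global extrema, which
    leaks future signal into early windows; this helper supports the causal
    mode where each window normalizes against the extrema seen so far.
    Entries where the running min equals the running max are unusable and a
    caller should fall back to the first non-degenerate prefix.
    """
    x = np.asarray(x, dtype=float)
    mins = np.minimum.accumulate(x)
    maxs = np.maximum.accumulate(x)
    out: list[NormalizationParams] = []
    for lo, hi in zip(mins, maxs):
        out.append(NormalizationParams(lo, hi) if hi > lo else None)  # type: ignore[arg-type]
    return out


# ---------------------------------------------------------------------------
# register file I/O: one delimited text file per signal
# ---------------------------------------------------------------------------

def read_register(
    eda_path: str | Path,
    rr_path: str | Path,
    annotations_path: str | Path | None = None,
    subject_id: str | None = None,
    sep: str = ",",
) -> PhysioRegister:
    """Read a register from delimited text files.

    The EDA file needs columns ``t,eda`` (seconds, microsiemens), the RR file
    ``beat_time,rr`` (both seconds) and the optional annotations file
    ``t_start,t_end,label``.
    """
    eda_df = pd.read_csv(eda_path, sep=sep)
    rr_df = pd.read_csv(rr_path, sep=sep)
    for df, cols, path in (
        (eda_df, ("t", "eda"), eda_path),
        (rr_df, ("beat_time", "rr"), rr_path),
    ):
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
    annotations: list[tuple[float, float, str]] = []
    if annotations_path is not None:
        ann_df = pd.read_csv(annotations_path, sep=sep)
        annotations = [
            (float(r.t_start), float(r.t_end), str(r.label))
            for r in ann_df.itertuples()
        ]
    return PhysioRegister(
        subject_id=subject_id or Path(eda_path).stem,
        eda_t=eda_df["t"].to_numpy(),
        eda=eda_df["eda"].to_numpy(),
        beat_times=rr_df["beat_time"].to_numpy(),
        rr=rr_df["rr"].to_numpy(),
        annotations=annotations,
    )


def write_register(register: PhysioRegister, out_dir: str | Path, sep: str = ",") -> dict[str, Path]:
    """Write a register as the three delimited text files read_register expects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = register.subject_id
    paths = {
        "eda": out / f"{sid}_eda.csv",
        "rr": out / f"{sid}_rr.csv",
        "annotations": out / f"{sid}_annotations.csv",
    }
    pd.DataFrame({"t": register.eda_t, "eda": register.eda}).to_csv(
        paths["eda"], sep=sep, index=False
    )
    pd.DataFrame({"beat_time": register.beat_times, "rr": register.rr}).to_csv(
        paths["rr"], sep=sep, index=False
    )
    pd.DataFrame(
        register.annotations, columns=["t_start", "t_end", "label"]
    ).to_csv(paths["annotations"], sep=sep, index=False)
    return paths
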