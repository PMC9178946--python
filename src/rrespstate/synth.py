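"""Seeded generator of labeled synthetic physiological registers.

Emulates the statistical structure the classifier relies on, so the whole
pipeline is testable without any recorded data:

* **RR tachogram** — beats are laid down sequentially; each inter-beat
  interval is the current state's mean RR plus respiratory sinus arrhythmia
  (a sinusoid at the breathing frequency whose amplitude shrinks under
  arousal, since vagal tone drives it) plus AR(1) noise, truncated at a
  physiological floor.  Relaxation means long intervals (slow heart),
  stress short ones.
* **EDA** — a piecewise-linear tonic level whose slope depends on state
  (drifting down in relaxation, flat at rest, climbing under stress) plus
  phasic skin-conductance responses: bi-exponential (fast rise, slow decay)
  kernels dropped at Poisson event times whose rate grows with arousal,
  plus white sensor noise.

The same seed always reproduces the identical register bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pipeline import PipelineConfig, build_feature_table
from .preprocess import PhysioRegister

__all__ = ["StateSchedule", "SynthConfig", "generate_register", "build_labeled_table", "generate_cohort"]

#: schedule state -> training label
STATE_LABEL = {
    "Relax": "Relax-RResp",
    "Basal": "Basal-RResp",
    "Stress": "Stress-RResp",
}


@dataclass(frozen=True)
class StateSchedule:
    """Ordered (duration_s, state) segments, e.g. a basal-stress-relax protocol."""

    segments: tuple[tuple[float, str], ...]

    def __post_init__(self) -> None:
        for dur, state in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            if state not in STATE_LABEL:
                raise ValueError(f"unknown state {state!r}")

    @classmethod
    def three_stage(cls, segment_s: float = 300.0) -> "StateSchedule":
        """The default protocol: rest, then stress, then relaxation."""
        return cls(
            (
                (segment_s, "Basal"),
                (segment_s, "Stress"),
                (segment_s, "Relax"),
            )
        )

    @property
    def duration(self) -> float:
        return sum(d for d, _ in self.segments)

    def state_at(self, t: float) -> str:
        acc = 0.0
        for dur, state in self.segments:
            acc += dur
            if t < acc:
                return state
        return self.segments[-1][1]

    def annotations(self) -> list[tuple[float, float, str]]:
        out = []
        acc = 0.0
        for dur, state in self.segments:
            out.append((acc, acc + dur, STATE_LABEL[state]))
            acc += dur
        return out


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults draw three partially overlapping classes.

    Mean RR levels (1.00 / 0.80 / 0.62 s for relaxation / rest / stress) span
    the plausible 60-97 bpm range of a seated subject; respiratory sinus
    arrhythmia sits at 0.25 Hz (15 breaths/min) with amplitude decreasing
    under arousal.  EDA tonic slopes and phasic-response rates follow the
    canonical arousal pattern: declining and quiet while relaxing, rising and
    busy under stress.  Noise scales are set so the basal class overlaps both
    neighbours, which keeps the intermediate class the hardest to classify.
    """

    rr_mean: dict = field(
        default_factory=lambda: {"Relax": 1.00, "Basal": 0.80, "Stress": 0.62}
    )
    rsa_amplitude: dict = field(
        default_factory=lambda: {"Relax": 0.05, "Basal": 0.03, "Stress": 0.015}
    )
    rsa_freq: float = 0.25  # Hz
    rr_noise_sd: float = 0.025  # s, AR(1) innovation scale
    rr_noise_phi: float = 0.8  # AR(1) coefficient
    rr_floor: float = 0.25  # s, shortest physiological interval
    eda_tonic_slope: dict = field(
        default_factory=lambda: {"Relax": -0.010, "Basal": 0.0, "Stress": 0.020}
    )
    eda_baseline: float = 5.0  # microsiemens
    scr_rate: dict = field(
        default_factory=lambda: {"Relax": 1.0, "Basal": 3.0, "Stress": 10.0}
    )  # events per minute
    scr_amplitude: float = 0.4  # microsiemens per response
    scr_rise_s: float = 1.0
    scr_decay_s: float = 4.0
    eda_noise_sd: float = 0.02  # microsiemens
    eda_fs: float = 8.0  # Hz

    def scaled_separation(self, factor: float) -> "SynthConfig":
        """Shrink (factor < 1) the between-state separations of every channel
        toward the basal value; factor 0 makes the three states identical."""
        def shrink(d: dict) -> dict:
            ref = d["Basal"]
            return {k: ref + factor * (v - ref) for k, v in d.items()}

        return replace(
            self,
            rr_mean=shrink(self.rr_mean),
            rsa_amplitude=shrink(self.rsa_amplitude),
            eda_tonic_slope=shrink(self.eda_tonic_slope),
            scr_rate=shrink(self.scr_rate),
        )


def _scr_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Bi-exponential skin-conductance-response shape, peak-normalized to 1."""
    k = np.exp(-t / decay) - np.exp(-t / rise)
    peak = np.max(k) if np.max(k) > 0 else 1.0
    return np.where(t >= 0, k / peak, 0.0)


def generate_register(
    schedule: StateSchedule,
    config: SynthConfig | None = None,
    seed: int = 0,
    subject_id: str = "synth",
) -> PhysioRegister:
    """Generate one labeled synthetic register (annotations = the schedule)."""
    config = config or SynthConfig()
    rng = np.random.default_rng(seed)
    total = schedule.duration

    # --- RR tachogram: sequential beats -----------------------------------
    beat_times: list[float] = []
    rr: list[float] = []
    t = 0.0
    ar = 0.0
    # breathing phase at recording start is arbitrary for a real subject
    rsa_phase = rng.uniform(0.0, 2 * np.pi)
    while True:
        state = schedule.state_at(t)
        ar = config.rr_noise_phi * ar + rng.normal(0.0, config.rr_noise_sd)
        interval = (
            config.rr_mean[state]
            + config.rsa_amplitude[state]
            * np.sin(2 * np.pi * config.rsa_freq * t + rsa_phase)
            + ar
        )
        interval = max(interval, config.rr_floor)
        t += interval
        if t > total:
            break
        beat_times.append(t)
        rr.append(interval)

    # --- EDA: tonic drift + phasic responses + sensor noise ----------------
    dt = 1.0 / config.eda_fs
    n = int(np.floor(total / dt)) + 1
    times = dt * np.arange(n)
    states = np.array([schedule.state_at(tt) for tt in times])
    slopes = np.array([config.eda_tonic_slope[s] for s in states])
    tonic = config.eda_baseline + np.cumsum(slopes) * dt
    tonic = np.maximum(tonic, 0.1)  # conductance stays positive

    phasic = np.zeros(n)
    acc = 0.0
    for dur, state in schedule.segments:
        rate_hz = config.scr_rate[state] / 60.0
        n_events = rng.poisson(rate_hz * dur)
        event_times = np.sort(rng.uniform(acc, acc + dur, size=n_events))
        for te in event_times:
            tail = times >= te
            phasic[tail] += config.scr_amplitude * _scr_kernel(
                times[tail] - te, config.scr_rise_s, config.scr_decay_s
            )
        acc += dur
    eda = tonic + phasic + rng.normal(0.0, config.eda_noise_sd, size=n)

    return PhysioRegister(
        subject_id=subject_id,
        eda_t=times,
        eda=eda,
        beat_times=np.array(beat_times),
        rr=np.array(rr),
        annotations=schedule.annotations(),
        meta={"seed": seed, "generator": "rrespstate.synth"},
    )


def build_labeled_table(
    register: PhysioRegister, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Full 51-feature labeled table of a (synthetic or real) register."""
    if not register.annotations:
        raise ValueError("register has no annotations to label windows from")
    return build_feature_table(register, config)


def generate_cohort(
    n_subjects: int = 20,
    schedule: StateSchedule | None = None,
    config: SynthConfig | None = None,
    seed: int = 0,
    counterbalance: bool = False,
    return_groups: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, np.ndarray]:
    """Pooled labeled feature table of a cohort of synthetic subjects.

    Subject k gets the derived seed ``seed + k``, so cohorts are reproducible
    yet subjects are independent draws.  ``counterbalance=True`` shuffles the
    order of the schedule's segments per subject (keeping their durations), as
    a counterbalanced protocol would, so that window position within the
    register carries no class information at the cohort level.
    ``return_groups=True`` additionally returns the per-row subject index,
    ready for group-aware cross-validation.
    """
    schedule = schedule or StateSchedule.three_stage()
    rng = np.random.default_rng(seed)
    tables = []
    group_ids = []
    for k in range(n_subjects):
        sched_k = schedule
        if counterbalance:
            segs = list(schedule.segments)
            rng.shuffle(segs)
            sched_k = StateSchedule(tuple(segs))
        reg = generate_register(
            sched_k, config, seed=seed + k, subject_id=f"synth{k:02d}"
        )
        t = build_labeled_table(reg)
        tables.append(t)
        group_ids.extend([k] * len(t))
    pooled = pd.concat(tables, ignore_index=True)
    if return_groups:
        return pooled, np.asarray(group_ids)
    return pooled
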