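"""Synthetic shank/thigh kinematics with controlled coordination structure.

Emulates recordings of three unilateral knee extension–flexion tasks —
unilateral sit-to-stand (UniSTS), step-up (SU) and continuous forward hop
(Hop) — at the study conditions: 14 participants, both legs, three
repetitions per trial, 60 Hz sampling.

The generative model per repetition r:

    thigh(t) = A_thigh · shape(t / T)
    shank(t) = A_shank · shape((t + δ_r·T/360) / T) + irregularity term + noise

with the per-repetition shank-vs-thigh phase offset δ_r ~
Normal(mean_phase_lag, rep_lag_sd) degrees, held fixed within the
repetition.  The sign is chosen so that a positive δ_r advances the shank
and yields a positive shank-minus-thigh CRP of +δ_r: the generator
parameter is the ground truth of the measure it drives.  The lag is injected
as a time shift of the same base waveform (not an additive angle offset)
because continuous relative phase measures temporal coupling and the
centering step removes amplitude offsets anyway.  ``rep_lag_sd`` is the
generative twin of sdMRP; ``irregularity`` — a band-limited smooth random
modulation in the 4–10 Hz motor-correction band, redrawn each repetition,
not white noise — is the generative twin of SampEn, while additive white
measurement noise is controlled separately by ``noise_sd``.

Waveforms: UniSTS and SU use a half-cosine rise–fall cycle (sinusoidal
after centering); Hop uses a shorter asymmetric pulse with a flat landing
plateau.  These are stand-ins for the tasks' kinematics: cyclic
flexion–extension with task-appropriate timing, with no claim of matching
any measured trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .io import Repetition, SegmentSeries, TaskRecording, write_recording

HOP_ACTIVE_FRACTION = 0.75  # fraction of the hop cycle in flight/extension; rest is landing plateau


def _shape_half_cosine(u: np.ndarray) -> np.ndarray:
    """Smooth rise–fall over one cycle: 0 at the endpoints, 1 at mid-cycle."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.mod(u, 1.0)))


def _shape_hop(u: np.ndarray) -> np.ndarray:
    """Asymmetric pulse: raised-cosine excursion then a flat landing plateau."""
    u = np.mod(u, 1.0)
    pulse = 0.5 * (1.0 - np.cos(2.0 * np.pi * u / HOP_ACTIVE_FRACTION))
    return np.where(u < HOP_ACTIVE_FRACTION, pulse, 0.0)


_SHAPES = {"half_cosine": _shape_half_cosine, "hop_pulse": _shape_hop}


@dataclass(frozen=True)
class TaskProfile:
    """Waveform family and scale for one task's knee flexion–extension cycle.

    ``shank_asymmetry`` adds a fixed second-harmonic component to the shank
    waveform (as a fraction of its amplitude).  It gives each task a
    repeatable within-cycle CRP excursion — real segment pairs do not hold
    a constant lag through a movement — which sets the scale of the CRP's
    standard deviation (and thus the SampEn tolerance r) independently of
    the between-repetition lag spread.  Being deterministic and identical
    across repetitions it adds no entropy and does not move the sdMRP.
    """

    task: str
    cycle_duration: float        # seconds per repetition cycle
    thigh_amplitude: float       # degrees
    shank_amplitude: float       # degrees
    cycle_shape: str = "half_cosine"
    shank_asymmetry: float = 0.0  # fraction of shank amplitude

    def __post_init__(self) -> None:
        if not (self.cycle_duration > 0 and self.thigh_amplitude > 0
                and self.shank_amplitude > 0):
            raise ParameterError("cycle_duration and amplitudes must be positive")
        if self.cycle_shape not in _SHAPES:
            raise ParameterError(f"unknown cycle shape {self.cycle_shape!r}")

    @property
    def shape(self):
        return _SHAPES[self.cycle_shape]

    def shank_wave(self, u: np.ndarray) -> np.ndarray:
        """Shank base waveform in degrees at cycle coordinate u."""
        base = self.shank_amplitude * self.shape(u)
        if self.shank_asymmetry:
            base = base + (self.shank_asymmetry * self.shank_amplitude
                           * np.sin(4.0 * np.pi * np.mod(u, 1.0)))
        return base


#: Study-condition stand-in profiles.  Cycle durations reflect the tasks'
#: tempo (a controlled sit-to-stand-and-return is slow, continuous hops are
#: fast); amplitudes reflect typical sagittal segment excursions.
DEFAULT_PROFILES = {
    "UniSTS": TaskProfile("UniSTS", cycle_duration=3.0, thigh_amplitude=80.0,
                          shank_amplitude=30.0, cycle_shape="half_cosine",
                          shank_asymmetry=0.1),
    "SU": TaskProfile("SU", cycle_duration=2.0, thigh_amplitude=70.0,
                      shank_amplitude=40.0, cycle_shape="half_cosine",
                      shank_asymmetry=0.1),
    "Hop": TaskProfile("Hop", cycle_duration=1.0, thigh_amplitude=40.0,
                       shank_amplitude=30.0, cycle_shape="hop_pulse",
                       shank_asymmetry=0.0),
}


@dataclass(frozen=True)
class CoordinationParams:
    """Ground-truth coordination structure for the generator."""

    mean_phase_lag: float = 20.0   # degrees, population shank-vs-thigh lag
    rep_lag_sd: float = 5.0        # degrees, between-repetition lag spread (drives sdMRP)
    irregularity: float = 0.0      # degrees-scale smooth within-cycle perturbation (drives SampEn)
    noise_sd: float = 0.0          # degrees, additive white measurement noise on the shank
    n_reps: int = 3                # repetitions per trial, as in the study design
    sampling_rate: float = 60.0    # Hz
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("mean_phase_lag", "rep_lag_sd", "irregularity",
                     "noise_sd", "sampling_rate"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ParameterError(f"{name} must be finite, got {v}")
        if self.rep_lag_sd < 0 or self.noise_sd < 0 or self.irregularity < 0:
            raise ParameterError("rep_lag_sd, noise_sd and irregularity must be >= 0")
        if self.n_reps < 2:
            raise ParameterError("n_reps must be >= 2")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")


#: Study-condition coordination parameters per task: the step-up (a familiar
#: stair-like movement) gets the smallest repetition-to-repetition lag
#: spread; the hop, the most dynamic task, gets the largest within-cycle
#: irregularity.
DEFAULT_PARAMS_BY_TASK = {
    "UniSTS": CoordinationParams(rep_lag_sd=6.0, irregularity=0.3, noise_sd=0.1),
    "SU": CoordinationParams(rep_lag_sd=4.0, irregularity=0.3, noise_sd=0.1),
    "Hop": CoordinationParams(rep_lag_sd=6.0, irregularity=2.0, noise_sd=0.1),
}

#: SD (degrees) of the per-participant random effect on the mean phase lag.
PARTICIPANT_LAG_SD = 3.0


def generate_recording(profile: TaskProfile, params: CoordinationParams,
                       participant_id: str = "synthetic", side: str = "right",
                       dominance: str = "dominant",
                       rng: np.random.Generator | None = None) -> TaskRecording:
    """Generate one trial: ``n_reps`` consecutive repetition cycles.

    Identical seed (via ``params.seed`` or a caller-supplied ``rng`` state)
    gives bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    n_per_rep = int(round(profile.cycle_duration * fs))
    if n_per_rep < 8:
        raise ParameterError("cycle_duration × sampling_rate must give >= 8 samples")
    shape = profile.shape

    reps = []
    for r in range(params.n_reps):
        t = (r * n_per_rep + np.arange(n_per_rep)) / fs
        u = np.arange(n_per_rep) / n_per_rep  # cycle coordinate in [0, 1)
        thigh = profile.thigh_amplitude * shape(u)
        delta_r = rng.normal(params.mean_phase_lag, params.rep_lag_sd)
        shank = profile.shank_wave(u + delta_r / 360.0)
        if params.irregularity > 0:
            # Band-limited random modulation in the 4-10 Hz motor-correction
            # band, redrawn per repetition: smooth (well below Nyquist at
            # 60 Hz) but unpredictable at the template scale SampEn probes,
            # unlike the separately controlled white noise_sd floor.
            perturb = np.zeros_like(u)
            for j in (1, 2, 3):
                freq = rng.uniform(4.0, 10.0)
                amp = params.irregularity * rng.uniform(0.5, 1.0) / j
                phi = rng.uniform(0.0, 2.0 * np.pi)
                perturb += amp * np.sin(2.0 * np.pi * freq * (t - t[0]) + phi)
            shank = shank + perturb
        if params.noise_sd > 0:
            shank = shank + rng.normal(0.0, params.noise_sd, size=n_per_rep)
        reps.append(Repetition(
            index=r + 1,
            shank=SegmentSeries(time=t, angle=shank, segment_label="shank",
                                side=side, sampling_rate=fs),
            thigh=SegmentSeries(time=t, angle=thigh, segment_label="thigh",
                                side=side, sampling_rate=fs),
        ))
    return TaskRecording(participant_id=participant_id, task=profile.task,
                         side=side, dominance=dominance, repetitions=tuple(reps))


def generate_cohort(n_participants: int = 14,
                    profiles: dict[str, TaskProfile] | None = None,
                    params_by_task: dict[str, CoordinationParams] | None = None,
                    seed: int | None = 0,
                    participant_lag_sd: float = PARTICIPANT_LAG_SD
                    ) -> list[TaskRecording]:
    """Generate a full cohort: every participant × side × task.

    Each participant carries a Normal(0, participant_lag_sd) random effect
    added to the mean phase lag of every task, and a randomly assigned
    dominant side (consistent across tasks).  Reproducible under ``seed``.
    """
    if n_participants < 1:
        raise ParameterError("n_participants must be >= 1")
    if profiles is None:
        profiles = DEFAULT_PROFILES
    if not profiles:
        raise ParameterError("profiles must not be empty")
    if params_by_task is None:
        params_by_task = DEFAULT_PARAMS_BY_TASK

    root = np.random.default_rng(seed)
    recordings: list[TaskRecording] = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        effect = root.normal(0.0, participant_lag_sd)
        dominant_side = "right" if root.random() < 0.5 else "left"
        for task, profile in profiles.items():
            base = params_by_task[task]
            params = replace(base, mean_phase_lag=base.mean_phase_lag + effect)
            for side in ("left", "right"):
                recordings.append(generate_recording(
                    profile, params, participant_id=pid, side=side,
                    dominance="dominant" if side == dominant_side else "nondominant",
                    rng=root))
    return recordings


def write_cohort(recordings: list[TaskRecording], directory) -> list:
    """Write a cohort as one delimited file per recording (io dialect)."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        name = f"{rec.participant_id}_{rec.task}_{rec.side}.csv"
        paths.append(write_recording(rec, directory / name))
    return paths
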