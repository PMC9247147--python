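"""Reading, writing and segmenting segment-angle recordings.

The on-disk dialect is plain delimited text (comma by default), one row per
sample, with columns ``{participant, task, side, dominance, repetition,
time_s, segment, angle_deg}``.  A file holds one task recording: one
participant performing one task on one side, as a set of labelled
repetitions.  Angles are sagittal-plane segment rotations in degrees; all
public interfaces stay in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError, SchemaError

TASKS = ("UniSTS", "SU", "Hop")
SIDES = ("left", "right")
SEGMENTS = ("shank", "thigh")
DOMINANCE = ("dominant", "nondominant")

#: Relative tolerance on sample-interval uniformity.  The analytic-signal
#: (Hilbert) step assumes uniform sampling, so this is enforced at load time.
UNIFORMITY_RTOL = 1e-6

MIN_SAMPLES = 4  # minimum for sample entropy with m=2 to be definable downstream


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentSeries:
    """One segment's sagittal angular rotation θ(t) for one repetition.

    Parameters
    ----------
    time : array of float
        Sample times in seconds, strictly increasing, uniformly spaced.
    angle : array of float
        Segment angle in degrees.
    segment_label : {"shank", "thigh"}
    side : {"left", "right"}
    sampling_rate : float, optional
        In Hz; inferred from ``time`` when omitted.
    """

    time: np.ndarray
    angle: np.ndarray
    segment_label: str
    side: str
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.angle, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "angle", a)
        if self.segment_label not in SEGMENTS:
            raise ParameterError(f"segment_label must be one of {SEGMENTS}, got {self.segment_label!r}")
        if self.side not in SIDES:
            raise ParameterError(f"side must be one of {SIDES}, got {self.side!r}")
        if t.ndim != 1 or a.ndim != 1 or t.shape != a.shape:
            raise DataError("time and angle must be 1-D arrays of equal length")
        if t.size < MIN_SAMPLES:
            raise DataError(f"a segment series needs at least {MIN_SAMPLES} samples, got {t.size}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(a))):
            raise DataError("time and angle must be finite (no missing values)")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise DataError("time must be strictly increasing")
        mean_dt = float(dt.mean())
        if np.max(np.abs(dt - mean_dt)) > UNIFORMITY_RTOL * mean_dt:
            raise DataError(
                "non-uniform sampling: sample intervals vary by more than "
                f"{UNIFORMITY_RTOL:g} relative tolerance; use resample_uniform() explicitly"
            )
        if self.sampling_rate is None:
            object.__setattr__(self, "sampling_rate", 1.0 / mean_dt)

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class Repetition:
    """One repetition of a task: co-sampled shank and thigh series."""

    index: int
    shank: SegmentSeries
    thigh: SegmentSeries

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ParameterError("repetition index is 1-based")
        if self.shank.segment_label != "shank" or self.thigh.segment_label != "thigh":
            raise ParameterError("Repetition fields must be (shank, thigh) in that order")
        if len(self.shank) != len(self.thigh) or not np.allclose(
            self.shank.time, self.thigh.time, rtol=0, atol=1e-9
        ):
            raise DataError("shank and thigh must share an identical time vector")


@dataclass(frozen=True)
class TaskRecording:
    """All repetitions of one participant × task × side."""

    participant_id: str
    task: str
    side: str
    dominance: str
    repetitions: tuple[Repetition, ...]

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ParameterError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.side not in SIDES:
            raise ParameterError(f"side must be one of {SIDES}")
        if self.dominance not in DOMINANCE:
            raise ParameterError(f"dominance must be one of {DOMINANCE}")
        object.__setattr__(self, "repetitions", tuple(self.repetitions))
        for rep in self.repetitions:
            if rep.shank.side != self.side or rep.thigh.side != self.side:
                raise DataError("all repetitions must be recorded on the recording's side")


@dataclass(frozen=True)
class ColumnSchema:
    """Maps the dialect's logical columns onto a delimited file's headers."""

    participant: str = "participant"
    task: str = "task"
    side: str = "side"
    dominance: str = "dominance"
    repetition: str = "repetition"
    time: str = "time_s"
    segment: str = "segment"
    angle: str = "angle_deg"
    delimiter: str = ","

    @property
    def required(self) -> tuple[str, ...]:
        return (self.participant, self.task, self.side, self.repetition,
                self.time, self.segment, self.angle)


DEFAULT_SCHEMA = ColumnSchema()


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, schema: ColumnSchema = DEFAULT_SCHEMA) -> TaskRecording:
    """Read one task recording from a delimited text file.

    Rows are grouped by the repetition column; within each repetition the
    shank and thigh rows must be co-sampled.  Repetition labels are
    preserved as-is (a file with repetitions 1 and 3 yields two repetitions
    with those indices).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=schema.delimiter)
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    for col, allowed in ((schema.task, TASKS), (schema.side, SIDES)):
        vals = df[col].unique()
        if len(vals) != 1:
            raise DataError(f"{path}: expected a single {col} value, got {list(vals)}")
    participant = str(df[schema.participant].iloc[0])
    task = str(df[schema.task].iloc[0])
    side = str(df[schema.side].iloc[0])
    if schema.dominance in df.columns:
        dominance = str(df[schema.dominance].iloc[0])
    else:
        dominance = "dominant"

    reps = []
    for rep_label, group in df.groupby(schema.repetition, sort=True):
        series = {}
        for seg_label, seg_rows in group.groupby(schema.segment):
            if seg_label not in SEGMENTS:
                raise DataError(f"{path}: unknown segment label {seg_label!r}")
            t = seg_rows[schema.time].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise DataError(
                    f"{path}: non-monotone time within repetition {rep_label} ({seg_label})"
                )
            series[seg_label] = SegmentSeries(
                time=t,
                angle=seg_rows[schema.angle].to_numpy(dtype=float),
                segment_label=str(seg_label),
                side=side,
            )
        if set(series) != set(SEGMENTS):
            raise DataError(f"{path}: repetition {rep_label} lacks both shank and thigh rows")
        if len(series["shank"]) != len(series["thigh"]):
            raise DataError(
                f"{path}: unequal shank/thigh sample counts in repetition {rep_label}"
            )
        reps.append(Repetition(index=int(rep_label), shank=series["shank"], thigh=series["thigh"]))

    return TaskRecording(
        participant_id=participant, task=task, side=side,
        dominance=dominance, repetitions=tuple(reps),
    )


def write_recording(recording: TaskRecording, path: str | Path,
                    schema: ColumnSchema = DEFAULT_SCHEMA) -> Path:
    """Write a task recording in the delimited dialect (inverse of read_recording)."""
    path = Path(path)
    rows = []
    for rep in recording.repetitions:
        for series in (rep.shank, rep.thigh):
            for t, a in zip(series.time, series.angle):
                rows.append({
                    schema.participant: recording.participant_id,
                    schema.task: recording.task,
                    schema.side: recording.side,
                    schema.dominance: recording.dominance,
                    schema.repetition: rep.index,
                    schema.time: t,
                    schema.segment: series.segment_label,
                    schema.angle: a,
                })
    pd.DataFrame(rows).to_csv(path, sep=schema.delimiter, index=False, float_format="%.10g")
    return path


def resample_uniform(time: np.ndarray, angle: np.ndarray, rate: float | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Linearly resample an (irregularly sampled) series onto a uniform grid.

    Explicit opt-in: never applied silently, because resampling changes the
    sampling frequency that sample entropy depends on.  ``rate`` defaults to
    the modal (most common, rounded) rate of the input.
    """
    t = np.asarray(time, dtype=float)
    a = np.asarray(angle, dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise DataError("resampling needs at least 2 strictly increasing time stamps")
    if rate is None:
        dts = np.round(np.diff(t), 9)
        vals, counts = np.unique(dts, return_counts=True)
        rate = 1.0 / float(vals[np.argmax(counts)])
    if rate <= 0:
        raise ParameterError("sampling rate must be positive")
    n = int(np.floor((t[-1] - t[0]) * rate)) + 1
    grid = t[0] + np.arange(n) / rate
    return grid, np.interp(grid, t, a)


# ---------------------------------------------------------------------------
# Automatic repetition segmentation
# ---------------------------------------------------------------------------

def segment_by_threshold(shank: SegmentSeries, thigh: SegmentSeries,
                         level: float, min_duration: float) -> list[Repetition]:
    """Split co-sampled series into repetitions at thigh-angle threshold crossings.

    A repetition window opens when the thigh angle crosses ``level`` upward
    and closes at the next downward crossing; windows shorter than
    ``min_duration`` seconds are discarded.  This is the automatic fallback
    for recordings without an explicit repetition column.
    """
    if len(shank) != len(thigh) or not np.allclose(shank.time, thigh.time, rtol=0, atol=1e-9):
        raise DataError("shank and thigh must be co-sampled")
    y = thigh.angle
    lo, hi = float(y.min()), float(y.max())
    if not (lo < level < hi):
        raise ParameterError(
            f"threshold level {level} is outside the thigh angle's open range ({lo}, {hi})"
        )
    above = y > level
    ups = np.flatnonzero(~above[:-1] & above[1:]) + 1
    downs = np.flatnonzero(above[:-1] & ~above[1:]) + 1

    reps: list[Repetition] = []
    for up in ups:
        later = downs[downs > up]
        if later.size == 0:
            break
        down = int(later[0])
        start, stop = int(up), down  # window covers the above-level excursion
        if thigh.time[stop - 1] - thigh.time[start] < min_duration:
            continue
        if stop - start < MIN_SAMPLES:
            continue
        reps.append(Repetition(
            index=len(reps) + 1,
            shank=_slice(shank, start, stop),
            thigh=_slice(thigh, start, stop),
        ))
    return reps


def _slice(series: SegmentSeries, start: int, stop: int) -> SegmentSeries:
    return SegmentSeries(
        time=series.time[start:stop], angle=series.angle[start:stop],
        segment_label=series.segment_label, side=series.side,
        sampling_rate=series.sampling_rate,
    )


# ---------------------------------------------------------------------------
# Results I/O (report tables)
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = [
    "section", "leg", "measure", "task", "task_b", "median", "ci_low", "ci_high",
    "statistic", "df", "z", "p", "effect_r", "magnitude",
]


def write_results(report, path: str | Path) -> Path:
    """Write a comparison report as one delimited table.

    Rows are tagged by ``section``: per-(leg, task, measure) medians with CI
    bounds, omnibus Friedman statistics, pairwise Wilcoxon contrasts with
    effect sizes, and the dominant-vs-nondominant Kruskal–Wallis rows.  The
    file re-reads losslessly to the printed precision via read_results.
    """
    path = Path(path)
    rows: list[dict] = []
    for m in report.medians:
        rows.append({"section": "median", "leg": m.leg, "measure": m.measure,
                     "task": m.task, "median": m.median,
                     "ci_low": m.ci_low, "ci_high": m.ci_high})
    for o in report.omnibus:
        rows.append({"section": "omnibus", "leg": o.leg, "measure": o.measure,
                     "statistic": o.chi2, "df": o.df, "p": o.p})
    for c in report.pairwise:
        rows.append({"section": "pairwise", "leg": c.leg, "measure": c.measure,
                     "task": c.task_a, "task_b": c.task_b, "z": c.z, "p": c.p,
                     "effect_r": c.r, "magnitude": c.magnitude})
    for d in report.dominance:
        rows.append({"section": "dominance", "measure": d.measure, "task": d.task,
                     "statistic": d.h, "df": d.df, "p": d.p})
    for k in report.normality:
        rows.append({"section": "normality", "leg": k.leg, "measure": k.measure,
                     "task": k.task, "p": k.p})
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_results(path: str | Path):
    """Read back a write_results table into a ComparisonReport."""
    from .stats import (ComparisonReport, DominanceEntry, MedianEntry,
                        NormalityEntry, OmnibusEntry, PairwiseEntry)

    df = pd.read_csv(path)
    missing = [c for c in _RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing result columns {missing}")
    medians, omnibus, pairwise, dominance, normality = [], [], [], [], []
    for _, r in df.iterrows():
        sec = r["section"]
        if sec == "median":
            medians.append(MedianEntry(leg=r["leg"], measure=r["measure"], task=r["task"],
                                       median=float(r["median"]), ci_low=float(r["ci_low"]),
                                       ci_high=float(r["ci_high"])))
        elif sec == "omnibus":
            omnibus.append(OmnibusEntry(leg=r["leg"], measure=r["measure"],
                                        chi2=float(r["statistic"]), df=int(r["df"]),
                                        p=float(r["p"])))
        elif sec == "pairwise":
            pairwise.append(PairwiseEntry(leg=r["leg"], measure=r["measure"],
                                          task_a=r["task"], task_b=r["task_b"],
                                          z=float(r["z"]), p=float(r["p"]),
                                          r=float(r["effect_r"]), magnitude=r["magnitude"]))
        elif sec == "dominance":
            dominance.append(DominanceEntry(task=r["task"], measure=r["measure"],
                                            h=float(r["statistic"]), df=int(r["df"]),
                                            p=float(r["p"])))
        elif sec == "normality":
            normality.append(NormalityEntry(leg=r["leg"], measure=r["measure"],
                                            task=r["task"], p=float(r["p"])))
        else:
            raise DataError(f"{path}: unknown section {sec!r}")
    return ComparisonReport(medians=medians, omnibus=omnibus, pairwise=pairwise,
                            dominance=dominance, normality=normality)
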