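"""End-to-end orchestration: recordings → CRP → variability → statistics → report.

A single declarative RunConfig drives both input modes (synthetic cohort or
a directory of delimited recording files), so a full analysis is one call:

    report, results = run_analysis(RunConfig(mode="synthetic", seed=7))

Outputs under ``output_dir``: per-recording variability results
(``variability.csv``), the comparison report (``report.csv``), the
dominance median table (``dominance_medians.csv``), a machine-readable run
manifest (``manifest.json``: config echo, seed, package versions), and
optionally figures.  Identical config + seed reproduces every output
byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import CrpcoordError, ParameterError
from .io import TaskRecording, read_recording, write_results
from .stats import ComparisonReport, compare_tasks, dominance_medians
from .synthetic import (CoordinationParams, DEFAULT_PARAMS_BY_TASK,
                        DEFAULT_PROFILES, generate_cohort)
from .variability import (DEFAULT_INTERIOR_MARGIN, DEFAULT_M, DEFAULT_R_FACTOR,
                          analyze_recording)

log = logging.getLogger("crpcoord")

RESULT_COLUMNS = ["participant_id", "task", "side", "dominance",
                  "sd_mrp", "sampen", "m", "r_tol", "n_concat", "sampling_rate"]


@dataclass
class RunConfig:
    """Declarative configuration for one analysis run."""

    mode: str = "synthetic"                  # {"synthetic", "files"}
    input_dir: str | None = None             # files mode: directory of recording CSVs
    n_participants: int = 14                 # synthetic mode cohort size
    seed: int = 0
    interior_margin: float = DEFAULT_INTERIOR_MARGIN
    m: int = DEFAULT_M
    r_factor: float = DEFAULT_R_FACTOR
    sampen_strict: bool = True
    ci_level: float = 0.95
    n_boot: int = 10_000
    p_adjust: str | None = None
    output_dir: str | None = None
    rep_lag_sd: dict = field(default_factory=dict)      # per-task overrides
    irregularity: dict = field(default_factory=dict)    # per-task overrides
    noise_sd: dict = field(default_factory=dict)        # per-task overrides

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ParameterError("mode must be 'synthetic' or 'files'")
        if self.mode == "files" and not self.input_dir:
            raise ParameterError("files mode requires input_dir")
        if not (0.0 <= self.interior_margin < 0.5):
            raise ParameterError("interior_margin must be in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def params_by_task(self) -> dict[str, CoordinationParams]:
        out = {}
        for task, base in DEFAULT_PARAMS_BY_TASK.items():
            out[task] = dataclasses.replace(
                base,
                rep_lag_sd=self.rep_lag_sd.get(task, base.rep_lag_sd),
                irregularity=self.irregularity.get(task, base.irregularity),
                noise_sd=self.noise_sd.get(task, base.noise_sd),
            )
        return out


def load_recordings(config: RunConfig) -> list[TaskRecording]:
    if config.mode == "synthetic":
        return generate_cohort(n_participants=config.n_participants,
                               profiles=DEFAULT_PROFILES,
                               params_by_task=config.params_by_task(),
                               seed=config.seed)
    paths = sorted(Path(config.input_dir).glob("*.csv"))
    if not paths:
        raise ParameterError(f"no .csv recordings found in {config.input_dir}")
    return [read_recording(p) for p in paths]


def analyze_cohort(recordings: list[TaskRecording], config: RunConfig) -> pd.DataFrame:
    """Per-recording variability results as a tidy DataFrame."""
    rows = []
    for rec in recordings:
        t0 = time.perf_counter()
        try:
            res = analyze_recording(rec, interior_margin=config.interior_margin,
                                    m=config.m, r_factor=config.r_factor,
                                    strict=config.sampen_strict)
        except CrpcoordError as exc:
            raise type(exc)(
                f"{rec.participant_id}/{rec.task}/{rec.side}: {exc}") from exc
        log.debug("analyzed %s/%s/%s in %.1f ms", rec.participant_id, rec.task,
                  rec.side, 1e3 * (time.perf_counter() - t0))
        row = {c: getattr(res, c) for c in RESULT_COLUMNS}
        for i, v in enumerate(res.mrp_per_rep, start=1):
            row[f"mrp_{i}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def run_analysis(config: RunConfig) -> tuple[ComparisonReport, pd.DataFrame]:
    """Execute the full chain and (optionally) persist results + manifest."""
    recordings = load_recordings(config)
    results = analyze_cohort(recordings, config)
    report = compare_tasks(results, ci_level=config.ci_level,
                           n_boot=config.n_boot, seed=config.seed,
                           p_adjust=config.p_adjust)
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        results.to_csv(outdir / "variability.csv", index=False, float_format="%.10g")
        write_results(report, outdir / "report.csv")
        dominance_medians(results, ci_level=config.ci_level,
                          n_boot=config.n_boot, seed=config.seed
                          ).to_csv(outdir / "dominance_medians.csv", index=False,
                                   float_format="%.10g")
        _write_manifest(config, outdir / "manifest.json")
    return report, results


def _write_manifest(config: RunConfig, path: Path) -> None:
    import scipy

    manifest = {
        "config": dataclasses.asdict(config),
        "versions": {
            "crpcoord": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def make_figures(report: ComparisonReport, recordings: list[TaskRecording],
                 outdir: str | Path, interior_margin: float = DEFAULT_INTERIOR_MARGIN
                 ) -> list[Path]:
    """CRP-per-repetition traces and grouped bar plots of both measures.

    Pairwise contrasts with p < 0.05 are marked on the bars; with no
    pairwise statistics available the bars are drawn unannotated and a
    warning is logged.  Returns the written file paths; an empty report is
    a warning no-op.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .crp import repetition_crp

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if not report.medians and not recordings:
        log.warning("empty report and no recordings: nothing to plot")
        return written

    if recordings:
        rec = recordings[0]
        fig, ax = plt.subplots(figsize=(7, 3.5))
        for rep in rec.repetitions:
            series = repetition_crp(rep)
            t = series.time - series.time[0]
            ax.plot(t, series.crp, label=f"repetition {rep.index}")
        ax.set_xlabel("time within repetition (s)")
        ax.set_ylabel("CRP (deg)")
        ax.set_title(f"{rec.participant_id} {rec.task} {rec.side} shank-thigh CRP")
        ax.legend(fontsize=8)
        path = outdir / "crp_traces.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    measure_labels = {"sd_mrp": ("sdMRP (deg)", "linear"),
                      "sampen": ("SampEn of CRP", "nonlinear")}
    if not report.pairwise and report.medians:
        log.warning("report has no pairwise statistics: bars drawn without markers")
    for measure, (ylabel, kind) in measure_labels.items():
        entries = [m for m in report.medians if m.measure == measure]
        if not entries:
            continue
        legs = sorted({m.leg for m in entries})
        tasks = sorted({m.task for m in entries})
        fig, ax = plt.subplots(figsize=(6, 3.5))
        width = 0.8 / max(len(legs), 1)
        xs = np.arange(len(tasks))
        for i, leg in enumerate(legs):
            vals = []
            errs = []
            for task in tasks:
                entry = next(m for m in entries if m.leg == leg and m.task == task)
                vals.append(entry.median)
                errs.append([entry.median - entry.ci_low, entry.ci_high - entry.median])
            ax.bar(xs + i * width, vals, width=width, label=f"{leg} leg",
                   yerr=np.transpose(errs), capsize=3)
        sig = [c for c in report.pairwise
               if c.measure == measure and c.p < 0.05]
        if sig:
            ax.annotate("* " + ", ".join(sorted({f"{c.task_a} vs {c.task_b}" for c in sig})),
                        xy=(0.01, 0.95), xycoords="axes fraction", fontsize=7)
        ax.set_xticks(xs + width * (len(legs) - 1) / 2)
        ax.set_xticklabels(tasks)
        ax.set_ylabel(ylabel)
        ax.set_title(f"{kind} coordination variability")
        ax.legend(fontsize=8)
        path = outdir / f"variability_{measure}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    if not written:
        log.warning("empty report: no figures produced")
    return written
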