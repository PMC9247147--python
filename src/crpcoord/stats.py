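"""Nonparametric statistical battery over per-participant variability results.

The comparison design: within each leg, sdMRP and SampEn are compared
across the three tasks with a Friedman omnibus test followed by pairwise
Wilcoxon signed-rank tests with effect size r = |Z|/√n; task-level medians
carry percentile-bootstrap confidence intervals.  Dominant vs nondominant
legs are compared per task with Kruskal–Wallis (as a two-group rank test,
ignoring the pairing).  A Kolmogorov–Smirnov normality screen is advisory:
its p-values are logged in the report but the nonparametric path always
runs.

No multiple-testing correction is applied by default; Holm and Bonferroni
adjustments are available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, DegenerateSignalError, ParameterError

MEASURES = ("sd_mrp", "sampen")

#: Effect-size magnitude thresholds for r = |Z|/sqrt(n):
#: small below 0.1, medium from 0.1, large above 0.5.
R_SMALL, R_LARGE = 0.1, 0.5


# ---------------------------------------------------------------------------
# Report containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MedianEntry:
    leg: str
    measure: str
    task: str
    median: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class OmnibusEntry:
    leg: str
    measure: str
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class PairwiseEntry:
    leg: str
    measure: str
    task_a: str
    task_b: str
    z: float
    p: float
    r: float
    magnitude: str


@dataclass(frozen=True)
class DominanceEntry:
    task: str
    measure: str
    h: float
    df: int
    p: float


@dataclass(frozen=True)
class NormalityEntry:
    leg: str
    measure: str
    task: str
    p: float


@dataclass
class ComparisonReport:
    """Medians + CIs, omnibus and pairwise statistics, dominance contrasts."""

    medians: list[MedianEntry] = field(default_factory=list)
    omnibus: list[OmnibusEntry] = field(default_factory=list)
    pairwise: list[PairwiseEntry] = field(default_factory=list)
    dominance: list[DominanceEntry] = field(default_factory=list)
    normality: list[NormalityEntry] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def ks_normality(sample) -> float:
    """Kolmogorov–Smirnov normality screen with estimated parameters.

    One-sample KS against a normal with the sample's own mean and SD
    (parameter plug-in).  Advisory only: it gates nothing, since the
    pipeline always takes the nonparametric path.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise DataError("normality screen needs n >= 5")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise DataError("normality screen is degenerate for a constant sample")
    return float(sps.kstest(x, "norm", args=(float(np.mean(x)), sd)).pvalue)


def friedman(block_matrix) -> tuple[float, int, float]:
    """Friedman rank test over a complete participants × conditions matrix.

    Returns (χ², df, p) with midrank ties and tie correction; df = k − 1.
    """
    m = np.asarray(block_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise DataError("friedman needs a 2-D matrix with >= 2 rows and >= 2 columns")
    if not np.all(np.isfinite(m)):
        raise DataError("friedman requires a complete matrix (no missing cells)")
    k = m.shape[1]
    try:
        with np.errstate(invalid="ignore"):
            res = sps.friedmanchisquare(*(m[:, j] for j in range(k)))
    except ValueError as exc:
        raise DataError(f"friedman is degenerate on this matrix: {exc}") from exc
    if np.isnan(res.statistic):
        # every row fully tied (identical conditions): zero concordance signal
        if np.all(m == m[:, [0]]):
            return 0.0, k - 1, 1.0
        raise DataError("friedman tie correction degenerate on this matrix")
    return float(res.statistic), k - 1, float(res.pvalue)


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test, normal approximation.

    Zero differences are dropped; |differences| are midranked; the signed
    statistic uses the tie-corrected variance with no continuity
    correction.  Z is signed so that x > y elementwise gives positive Z.
    Returns (Z, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("wilcoxon needs two equal-length 1-D samples")
    d = x - y
    d = d[d != 0.0]
    if d.size == 0:
        raise DegenerateSignalError("all paired differences are zero")
    n = d.size
    if n < 5:
        raise DataError("wilcoxon needs >= 5 nonzero paired differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over tied groups of |d|
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        raise DegenerateSignalError("zero variance in signed-rank statistic")
    z = (w_plus - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


@dataclass(frozen=True)
class EffectSize:
    r: float
    magnitude: str


def effect_size_r(z: float, n: int) -> EffectSize:
    """Rank-test effect size r = |Z| / sqrt(n), n = number of pairs.

    Magnitude labels: small for r < 0.1, large for r > 0.5, medium between.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    r = abs(z) / np.sqrt(n)
    if r < R_SMALL:
        mag = "small"
    elif r > R_LARGE:
        mag = "large"
    else:
        mag = "medium"
    return EffectSize(r=float(r), magnitude=mag)


def kruskal_wallis(groups: Sequence) -> tuple[float, float]:
    """Kruskal–Wallis rank test (tie-corrected H, χ² p with df = k − 1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise DataError("kruskal-wallis needs >= 2 groups with >= 2 observations each")
    try:
        res = sps.kruskal(*groups)
    except ValueError as exc:  # all values identical
        raise DataError(f"kruskal-wallis is degenerate: {exc}") from exc
    return float(res.statistic), float(res.pvalue)


def median_ci(sample, level: float = 0.95, n_boot: int = 10_000,
              seed: int | None = 0) -> tuple[float, float, float]:
    """Median with a seeded percentile-bootstrap confidence interval."""
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise DataError("median CI needs n >= 5")
    if not (0.0 < level < 1.0):
        raise ParameterError("confidence level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    boots = np.median(rng.choice(x, size=(n_boot, x.size), replace=True), axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return float(np.median(x)), float(lo), float(hi)


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; not applied by default)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (p.size - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def compare_tasks(results: pd.DataFrame, tasks: Sequence[str] | None = None,
                  measures: Sequence[str] = MEASURES, ci_level: float = 0.95,
                  n_boot: int = 10_000, seed: int | None = 0,
                  p_adjust: str | None = None) -> ComparisonReport:
    """Build the full comparison report from per-recording results.

    ``results`` needs columns {participant_id, task, side, dominance} plus
    one column per measure.  Per leg × measure: Friedman omnibus over
    tasks, pairwise Wilcoxon with effect sizes, per-task median + bootstrap
    CI, and the advisory KS normality p.  Per task × measure: dominant vs
    nondominant Kruskal–Wallis.
    """
    if tasks is None:
        tasks = sorted(results["task"].unique())
    report = ComparisonReport()
    seed_seq = np.random.SeedSequence(seed)
    ci_seeds = iter(s.generate_state(1)[0] % (2 ** 31) for s in
                    seed_seq.spawn(len(MEASURES) * 2 * len(tasks) + 64))

    for leg in sorted(results["side"].unique()):
        leg_df = results[results["side"] == leg]
        wide = leg_df.pivot_table(index="participant_id", columns="task",
                                  values=list(measures), aggfunc="mean")
        for measure in measures:
            block = wide[measure][list(tasks)].dropna()
            if block.shape[0] >= 2 and block.shape[1] >= 2:
                chi2, df, p = friedman(block.to_numpy())
                report.omnibus.append(OmnibusEntry(leg=leg, measure=measure,
                                                   chi2=chi2, df=df, p=p))
            pair_ps: list[float] = []
            pair_entries: list[PairwiseEntry] = []
            for task_a, task_b in combinations(tasks, 2):
                a, b = block[task_a].to_numpy(), block[task_b].to_numpy()
                try:
                    z, p = wilcoxon_signed_rank(a, b)
                except DataError:
                    continue
                eff = effect_size_r(z, len(a))
                pair_entries.append(PairwiseEntry(
                    leg=leg, measure=measure, task_a=task_a, task_b=task_b,
                    z=z, p=p, r=eff.r, magnitude=eff.magnitude))
                pair_ps.append(p)
            if p_adjust == "holm" and pair_ps:
                for entry, adj in zip(pair_entries, holm_adjust(pair_ps)):
                    entry = PairwiseEntry(**{**entry.__dict__, "p": adj})
                    report.pairwise.append(entry)
            else:
                report.pairwise.extend(pair_entries)
            for task in tasks:
                vals = block[task].to_numpy() if task in block else np.array([])
                if vals.size >= 5:
                    med, lo, hi = median_ci(vals, level=ci_level, n_boot=n_boot,
                                            seed=int(next(ci_seeds)))
                    report.medians.append(MedianEntry(leg=leg, measure=measure,
                                                      task=task, median=med,
                                                      ci_low=lo, ci_high=hi))
                    try:
                        report.normality.append(NormalityEntry(
                            leg=leg, measure=measure, task=task,
                            p=ks_normality(vals)))
                    except DataError:
                        pass

    for task in tasks:
        task_df = results[results["task"] == task]
        for measure in measures:
            groups = [task_df.loc[task_df["dominance"] == d, measure].to_numpy()
                      for d in ("dominant", "nondominant")]
            if all(g.size >= 2 for g in groups):
                try:
                    h, p = kruskal_wallis(groups)
                except DataError:
                    continue
                report.dominance.append(DominanceEntry(task=task, measure=measure,
                                                       h=h, df=1, p=p))
    return report


def dominance_medians(results: pd.DataFrame, ci_level: float = 0.95,
                      n_boot: int = 10_000, seed: int | None = 0) -> pd.DataFrame:
    """Median (CI) per measure × task × dominance — the dominance table layout."""
    rows = []
    seed_seq = np.random.SeedSequence(seed)
    seeds = iter(s.generate_state(1)[0] % (2 ** 31) for s in seed_seq.spawn(64))
    for measure in MEASURES:
        for task in sorted(results["task"].unique()):
            for dom in ("dominant", "nondominant"):
                vals = results.loc[(results["task"] == task)
                                   & (results["dominance"] == dom), measure].to_numpy()
                if vals.size >= 5:
                    med, lo, hi = median_ci(vals, level=ci_level, n_boot=n_boot,
                                            seed=int(next(seeds)))
                    rows.append({"measure": measure, "task": task, "dominance": dom,
                                 "median": med, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)
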