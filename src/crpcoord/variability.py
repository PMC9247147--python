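"""Linear and nonlinear coordination-variability measures.

Linear: the mean relative phase (MRP) is the mean CRP over one repetition;
its standard deviation across repetitions (sdMRP, sample SD with n−1
denominator) quantifies how consistently the lag between segments is
reproduced from repetition to repetition.

Nonlinear: the per-repetition CRP series are concatenated into one vector
X = [CRP_1; CRP_2; CRP_3] and sample entropy SampEn(m, r, N) = −ln(A/B) is
applied to X, where B counts pairs of length-m templates within Chebyshev
distance r of each other and A the same for length m+1.  Low SampEn means a
regular, repeatable coordination pattern (0 for a strictly periodic
signal); values above 1 indicate little to no periodic structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .crp import CRPSeries, repetition_crp
from .errors import (DataError, DegenerateSignalError, ParameterError,
                     UndefinedEntropyError)
from .io import TaskRecording

DEFAULT_M = 2          # embedding dimension, the typical SampEn choice
DEFAULT_R_FACTOR = 0.2  # tolerance r = 0.2 × SD(X), the typical choice
DEFAULT_INTERIOR_MARGIN = 0.1  # fraction excluded at each end (Hilbert edge effects)


@dataclass(frozen=True)
class ConcatenatedCRP:
    """X: the repetitions' CRP values laid end to end.

    ``boundaries`` holds the cumulative start index of every repetition
    after the first, so boundary-spanning templates can be identified.
    """

    values: np.ndarray
    boundaries: tuple[int, ...]

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class VariabilityResult:
    """Per participant × leg × task coordination-variability summary."""

    participant_id: str
    task: str
    side: str
    dominance: str
    mrp_per_rep: tuple[float, ...]
    sd_mrp: float
    sampen: float
    m: int
    r_tol: float      # absolute tolerance in degrees actually used
    n_concat: int     # length N of the concatenated CRP vector
    sampling_rate: float


def interior(values: np.ndarray, margin: float) -> np.ndarray:
    """Drop the first and last ``margin`` fraction of samples."""
    if not (0.0 <= margin < 0.5):
        raise ParameterError("interior margin must be in [0, 0.5)")
    n = values.size
    k = int(np.floor(n * margin))
    out = values[k:n - k]
    if out.size == 0:
        raise DataError("no samples remain after interior-margin exclusion")
    return out


def mrp(crp_series: CRPSeries, interior_margin: float = DEFAULT_INTERIOR_MARGIN,
        circular: bool = False) -> float:
    """Mean relative phase of one repetition, degrees.

    The arithmetic mean of the wrapped CRP samples is the default.  The
    circular-mean variant exists for series that straddle the ±180°
    boundary, where the arithmetic mean of wrapped angles is misleading;
    with data away from that boundary the two agree.
    """
    vals = interior(crp_series.crp, interior_margin)
    if circular:
        rad = np.radians(vals)
        return float(np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))))
    return float(np.mean(vals))


def sd_mrp(mrps) -> float:
    """Sample standard deviation (n−1) of per-repetition MRPs, degrees."""
    arr = np.asarray(mrps, dtype=float)
    if arr.size < 2:
        raise DataError("sdMRP needs at least 2 repetitions")
    return float(np.std(arr, ddof=1))


def concat_crp(crps) -> ConcatenatedCRP:
    """Concatenate per-repetition CRP series in repetition order (X vector)."""
    crps = list(crps)
    if not crps:
        raise DataError("cannot concatenate an empty list of CRP series")
    order = crps[0].segment_order
    if any(c.segment_order != order for c in crps):
        raise DataError("all CRP series must share the same segment order")
    lengths = [len(c) for c in crps]
    boundaries = tuple(np.cumsum(lengths[:-1]).tolist())
    return ConcatenatedCRP(values=np.concatenate([c.crp for c in crps]),
                           boundaries=boundaries)


# ---------------------------------------------------------------------------
# Sample entropy
# ---------------------------------------------------------------------------

def template_counts(x: np.ndarray, m: int, r: float, strict: bool = True,
                    boundaries: tuple[int, ...] = (),
                    exclude_boundary_spanning: bool = False) -> tuple[int, int]:
    """Matched template-pair counts (A, B) for SampEn.

    Both counts run over template start indices that admit a length-(m+1)
    template, so A/B is a valid conditional-probability estimate; pairs are
    counted once (i < j), excluding self-matches.  Distance is Chebyshev
    (maximum coordinate difference); the match test is strict ``d < r`` by
    default, with ``strict=False`` giving the ``d <= r`` convention used by
    some references.  With ``exclude_boundary_spanning`` any template whose
    span crosses a repetition boundary of the concatenated vector is
    dropped (sensitivity analysis; off by default since X is defined as a
    plain concatenation).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    n_templates = n - m  # starts 0 .. n-m-1 admit the (m+1)-extension
    if n_templates < 2:
        raise DataError(f"sample entropy needs N >= m + 2 (N={n}, m={m})")

    # Embedding matrices: rows are templates of length m and m+1.
    idx = np.arange(n_templates)[:, None]
    emb_m1 = x[idx + np.arange(m + 1)[None, :]]   # (n_templates, m+1)
    emb_m = emb_m1[:, :m]

    keep = np.ones(n_templates, dtype=bool)
    if exclude_boundary_spanning and boundaries:
        for b in boundaries:
            keep &= ~((idx[:, 0] < b) & (idx[:, 0] + m + 1 > b))
        emb_m1 = emb_m1[keep]
        emb_m = emb_m[keep]
        if emb_m.shape[0] < 2:
            raise DataError("too few templates after boundary exclusion")

    def _count(emb: np.ndarray) -> int:
        d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
        hit = (d < r) if strict else (d <= r)
        iu = np.triu_indices(emb.shape[0], k=1)
        return int(np.count_nonzero(hit[iu]))

    return _count(emb_m1), _count(emb_m)


def sampen(x, m: int = DEFAULT_M, r_factor: float = DEFAULT_R_FACTOR,
           strict: bool = True, boundaries: tuple[int, ...] = (),
           exclude_boundary_spanning: bool = False) -> float:
    """Sample entropy SampEn(m, r, N) = −ln(A/B) with r = r_factor × SD(x).

    Raises DegenerateSignalError for a zero-variance signal and
    UndefinedEntropyError when no templates match (B = 0) or no extended
    templates match (A = 0, infinite entropy) — neither is silently coerced.
    """
    if isinstance(x, ConcatenatedCRP):
        if not boundaries:
            boundaries = x.boundaries
        x = x.values
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("sample entropy input must be finite")
    if r_factor <= 0:
        raise ParameterError("r_factor must be positive")
    sd = float(np.std(x))
    if sd == 0.0:
        raise DegenerateSignalError("sample entropy is undefined for a constant signal")
    a, b = template_counts(x, m, r_factor * sd, strict=strict, boundaries=boundaries,
                           exclude_boundary_spanning=exclude_boundary_spanning)
    if b == 0:
        raise UndefinedEntropyError("no length-m template pairs matched (B = 0)")
    if a == 0:
        raise UndefinedEntropyError("no length-(m+1) template pairs matched (A = 0)")
    return float(-math.log(a / b)) + 0.0  # normalize -0.0 for the A == B case


# ---------------------------------------------------------------------------
# Per-recording analysis
# ---------------------------------------------------------------------------

def analyze_recording(recording: TaskRecording,
                      interior_margin: float = DEFAULT_INTERIOR_MARGIN,
                      m: int = DEFAULT_M, r_factor: float = DEFAULT_R_FACTOR,
                      strict: bool = True, circular_mrp: bool = False
                      ) -> VariabilityResult:
    """Compute MRP per repetition, sdMRP, and SampEn of concatenated CRP.

    The interior margin (default 10% each end of every repetition) is
    excluded both from the MRP average and from the CRP segments entering
    the concatenation, so Hilbert edge distortion does not contaminate
    either measure.
    """
    if len(recording.repetitions) < 2:
        raise DataError("variability analysis needs at least 2 repetitions")
    crps = [repetition_crp(rep) for rep in recording.repetitions]
    mrps = tuple(mrp(c, interior_margin, circular=circular_mrp) for c in crps)
    trimmed = [
        CRPSeries(time=interior(c.time, interior_margin),
                  crp=interior(c.crp, interior_margin),
                  segment_order=c.segment_order)
        for c in crps
    ]
    x = concat_crp(trimmed)
    sd = float(np.std(x.values))
    ent = sampen(x, m=m, r_factor=r_factor, strict=strict)
    return VariabilityResult(
        participant_id=recording.participant_id, task=recording.task,
        side=recording.side, dominance=recording.dominance,
        mrp_per_rep=mrps, sd_mrp=sd_mrp(mrps), sampen=ent,
        m=m, r_tol=r_factor * sd, n_concat=len(x),
        sampling_rate=float(recording.repetitions[0].shank.sampling_rate),
    )
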