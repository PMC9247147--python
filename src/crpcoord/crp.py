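"""Continuous relative phase (CRP) from segment angular rotations.

The chain per repetition is

    θ(t)  --center-->  θ_c(t)  --analytic signal-->  φ(t)  --difference-->  CRP(t)

* centering removes the midrange so the angle oscillates symmetrically
  about zero: θ_c(t_i) = θ(t_i) − min θ − (max θ − min θ)/2;
* the instantaneous phase φ(t_i) is the four-quadrant angle of the analytic
  signal ζ(t) = θ_c(t) + i·H[θ_c](t), with H the Hilbert transform computed
  by the discrete FFT construction on the full repetition;
* CRP(t_i) = wrap(φ_shank(t_i) − φ_thigh(t_i)) into (−180°, 180°].

CRP = 0° means the two segments move fully in phase, ±180° fully out of
phase.  The difference is taken on unwrapped phases before wrapping, which
avoids spurious ±360° jumps at the wrap boundary.  Edge distortion of the
FFT Hilbert transform is handled downstream by excluding an interior margin
from summary statistics, never by padding.

All angles are degrees on the public surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .errors import DataError, DegenerateSignalError
from .io import Repetition, SegmentSeries, UNIFORMITY_RTOL

MIN_PHASE_SAMPLES = 8


def wrap_angle(x):
    """Wrap angle(s) in degrees into the half-open interval (−180, 180]."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("angles must be finite")
    w = -((-x + 180.0) % 360.0 - 180.0)
    out = np.where(w == -180.0, 180.0, w)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CenteredSeries:
    """Midrange-removed angular rotation θ_c(t); range symmetric about 0."""

    time: np.ndarray
    value: np.ndarray


@dataclass(frozen=True)
class PhaseSeries:
    """Instantaneous phase φ(t) of one segment, degrees.

    ``phase`` is wrapped into (−180, 180]; ``unwrapped`` accumulates the
    smallest-magnitude per-step increment and differs from ``phase`` by
    exact multiples of 360 at every sample.
    """

    time: np.ndarray
    phase: np.ndarray
    unwrapped: np.ndarray


@dataclass(frozen=True)
class CRPSeries:
    """Per-sample shank-minus-thigh phase difference, degrees in (−180, 180]."""

    time: np.ndarray
    crp: np.ndarray
    segment_order: tuple[str, str] = ("shank", "thigh")

    def __len__(self) -> int:
        return int(self.crp.size)


def center(series: SegmentSeries) -> CenteredSeries:
    """Remove the midrange so the angle's range is symmetric about zero.

    For a constant series the output is identically zero (max = min).
    """
    theta = np.asarray(series.angle, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise DataError("cannot center a series with non-finite values")
    lo, hi = theta.min(), theta.max()
    value = theta - lo - (hi - lo) / 2.0
    return CenteredSeries(time=np.asarray(series.time, dtype=float), value=value)


def analytic_phase(series: CenteredSeries) -> PhaseSeries:
    """Instantaneous phase of the analytic signal of a centered series.

    The analytic signal has the centered angle as its real part and the
    Hilbert transform as its imaginary part; the phase is the four-quadrant
    angle of that complex signal (a plain two-quadrant arctangent of the
    imaginary/real ratio cannot reach the full (−180, 180] range needed to
    distinguish in-phase from anti-phase coupling).
    """
    t = np.asarray(series.time, dtype=float)
    x = np.asarray(series.value, dtype=float)
    if x.size < MIN_PHASE_SAMPLES:
        raise DataError(f"analytic phase needs at least {MIN_PHASE_SAMPLES} samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataError("time must be strictly increasing")
    mean_dt = dt.mean()
    if np.max(np.abs(dt - mean_dt)) > UNIFORMITY_RTOL * mean_dt:
        raise DataError("analytic phase requires uniform sampling")
    if np.max(np.abs(x)) == 0.0:
        raise DegenerateSignalError("phase is undefined for an all-zero signal")
    zeta = hilbert(x)
    unwrapped = np.degrees(np.unwrap(np.angle(zeta)))
    return PhaseSeries(time=t, phase=wrap_angle(unwrapped), unwrapped=unwrapped)


def crp(phase1: PhaseSeries, phase2: PhaseSeries) -> CRPSeries:
    """Continuous relative phase: wrap(φ1 − φ2), with φ1 = shank, φ2 = thigh.

    The sign convention is shank phase minus thigh phase, fixed globally.
    The difference is formed on the unwrapped phases and wrapped afterwards.
    """
    if phase1.time.shape != phase2.time.shape or not np.allclose(
        phase1.time, phase2.time, rtol=0, atol=1e-9
    ):
        raise DataError("CRP requires identical time vectors for both phase series")
    diff = phase1.unwrapped - phase2.unwrapped
    return CRPSeries(time=phase1.time, crp=wrap_angle(diff))


def repetition_crp(rep: Repetition) -> CRPSeries:
    """Full per-repetition chain: center both segments, phase both, difference.

    Centering is applied per repetition (the mean relative phase is defined
    over each repetition), and the shank-minus-thigh order is fixed.
    """
    p_shank = analytic_phase(center(rep.shank))
    p_thigh = analytic_phase(center(rep.thigh))
    return crp(p_shank, p_thigh)
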