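# Methods

`crpcoord` quantifies how consistently two adjacent lower-limb segments —
shank and thigh — coordinate across repetitions of cyclic unilateral
movements (unilateral sit-to-stand, step-up, continuous hop), from
sagittal-plane segment-angle time series sampled at 60 Hz.

## Continuous relative phase

For each repetition, each segment's angle θ(t) is centered by midrange
removal,

    θ_c(t_i) = θ(t_i) − min θ − (max θ − min θ) / 2,

so the oscillation is symmetric about zero.  The instantaneous phase is
the four-quadrant angle of the analytic signal ζ(t) = θ_c(t) + i·H[θ_c](t),
with H the Hilbert transform computed by the FFT analytic-signal
construction (`scipy.signal.hilbert`) on the full repetition.  The
continuous relative phase is

    CRP(t_i) = wrap(φ_shank(t_i) − φ_thigh(t_i)) ∈ (−180°, 180°],

differenced on unwrapped phases before wrapping.  CRP = 0° means fully
in-phase coupling, ±180° fully anti-phase.  A two-quadrant arctangent of
H/θ_c would fold the phase into a half-range and cannot distinguish those
regimes, so the four-quadrant angle is used.

Assumptions: uniform sampling (enforced at load time to 1e−6 relative
tolerance; linear-interpolation resampling exists but is an explicit
opt-in, because sample entropy depends on the sampling frequency);
a reasonably narrowband, oscillatory signal, which holds for
flexion–extension cycles.

**Edge handling.** The FFT Hilbert transform distorts phase near window
edges.  Rather than padding (which invents data), summary statistics
exclude a configurable interior margin — default 10% of samples at each
end of every repetition — both from the repetition mean and from the
segments entering the concatenated entropy vector.  Setting the margin to
0 gives a strict-literal mode.

Sign convention: shank phase minus thigh phase, fixed everywhere.
Centering is per repetition, because the mean relative phase is defined
per repetition.

## Variability measures

*Linear.*  The mean relative phase MRP_r is the arithmetic mean of the
wrapped CRP over repetition r's interior (a circular-mean variant exists
but is non-default; it matters only if CRP straddles ±180°).  The linear
coordination variability is the sample standard deviation (n−1) of the
per-repetition MRPs, sdMRP.  With k = 3 repetitions the sample SD is
biased low by the factor c4(3) ≈ 0.886, so the expected sdMRP under a
lag-spread σ is ≈ 0.886 σ; the parameter-recovery tests check exactly
this.

*Nonlinear.*  The per-repetition CRP series are concatenated,
X = [CRP_1; CRP_2; CRP_3], and sample entropy

    SampEn(m, r, N) = −ln(A / B)

is applied to X, with m = 2, r = 0.2 × SD(X) (population SD), Chebyshev
template distance, strict inequality d < r, self-matches excluded, pairs
counted once (i < j), and both A (length m+1) and B (length m) counted
over the start indices 1…N−m that admit an (m+1)-length template — making
A/B a valid conditional-probability estimate.  A strictly periodic signal
gives 0; values above 1 indicate little periodic structure.  `strict=False`
switches to the d ≤ r convention used by some references; a flag can drop
templates spanning repetition boundaries (off by default, since X is
defined as a plain concatenation; the boundary indices are recorded for
this purpose).  B = 0 or A = 0 raises an explicit undefined-entropy error,
never a silent substitute value.  SampEn is reported together with N and
the sampling rate; no sampling-frequency correction is applied.

## Statistics

Within each leg, sdMRP and SampEn are compared across the three tasks
with the Friedman test (midranks, tie correction, χ² approximation,
df = k−1), followed by pairwise Wilcoxon signed-rank tests using the
normal approximation with tie-corrected variance and **no continuity
correction** — this choice makes an all-one-sign contrast at n = 14 give
|Z| = 3.296 ≈ 3.3 exactly.  Effect size r = |Z|/√n with n = participant
count; magnitudes are labelled small (r < 0.1), large (r > 0.5), and
medium otherwise (the conventional thresholds leave (0.3, 0.5] unnamed;
it is folded into "medium").  Task-level medians carry seeded
percentile-bootstrap confidence intervals (default 95%, 10,000 resamples)
— the CI method is a package decision, prominently configurable, as no
single standard exists for a median CI at n = 14.  Dominant vs
nondominant legs are compared per task with Kruskal–Wallis as a two-group
rank test; this ignores the leg pairing and is kept as such deliberately,
with the caveat that pairing would normally call for a signed-rank test.

The Kolmogorov–Smirnov normality screen (plug-in parameters, i.e. tested
against Normal(x̄, s)) is advisory: its p-values are logged in the report
but the nonparametric path always runs.  No multiple-testing correction
is applied by default; Holm/Bonferroni adjustment is available.

All approximate tests are validated against exhaustive permutation
oracles at tiny n (all (3!)⁶ Friedman rank assignments, all 2⁶ sign
flips, all C(10,5) group splits) and against closed forms (perfect
concordance χ² = n(k−1); maximal-separation H).  The χ² and normal
approximations at tiny n agree with the exact p only for some observed
statistics; the test fixtures use configurations where the gap is inside
the asserted tolerance (e.g. Friedman χ² = 7.0 at 6×3, gap 0.0013;
Kruskal–Wallis at 5+5, gap 0.0084 — at 3+3 the exact distribution's
granularity of 0.05 makes sub-0.01 agreement impossible for any fixture).

## Synthetic cohort generator

The generator emulates the study conditions — 14 participants, both
legs, three tasks, three repetitions per trial, 60 Hz — with controlled
ground truth:

| parameter | meaning | default |
|---|---|---|
| `mean_phase_lag` | population shank-vs-thigh phase offset (deg) | 20 |
| `rep_lag_sd` | between-repetition lag spread (deg); generative twin of sdMRP | UniSTS 6, SU 4, Hop 6 |
| `irregularity` | within-cycle smooth perturbation scale (deg); generative twin of SampEn | UniSTS 0.3, SU 0.3, Hop 2.0 |
| `noise_sd` | additive white measurement noise on the shank (deg) | 0.1 |
| participant lag random effect SD | between-participant mean-lag spread (deg) | 3 |

Per repetition r the thigh follows A·shape(t/T) and the shank the same
family shifted by a lag δ_r ~ Normal(mean_phase_lag, rep_lag_sd) held
fixed within the repetition.  The lag is a *time shift*, not an additive
angle offset, because CRP measures temporal coupling and centering
removes offsets.  A positive lag is injected as a shank phase lead so
that the ground-truth CRP equals +δ_r.

Waveforms: UniSTS and SU use a half-cosine rise–fall (a pure sinusoid
after centering; durations 3 s and 2 s, thigh/shank amplitudes 80/30 and
70/40 deg); Hop uses a 1 s asymmetric raised-cosine pulse with a flat
landing plateau over the final 25% of the cycle (40/30 deg).  The
half-cosine tasks add a fixed second-harmonic component to the shank
waveform (10% of shank amplitude).  This deterministic *shape asymmetry*
gives each task a repeatable within-cycle CRP excursion — real segment
pairs do not hold a constant lag through a movement — and it serves a
numerical purpose: it sets the scale of SD(X), and therefore of the
SampEn tolerance r, independently of the between-repetition lag spread.
Without it, SD(X) is dominated by rep_lag_sd and SampEn becomes an
artifact of the linear variability.  Being identical in every repetition
the asymmetry adds no entropy and leaves sdMRP recovery unbiased (the
lag-to-MRP gain stays within 3% of 1 for all three profiles).

The irregularity term is a sum of three random-phase sinusoids with
frequencies drawn uniformly from 4–10 Hz per repetition, scaled by
`irregularity` — smooth and band-limited (well below the 30 Hz Nyquist),
redrawn each repetition, distinct from the white `noise_sd` floor.  The
band matters: cycle-locked low-order harmonics (2–4 per cycle) were tried
first and make SampEn *non-monotone* in the irregularity scale, because
r = 0.2·SD(X) grows with the perturbation while a smooth low-order
pattern is locally predictable at the 3-sample template scale; the 4–10 Hz
band restores a monotone response, which the trend tests enforce over 100
seeds.

What the generator does **not** emulate: forward dynamics, ground
reaction forces, impact transients, sensor orientation fusion, soft-tissue
artifact, or any measured trajectory of the three tasks.  Passing tests
therefore demonstrate that the *measures and statistics* behave correctly
on signals with known coordination structure, not that the package
reproduces any specific cohort's numbers.

## Numerical choices and degenerate inputs

- Angles in degrees on every public surface; wrapping maps onto
  (−180°, 180°] with the boundary fixed at +180°.
- Constant series center to exactly zero; an all-zero series has
  undefined phase and raises a degenerate-signal error.
- Zero-variance X raises a degenerate-signal error from SampEn; unmatched
  templates raise an undefined-entropy error.
- sdMRP needs ≥ 2 repetitions; the normality screen, median CIs ≥ 5
  observations; Wilcoxon ≥ 5 nonzero differences — all hard errors, not
  warnings.
- Friedman on a matrix whose conditions are identical returns χ² = 0,
  p = 1 (the tie-corrected statistic is otherwise 0/0).
- Determinism: every stochastic step (generator, bootstrap) is driven by
  NumPy `SeedSequence` spawning from a single run seed; identical config
  and seed reproduce result files byte-identically.

## Problem sizes

The trend and calibration checks use sizes chosen to keep the full suite
in the minutes range on one CPU: 100 seeds per irregularity level, 1,000
trials for lag-spread recovery, 2,000 null matrices for Friedman
calibration, and 200 simulated 14-participant cohorts for the
cohort-level pattern and the ≈5% dominance-null rejection check.

## Known limitations

- The Hop profile's analytic phase is not uniform in time (non-sinusoidal
  waveform), so its CRP has a deterministic within-cycle excursion of
  ~20°; MRP remains an accurate lag estimator but its absolute value
  carries a task-specific offset of ~1°.
- The arithmetic MRP is misleading for couplings near ±180°; use the
  circular variant there.
- SampEn values are sampling-frequency dependent; compare them only at
  equal rates (N and rate are reported alongside).
- The two-group dominance comparison ignores pairing, which is
  conservative when legs correlate positively.
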