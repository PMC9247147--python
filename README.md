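# crpcoord

Interlimb coordination-variability analysis for cyclic lower-limb
movements: from shank and thigh segment-angle time series to continuous
relative phase (CRP), linear variability (sdMRP), nonlinear variability
(sample entropy of the concatenated CRP), and nonparametric comparisons
across tasks and leg dominance.

**Who it is for.**  Biomechanists and movement scientists analysing
repeated unilateral tasks — unilateral sit-to-stand (UniSTS), step-up
(SU), continuous forward hop (Hop) — recorded as sagittal-plane segment
angles (e.g. from inertial sensors at ~60 Hz), and anyone needing a
tested CRP/SampEn reference implementation with a synthetic-kinematics
generator for method validation.

## The measures

For each repetition, each segment angle θ(t) is centered by midrange
removal (θ_c = θ − min θ − (max θ − min θ)/2), transformed into the
analytic signal ζ(t) = θ_c(t) + i·H[θ_c](t) by the Hilbert transform, and
assigned the instantaneous phase φ(t) = ∠ζ(t).  The continuous relative
phase is

&nbsp;&nbsp;&nbsp;&nbsp;CRP(tᵢ) = φ_shank(tᵢ) − φ_thigh(tᵢ), wrapped to (−180°, 180°],

with 0° fully in-phase and ±180° fully anti-phase.  Per recording:

- **MRP** — mean CRP over each repetition's interior;
- **sdMRP** — sample SD of the MRPs across repetitions (linear
  coordination variability);
- **SampEn CRP** — sample entropy SampEn(m, r, N) = −ln(A/B) of the
  concatenation X = [CRP₁; CRP₂; CRP₃], with m = 2, r = 0.2·SD(X),
  Chebyshev distance (nonlinear variability; 0 for a periodic signal,
  above 1 for pattern-free noise).

Cohort statistics: Friedman omnibus per leg × measure, pairwise Wilcoxon
signed-rank (normal approximation, no continuity correction) with effect
size r = |Z|/√n, bootstrap median CIs, and Kruskal–Wallis for dominant
vs nondominant legs.  See `docs/methods.md` for assumptions, edge
handling and design choices.

## Worked example

Simulate a 14-participant cohort at the default task contrasts (step-up
has the smallest repetition-to-repetition lag spread, hop the largest
within-cycle irregularity) and run the full analysis:

```python
from crpcoord import RunConfig, run_analysis

report, results = run_analysis(RunConfig(mode="synthetic",
                                         n_participants=14, seed=7))
print(results.groupby("task")[["sd_mrp", "sampen"]].median().round(2))
for o in report.omnibus:
    print(f"{o.leg} {o.measure}: chi2({o.df}) = {o.chi2:.2f}, p = {o.p:.3g}")
```

prints

```
        sd_mrp  sampen
task
Hop       5.05    0.80
SU        3.52    0.32
UniSTS    5.16    0.32

left sd_mrp: chi2(2) = 5.29, p = 0.0712
left sampen: chi2(2) = 21.14, p = 2.56e-05
right sd_mrp: chi2(2) = 5.29, p = 0.0712
right sampen: chi2(2) = 21.14, p = 2.56e-05
```

The medians show the expected pattern: linear variability (sdMRP, in
degrees) is lowest in the step-up, and nonlinear variability (SampEn,
dimensionless) is highest in the hop.  The pairwise contrasts carry the
detail, e.g. on the right leg:

```
right sampen Hop vs SU:     Z = 3.30, p = 0.000982, r = 0.88 (large)
right sampen Hop vs UniSTS: Z = 3.30, p = 0.000982, r = 0.88 (large)
right sd_mrp SU vs UniSTS:  Z = -2.10, p = 0.0355,  r = 0.56 (large)
```

The same pipeline runs from the command line:

```sh
crpcoord simulate --n-participants 14 --seed 7 --out cohort/
crpcoord analyze --mode files --input-dir cohort/ --out results/
crpcoord figures --seed 7 --out results/
```

File mode reads plain delimited text with columns
`{participant, task, side, dominance, repetition, time_s, segment,
angle_deg}`; outputs are delimited tables plus a JSON manifest (config,
seed, versions) that reproduces any run byte-identically.

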