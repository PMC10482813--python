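# Methods

This note records the models, parameter choices and numerical decisions
behind `pao2osc`, and what the synthetic experiments do and do not show.

## Canonical grid and units

The analysis grid is one aggregate breath of 600 samples at 10 Hz
(dt = 0.1 s), inspiration occupying the first third (I:E = 1:2). All
PaO2 values are carried in mmHg; kPa inputs are converted at
7.50062 mmHg/kPa on read. A configurable respiratory-rate parameter
rescales the grid length (`600·10/rr`), but every experiment in this
package uses the canonical grid.

## Synthetic signal model

A condition's within-breath morphology is a unit-variance template

    T(t) = a·cos(2πτ) + w₂·cos(4πτ + φ₂) + w₃·cos(6πτ + φ₃),  τ = t/60 − 1/3,

standardized over the breath, where `a = 1 − 2θ` interpolates from the
ventilation-dependent shape (θ = 0, peak exactly at end-inspiration) to
its inversion (θ = 1), the second harmonic creates the biphasic
two-peaks-per-breath intermediates, and the third harmonic carries the
finer late-breath structure. The template family is phenomenological:
no recruitment/perfusion mechanism is modelled, and the harmonic form of
the intermediate shapes is this package's proxy, not an empirical claim.

**Archetypes.** Five archetypes (progression ranks 1–5) are fixed unit
vectors in the harmonic-coefficient basis (cos1, cos2, sin2, cos3,
sin3). Their across-rank coefficient patterns follow linear, quadratic,
cubic and quartic contrasts, so the five mean shapes span four
directions; per-condition jitter (SD 0.04 on the first four coordinates,
0.37 on the third-harmonic sine) adds a fifth, within-cluster direction.
This geometry was chosen so that a 75-condition cohort reproduces the
qualitative findings the pipeline is designed to exhibit: five
components needed for ≥ 95% of variance, a dominant first component
(~55% share), and five recoverable clusters whose first-component scores
are nearly linear in the progression rank. With only a fundamental and
one extra harmonic the shape family would span at most three dimensions
and a five-component structure would be impossible — that is why the
third harmonic exists in the model.

**Trace assembly.** Each condition's 10 Hz record is: 10 tidal breaths,
a 20 s end-expiratory breath hold (airway pressure parked at PEEP), and
10 post-restart breaths. PaO2 follows the ventilator phase at
`t − true_offset` (default lag 1.2 s, cohort draws N(1.23, 0.23²)
clipped to [0.4, 3] s), so the hold decline and the post-restart
recovery both start one lag after the corresponding pressure event. The
hold decline is linear at 2.5 mmHg/s (≈ 50 mmHg over the hold,
consistent with rapid desaturation at high shunt during apnoea; large
enough that the recovery upstroke dominates the within-breath phase
value for every morphology). Recovery is exponential with τ = 4 s, with
the oscillation ramped back in over two breaths. Airway pressure is an
ideal pressure-control square wave with driving pressure 1.4·VT/kg
(×1.25 if lavage-injured).

**Noise dial.** Requested SNR (dB) fixes the total residual budget
R = A²·10^(−SNR/10) relative to the oscillation amplitude A. Cardiac
ripple (default 5% of A, rate uniform in 110–146/min) is budgeted into R
(capped at 25% of it) and white Gaussian noise supplies the remainder,
so the generator's dial and the pipeline's SNR estimator agree by
construction; measured agreement is within ±1 dB over 10–40 dB.
Exclusion-violating conditions are produced by parking the mean just
above 100 mmHg (trough), forcing SNR to 15 dB (snr), or suppressing the
post-restart recovery entirely (unalignable).

## Alignment offset estimation

The breath-hold decline is fitted by OLS over its last 5 s. A change
point exists if ≥ 5 consecutive post-restart samples exceed the
extrapolated decline line by 3 residual SDs. The reported offset comes
from a piecewise fit on the sample grid: candidate kinks score pre-kink
samples against the fixed decline line and the following 5 s against a
rise segment anchored on the decline line at the kink (continuity) with
free slope and curvature; the candidate minimizing the mean squared
error wins. Noisy recoveries are pre-smoothed with a 0.5 s moving
average; noise-free input is scored raw, so an exact piecewise-linear
kink is recovered exactly. Candidates whose rise slope is below
1 mmHg/s are invalid — a recovery that never rises yields no offset and
the condition is unalignable. Offsets outside [0.2, 5] s are rejected.
Calibration on synthetic traces: |error| ≤ 0.2 s in ≥ 90% of seeds at
20 dB and ~98% at 30 dB, with bias under 0.08 s.

The curvature term and the anchored fit are deliberate departures from
a naive "first threshold crossing" rule, whose detection latency
(≈ 3σ / rise slope) would exceed 0.2 s at 20 dB.

## Preprocessing details

* The ten breaths are taken from tidal ventilation immediately before
  the hold, the offset applied retrospectively and rounded to the
  nearest sample.
* The linear trend is removed by OLS over the concatenated 6000-sample
  series (output has exactly zero OLS slope and zero mean). Note that on
  an integer number of breaths, OLS picks up a spurious slope
  12·A·sin(φ)/(ω·L²) from the periodic component itself; this shifts
  breath means by up to ±2 mmHg but cancels in the median aggregate.
* SNR = 10·log₁₀(Var_t(median breath) / Var(residuals)), residuals being
  each detrended breath minus the median breath with the breath's
  residual mean removed (breath-to-breath baseline offsets are drift,
  not noise that impairs respiratory-rate detection), capped at +60 dB.
* Exclusion reasons are evaluated in the fixed order trough → SNR →
  alignment; the trough threshold is strict (`< 100 mmHg`), evaluated on
  the raw extracted segment before detrending.

## FPCA

Curves live on a dense common grid, so the covariance operator
discretizes exactly: the model is the SVD of the centred data matrix
scaled by √dt, with 1/(n−1) covariance normalization. Eigenfunctions are
unit-norm in L2(dt); scores are dt-weighted inner products and their
per-component variance equals the eigenvalue. No smoothing is applied —
median aggregation has already denoised the curves — though `fit_fpca`
accepts a pre-smoothing hook. Eigenfunction signs are fixed by making
each function's largest-magnitude element positive; components below
1e−12 of the leading eigenvalue are dropped. The brute-force reference
(explicit eigendecomposition of the p×p covariance) is kept in the test
suite and must agree to 1e−8.

## Clustering

`kmeans_hw` implements Hartigan–Wong optimal-transfer updates (costs
n/(n−1) and n/(n+1) on removal/insertion) from random data-point
initializations, best-of-`n_starts` by WCSS, compiled with numba. An
empty cluster is re-seeded from the point farthest from its center;
singletons never transfer (their removal cost is infinite). Exhaustive
partition enumeration on ≤ 9 points is the test-suite oracle.

AIC = WCSS + 2·m·k with m = number of retained components. Scores are
not standardized before clustering, preserving FPCA's variance ranking.
`select_k_monte_carlo` runs `n_iterations` (default 10,000) independent
single-start runs per candidate k — across-initialization variability is
the quantity of interest, so no restarting inside an iteration — and
records mean and SD of the AIC. The cluster count is the **largest k
whose mean AIC lies within one pooled SD of the minimum** (configurable
to strict minimum): single-start k-means on well-separated data lands in
local optima often enough that neighbouring k are statistically
indistinguishable, and the richer solution is preferred up to the
retained dimensionality. k ranges over 1…K (a zero-cluster model is
undefined for k-means).

Final clusters (best of 100 starts) are ranked by mean first-component
score; when member curves are available the direction is normalized so
rank 1 is the cluster whose mean curve is inspiration-peaked.

## Statistics

Progression rank enters all models as a continuous 1…K variable.
Omnibus tests are classical one-way ANOVA and Pearson chi-square without
continuity correction; no post-hoc pairwise testing and no multiple-
testing correction across covariate rows (flagged in the table
metadata). The mixed model is a random-intercept-per-animal linear model
fitted by REML (statsmodels MixedLM); a single animal or a boundary
variance estimate is flagged singular rather than raised, and AIC-guided
fixed-effect selection enumerates all subsets (≤ 10 candidates) under ML
for comparability. Mechanical power uses the simplified pressure-control
formula 0.098·RR·VT·(ΔPinsp + PEEP) in J/min.

Covariate simulation is linear in θ plus a per-animal random intercept
plus Gaussian noise (defaults: PaO2/FiO2 44 − 19·θ kPa, PPV 12 + 8·θ %,
cardiac output 4.7 + 0.3·θ L/min); a separate outcome generator drives
the mixed-model recovery experiments (rank = linear(covariates) +
animal intercept + noise). With 7 animals the REML SD estimate has ≈ 29%
sampling error, so recovery is assessed on the median across 20 refits.

## Problem sizes and determinism

The recovery experiments use 20 cohorts of 75 conditions (5 archetypes ×
15) at 30 dB with the Monte-Carlo selection at 1,000 iterations per k —
sizes at which the full suite completes in well under a minute per
experiment while the Monte-Carlo means are stable to ≪ 1%. Every
generator and every stochastic stage takes an explicit seed; the
pipeline expands one master seed into fixed per-stage streams (SHA-256
of "seed:stage"), and a rerun with the same config is bit-identical.

## What the synthetic experiments do not show

The generator emulates the study conditions (sampling, breath timing,
amplitudes, noise, exclusion modes), not porcine physiology: morphology
templates are harmonic proxies, cardiac ripple is a pure sinusoid,
breath-to-breath variability beyond the modelled jitter is absent, and
covariate–morphology couplings are linear by construction. Passing
recovery tests therefore validates the *pipeline* — alignment,
aggregation, FPCA, cluster-count selection, progression statistics — on
signals with known truth; it does not re-establish any physiological
finding. Reference values reported from the original animal experiments
(e.g. a first component explaining 56.9% of variance, a progression
regression R² of 0.88, a 0.74-cluster animal-intercept SD) are tied to
recordings that are not publicly available and are treated as
qualitative anchors only.

## Known limitations

* Single respiratory rate per cohort; no resampling between rates.
* No haemoglobin-buffering damping of low-PaO2 signals (such conditions
  are excluded, as in the analysis the pipeline follows).
* k-means with a progression ordering approximates what is plausibly a
  continuum; soft or ordinal models are out of scope.
* The two-line alignment assumes the ventilation-to-PaO2 lag measured at
  the breath hold transfers to tidal breathing.
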