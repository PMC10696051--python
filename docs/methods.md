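# Methods

This note records the models implemented in `tempovar`, the numerical
choices behind them, what the synthetic data do and do not emulate, and the
design decisions taken where more than one reasonable option existed.  All
rates are per hour and FPTs in hours internally; division-time laws are
parameterized in minutes (lab convention); the CLI converts units
explicitly.

## Exact simple-birth-process statistics (`sbp_exact`)

The abundance law of the simple birth process started from n₀ cells is a
shifted negative binomial,
P_t(n|n₀) = C(n−1, n₀−1) e^{−μn₀t} (1−e^{−μt})^{n−n₀}, with mean n₀e^{μt}
and variance n₀e^{μt}(e^{μt}−1).  Because abundance paths are monotone, the
probability of having reached Ω by time t equals the FPT CDF; it is
evaluated through the negative-binomial survival function (a regularized
incomplete beta), which is exact and O(1) in Ω rather than an Ω-term sum.
The FPT density μ(Ω−n₀)C(Ω−1,n₀−1)e^{−μn₀t}(1−e^{−μt})^{Ω−n₀−1} and the
pmf are evaluated in log space (log-gamma arithmetic) so that thresholds in
the hundreds or thousands do not overflow; the pmf returns an exact 0 (not
underflow noise) below the inoculum.

FPT moments are partial harmonic and inverse-square sums.  Below Ω = 1000
they are formed by direct summation (transparent and exactly equal to the
definition); above, as digamma/trigamma differences, which are exact to
machine precision and make Ω = 2×10⁷ (the milk example) or larger free.
The two code paths agree to 1 part in 10¹² at the switchover (tested).

## Zero-truncated Poisson inocula (`poisson_inocula`)

With inoculum M ~ Poisson(n₀) conditioned on M ≥ 1 and deterministic
growth, T(M) = ln(Ω/M)/μ, so σ_t = SD(ln M)/μ exactly; the threshold
cancels.  The series for E[ln M] and E[ln²M] is truncated at
k_max = n₀ + 12√n₀ + 60, past which the remaining mass is below machine
precision for any shape up to ~10³ (the computed normalization is checked
against 1 and the function raises if mass is missing).  Natural logs are
used throughout, consistent with the 1/μ prefactors.

The delta-method approximations are mean ≈ ln(Ω/n₀)/μ + 1/(2μn₀) (the
second-order correction is exposed separately so each order can be tested)
and variance ≈ 1/(μ²n₀).  The relative error of the variance approximation
is ~1.7/n₀ (measured: 8.6% at shape 20, 4.0% at 40, 1.9% at 80, validated
against the exact series and Monte Carlo); a warning is emitted below
shape 5, where the expansion is qualitative at best.  Convergence of the
exact TSD to the 1/(μ√n₀) asymptote is from above and monotone in the
shape.

## Simulators (`simulate`)

*SBP first-passage sampling* uses the Markov decomposition — the FPT is
Σ Exp(μn) over n from the inoculum to Ω−1 — rather than event-by-event
simulation; it is exact, vectorized, and processed in chunks so memory
stays bounded for large replicate counts.

*Age-structured (Bellman–Harris) sampling* is an event-queue (binary heap)
simulation: each division removes one individual and inserts two with
fresh division-time draws; the FPT is the time of the division that first
brings the count to Ω.  Counts change only at events, so no interpolation
is involved.  Division times are Erlang(k, mean/k) — the k-stage
interpretation of a χ²(2k) law rescaled to the requested mean, CV = 1/√k.
Inoculated individuals sit at a random point of their division cycle:
their first division is uniform on one doubling window [0, ln2/μ_eff] with
μ_eff = ln2/(mean division time), drawn independently per individual.  Two
alternative initial phases are available: `exponential` (memoryless start,
which makes the k=1 law exactly a simple birth process — used as a
cross-validation between the two independent simulator implementations)
and `zero` (a fresh full cycle).  Ties between simultaneous events have
probability zero; the heap breaks them by insertion order.

*Zero-truncated Poisson inocula* are drawn by inverse CDF (mapping uniforms
into [P(0), 1] and applying the Poisson quantile function), which is exact
and reproducible at any shape, unlike rejection sampling.

*Two-step model*: SBP growth to a switch time t, deterministic afterwards.
The abundance at the switch is sampled as a sum of n₀ geometric variables
(the per-lineage SBP abundance law), and the FPT is ln(Ω/N(t))/μ.  Its
leading-order variance (1−e^{−μt})/(μ²n₀) reaches half the asymptotic
1/(μ²n₀) after exactly one doubling time — temporal variance accumulates
while populations are small, which is also why the noise encodes the
early growth rate.

Reference protocol (`protocols.five_model_tsd_table`): threshold Ω = 500,
rate μ = 1.66/hr (25-min division time), 20-stage law, every integer
inoculum 1–30, 2000 replicates per point.  The TSD-versus-inoculum slope in
log-log coordinates is −0.5 ± 0.1 for all five inoculation/growth
combinations on this dense grid.  Two caveats established by exact
computation: models with Poisson inocula flatten below shape ≈ 3 (zero
truncation suppresses inoculum variability), and the SBP-with-Poisson
combination runs ~−0.6 locally at moderate inocula because the O(1/n₀)
corrections of growth and inoculum noise add; the dense integer grid, where
large-inoculum points dominate the fit as in the reference comparison,
recovers the asymptotic −1/2 law for every model.

## Estimation (`estimate`)

Threshold-crossing times are linearly interpolated between the bracketing
samples of each trajectory; with 2–3-min read intervals, sample-and-hold
would bias crossing times by up to one interval, which is material against
TSDs of ~0.1 h.  Trajectories that never cross are excluded and counted
(warning above 10% exclusions, error at 100%).

TSD uses the n−1 denominator.  Uncertainty is a percentile bootstrap with
a fixed seed — the simplest reproducible choice; default levels are 95%
for simulation comparisons and 68% for empirical TSDs and growth-rate
estimates.  The estimator μ̂ = (Σ_{n=n₀}^{Ω−1} 1/n²)^{1/2}/σ_t is the exact
inverse of the SBP TSD relation (tested as an identity); when the measured
TSD contains additional dispersive noise μ̂ underestimates μ, and on
sub-SBP-dispersion data (tight division-time laws) it overestimates —
both directions are exercised in tests.  `precision_curve` reports, per
subsample size m, the median and percentile interval of μ̂ over bootstrap
resamples of size m (default 5000 resamples), alongside the full-sample
point estimate.

## Plate pipeline (`plate_pipeline`)

The measurement background (light occluded by medium and plate, not cells)
is the mean OD across all wells at time 0, per plate, subtracted from every
reading; the operation recomputes from the raw matrix and is idempotent.
QC flags wells whose *raw* OD600 exceeds 0.125 at 1 h (condensation or
misread); anaerobic or contaminated wells cannot be detected automatically
and enter through a manual exclusion list.  Growth rates are OLS slopes of
ln(corrected OD) over a 30-min window centered on the well's crossing of a
threshold OD (default 0.03); corrected ODs ≤ 0 are masked for the log,
never clipped.  Pooling weights wells equally across replicates and
inoculum groups.  TSD-versus-threshold tables compose crossing-time
extraction with the bootstrap TSD over a log-spaced OD grid (default
0.01–0.3), per inoculum group.  The OD↔CFU standard curve is a linear
least-squares fit valid only over its calibration OD range (warning
outside).

The lag-phase check compares the no-lag deterministic prediction
t_det = ln(Ω_CFU/n₀)/μ with the mean observed crossing time.  Note a model
fact with practical consequences: for zero-lag *stochastic* growth the mean
FPT exceeds t_det (by ≈ γ_Euler/μ at n₀ = 1, by ≈ 1/(2μn₀) generally), so
Δ = t_det − observed is slightly *negative* under the pure growth models;
a substantial positive Δ in data therefore cannot come from these models,
and a true lag phase pushes Δ down by the lag duration (both behaviours
are tested on constructed fixtures).

## Synthetic plates (`synthetic_fixtures`)

Each well draws a Poisson (optionally exact) inoculum, simulates stochastic
growth at event level up to a switch abundance of 1000 cells, and continues
deterministically at the model's asymptotic rate (the renewal Malthusian
rate for age-structured growth).  This hybrid is justified by the
variance-accumulation result: contributions to temporal variance fall off
as the inverse square of the population size, so event-level noise beyond
~10³ cells is negligible against the retained part, while OD-scale
thresholds (10⁶–10⁸ cells) become reachable.  Abundance is mapped to OD
through a linear coefficient anchored at OD 0.03 = 1.4×10⁷ CFU, plus a
per-plate constant baseline (default 0.110, within the empirically
observed 0.099–0.121 range) and additive Gaussian read noise at the 0.001
instrument resolution.  Saturation is a C¹ exponential approach to the
carrying capacity above 40% of it — a fixture choice emulating the
slowdown above OD ≈ 0.2, not a mechanistic claim.  Zero-inoculum wells
stay at baseline, as in real plates, and the pipeline drops and counts
them.  Ground truth (true rate, per-well inocula, noiseless OD matrix) is
returned alongside every plate.

What the fixtures deliberately do not emulate: condensation artifacts,
evaporation, well-position effects, Beer–Lambert nonlinearity at high OD,
mother–daughter division-time correlations, and lag-phase biology beyond a
configurable fixed delay.  Tests passing on these fixtures show the
pipeline's statistics are correct under the stated noise model; they do
not certify behaviour under instrument pathologies.

## Desynchronization (`desync`)

For an Erlang(k) division-time law with mean τ, the renewal characteristic
equation 2(1+θs)^{−k} = 1 (θ = τ/k) has closed-form roots
s_j = (2^{1/k}e^{2πij/k} − 1)/θ.  The real root s₀ is the Malthusian rate
(k(2^{1/k}−1)/τ, decreasing to ln2/τ from above as k→∞); the j = ±1 pair
governs oscillations, whose relative amplitude decays by
exp[(Re s₁ − s₀)τ] per division cycle.  For k = 1 there is a single pole
and no oscillation.  "Asymptotically exponential" is operationalized as
relative amplitude < 5% — a documented choice, exposed as a parameter —
which for the 20-stage, 25-min law gives ≈ 3 division cycles.  A
time-domain cross-check integrates the renewal equation
b(t) = 2f(t) + 2(f∗b)(t) by trapezoidal convolution from a synchronized
cohort and verifies that the peak envelope of b(t)e^{−s₀t} decays per
oscillation period at the pole-gap rate within 5%, and that the late-time
log-slope of b equals s₀.

## Problem sizes and reproducibility

Simulation sizes used by the test suite and acceptance script were chosen
so that Monte-Carlo standard errors sit well below the tolerances they
feed (10⁵ replicates for moment checks against closed forms, 2000
replicates per point for the five-model comparison, ≥4-SE acceptance
bands for stochastic comparisons).  Every stochastic routine takes an
explicit integer seed and is bit-reproducible for a fixed (seed, config)
pair; statistical tests use fixed seeds and tolerance bands derived from
the sample's own moments (including fourth-moment-based standard errors
for variance comparisons).
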