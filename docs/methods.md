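# Methods

This note records the modelling choices behind tqtpipe: what each stage
assumes, the defaults and why, what the synthetic-trial generator does and
does not emulate, and the numerical decisions that matter.

## Trial structure and the synthetic generator

The generator reproduces the design of a single-dose, nested-crossover TQT
study: four sequences randomized 2:2:1:4 (defaults 14/14/7/28 subjects),
two periods separated by a 7-day washout. Sequences 1/2 cross moxifloxacin
400 mg with placebo, sequence 3 is placebo/placebo, and sequence 4 doses
islatravir 0.75 mg in period 1 and 240 mg in period 2. Triplicate ECGs are
extracted at three pre-dose times (−20, −10, −5 min) and at 0.5, 1, 1.5, 2,
3, 4, 8, 12 and 24 h post-dose; PK is sampled pre-dose and at the same
post-dose times plus 96 and 168 h.

**PK.** One-compartment first-order absorption,
C(t) = (F·D/V)·ka/(ka−ke)·(e^(−ke·t) − e^(−ka·t)), with log-normal
between-subject variability (default CV 35%) applied to clearance and
volume as subject-level properties, and 10% proportional assay error.
Islatravir defaults (ka = 3.2 h⁻¹, ke = 0.15 h⁻¹, V/F = 184 L) reproduce
the published exposure scale for 240 mg — GM Cmax ≈ 3.8 µM at Tmax ≈ 1 h
and AUC0–inf ≈ 30 h·µM. A single compartment cannot simultaneously match
that Cmax/AUC ratio and the published AUC0–24/AUC0–inf fraction (~0.71; the
real profile is multiphasic), so the calibration privileges Cmax, Tmax and
AUC0–inf; simulated AUC0–24 sits closer to AUC0–inf than observed. M4 is
generated as a fixed 0.29 fraction of the parent concentration (matching
the reported ~threefold lower exposure) with its own 0.5 ng/mL LLOQ, which
makes the 0.75-mg M4 profile quantifiable only through roughly 4 h, so
terminal-phase parameters are not calculable for part of that arm.
Moxifloxacin (ka = 1.4 h⁻¹, ke = 0.058 h⁻¹, V/F = 191 L, reported in
ng/mL) gives GM Cmax ≈ 1,830 ng/mL at Tmax ≈ 2.4 h. ka = ke is a removable
singularity, handled by an epsilon perturbation of ke.

**QT.** QT = µ·RR^α + b_subject + b_period + A·cos(2πt/24) + θ·C(t) + ε per
replicate, with RR shared across a triplicate. Defaults: µ = 400 ms at
RR = 1 s, α = 0.3754, between-subject SD 12 ms, between-period SD 5 ms,
replicate residual SD 6 ms, circadian amplitude 3 ms (phase fixed at dosing
time — the simplest structure that keeps the time-point fixed effect
non-degenerate), RR log-normal with median 0.9 s and ~10% spread, truncated
to 0.6–1.5 s. The lower truncation keeps heart rate at or below 100 bpm so
the healthy-volunteer arms stay inside the categorical flag thresholds by
construction. The concentration slope θ is the only treatment-specific
physiological parameter: 0 for islatravir by default, and for moxifloxacin
14 ms divided by the typical GM Cmax (≈ 0.00765 ms per ng/mL), placing the
positive-control effect at ~14 ms at Cmax. PR and QRS are generated within
physiological ranges and capped below their flag thresholds; heart rate is
60000/RR exactly.

What the generator does *not* emulate: dropout and discontinuation,
QT/RR hysteresis or drug-effect delay, food or covariate effects on PK,
multiphasic distribution, T/U-wave morphology beyond a constant flag rate,
and any assay drift. Passing tests therefore demonstrate that the analysis
chain recovers the truth of *this* data-generating process at the study's
size and noise scale — not that it is robust to those real-data features.

## QT correction and adequacy

Triplicates are aggregated by arithmetic mean (the common TQT convention
for summarizing an extraction window). The correction exponent is the
pooled OLS slope of ln QT on ln RR (RR in seconds, natural logs, so the
intercept is QT at RR = 1 s and the exponent is on the conventional scale)
over the drug-free set: all placebo observations plus all pre-dose
observations from every arm. Pooling across subjects is the default; a
per-subject random-intercept variant is available
(`derive_population_exponent_mixed`) but off by default, as the pooled
regression is what a single drug-free QT-vs-RR regression line depicts.
Whether post-washout pre-dose points belong in the drug-free set is
configurable (`include_predose`); they are included by default.

Adequacy regresses QTc (ms) on RR (ms) over the same drug-free set and
declares the correction adequate when the two-sided 95% CI (t quantiles,
n−2 df) of the slope contains zero. A degenerate zero-residual fit (QTc
exactly constant) collapses the CI to a point; a small absolute guard
(1e−10 on the slope scale) prevents floating-point noise from deciding
adequacy there. Baselines are period-specific (mean of that period's three
pre-dose aggregated values), so period effects cancel within ΔQTcP.

## Noncompartmental PK

BLQ samples before the first quantifiable concentration are set to zero;
embedded or terminal BLQ samples are treated as missing. Values exactly at
the LLOQ are quantifiable. AUC uses the linear trapezoid on ascending or
tied segments and the log trapezoid on strictly descending positive
segments; window endpoints off the grid are interpolated with the same
segment rule, which makes adjacent windows exactly additive. λz candidates
are all runs of ≥3 consecutive points strictly after Tmax through the last
quantifiable sample; the run maximizing adjusted R² wins, ties to the
larger run; fewer than three eligible points leaves λz and the
extrapolation-dependent quantities not calculable. Extrapolation uses the
regression-predicted concentration at t_last (not the observed one).

Numerical fidelity: log-down integration is exact on monoexponential
decline, so sampled AUC matches dense integration to well under 0.5% there.
On an absorption profile with Tmax ≈ 1 h, the 0.5-h early sampling spacing
leaves the linear chords ~1% under the true area — an irreducible property
of the schedule, not of the integrator — which is why the oral-profile
checks carry a 1.5% tolerance while the monoexponential checks are tight.

## Concentration-QTc model

One pooled model with placebo as reference: fixed effects for treatment,
time point, centered baseline QTcP, and one concentration column per
analyte (islatravir in µM, moxifloxacin in ng/mL), each with its own slope.
Separate slopes are used because the two analytes are measured in different
units on scales ~500× apart; a single shared slope across both would be
dimensionally meaningless. Both islatravir doses share the islatravir
slope. Concentrations are time-matched to the ECG schedule through 24 h;
BLQ matches count as zero and rows without a matched sample are dropped
and logged.

"Double compound symmetry" is implemented as two nested exchangeable
levels — subject, and subject-by-period — plus an independent residual
(V = σ²_s·J + σ²_sp·blockdiag(J_p) + σ²_e·I per subject). A Kronecker
CS⊗CS structure is a plausible alternative reading but is not implemented.
REML estimation maximizes the restricted likelihood over the three
log-variances with L-BFGS-B from three dispersed starts (a boundary
component simply runs to the lower bound and is reported as zero);
convergence is reported, never silently ignored. Fixed effects and their
covariance are the GLS solution at the converged components. Identical
per-subject block patterns are factored once per pattern, which keeps a
63-subject fit around 0.1 s and makes thousand-replicate simulation studies
practical. The implementation is validated against statsmodels' MixedLM
(variance components and coefficients to ~1e−4, REML log-likelihood to
1e−4) and against a brute-force grid maximizer of the same criterion on a
small balanced instance.

Degrees of freedom for all t quantiles are residual (N − rank(X));
Satterthwaite or Kenward-Roger adjustments are out of scope and would
produce slightly wider intervals in small samples. ΔΔQTcP at a reference
concentration is β_T + β_conc·c_ref with SE from the quadratic form over
the fixed-effect covariance; the two-sided 90% CI limits are the one-sided
95% bounds (upper for test drugs, lower for the positive control). The
primary model excludes treatment-by-time interaction; the by-time-point
analysis adds it (and drops the concentration terms) and reports per-time
LSM differences from placebo with 90% CIs. Decision thresholds are strict:
"< 10 ms" and "> 5 ms" exactly as printed, so a bound of exactly 10 ms is
not negative and exactly 5 ms does not confirm sensitivity.

Known small biases accepted by design: the model regresses on *measured*
concentrations while the generator's QT effect uses true concentrations, so
a 10% assay CV attenuates recovered slopes by ~2%; the observed GM Cmax is
a maximum over noisy samples and so sits a few percent above the true
typical Cmax. Both effects are visible in, and bounded by, the simulation
acceptance checks.

## Problem sizes and tolerances in the test suite

Simulation-based checks use the study's own size (63 subjects) throughout:
200 replicate trials for exponent recovery and adequacy behaviour, 500 for
slope recovery and SE calibration, and 1,000 for one-sided coverage and
positive-control power, with Monte-Carlo tolerances stated per test (±0.01
on the mean exponent, ±5% on the mean slope, ±2 points on 95% coverage).
Unit-level oracles are exact or near machine precision. Hypothesis
property tests run derandomized with fixed profiles.

## Categorical safety

Flags use strict comparisons (HR > 100 bpm, PR > 220 ms, QRS > 110 ms) on
recorded values; heart rate is taken from the HR field with a consistency
warning when it deviates from 60000/RR by more than 2 bpm. Missing values
leave the flag undefined and drop out of that flag's denominator. Counts
are per observation by treatment and time point; a per-participant rollup
can be obtained by grouping the flag table on subject before counting.

## Reporting

All stage outputs are delimited text with the seed recorded in a comment
header; the run summary is a YAML key-value file; no binary outputs are
produced. A fixed exponent (e.g. a previously established 0.3754) can be
supplied through the config, in which case derivation is skipped and
logged, and only adequacy is re-assessed.
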