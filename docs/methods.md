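# Methods

## The monitored process

One record per chronologically ordered case, with three clocks in whole
days: the wet-lab component (sample receipt to sequencing-assay
result), the dry-lab component (assay result to bioinformatics report),
and the overall accession-to-report TAT. Case numbering is 1-based.
The container enforces `overall ≥ max(wet, dry)` wherever both
components are present; wet/dry may be absent (overall-only mode), in
which case component analyses are skipped with a logged notice.

## Learning-curve regressions

Both models regress TAT on case number `j = 1..n` and are intended as
sensitivity analyses for each other: one guards against outliers, the
other respects the count nature and overdispersion of day counts.

**Robust linear.** `TAT_j = β₀ + β₁ j + ε` fitted by IRLS. Residuals
are scaled by the normalized median absolute deviation recomputed at
each iteration; weights are Huber (k = 1.345) until convergence, then
Tukey biweight (c = 4.685) from the Huber solution until convergence.
Points with Cook's distance > 1 under the initial OLS fit are dropped
first; this makes a single gross outlier exactly inert rather than
merely down-weighted. Convergence is a relative coefficient change
below 1e-8, capped at 100 iterations per stage; non-convergence is
flagged (`converged=False`) with the partial result returned. The
standard error is the weighted-least-squares sandwich
`(XᵀWX)⁻¹ Xᵀ W r rᵀ W X (XᵀWX)⁻¹` at the final weights — an asymptotic
approximation; on degenerate inputs (exact lines) it collapses to 0
and the CI collapses to the point estimate.

**Negative binomial (NB2).** `log μ_j = β₀ + β₁ j` with
`Var = μ + μ²/k`, size `k > 0` estimated jointly by maximum
likelihood. The fit alternates Fisher scoring for `(β₀, β₁)` with a
damped Newton step for `log k`, both with step halving so the
log-likelihood is non-decreasing across iterations; starting values
come from a log-scale least-squares line and a moment estimate of `k`.
Wald standard errors use the observed information (central-difference
Hessian in `(β₀, β₁, log k)`; the coefficient block of the inverse is
invariant to the dispersion parameterization). The reported confidence
interval is on the IRR scale — the exponential of the slope CI — so
`exp` of the slope bounds reproduces it exactly. p-values are
two-sided Wald with a normal reference. Validation rejects
non-integer or negative counts and all-zero series.

## Control charts

**CUSUM.** `C_j = Σ_{i≤j} (E − O_i)` with `E` the whole-series mean of
the analyzed component unless overridden. A fixed reference is what
makes the per-case increment `E − O_j` independent of `j` and the
trajectory interpretable: downward drift = observed above reference.
The final value obeys the telescoping identity `C_n = nE − ΣO` (zero
when `E` is the series mean).

**EWMA.** `Z_j = λ O_j + (1 − λ) Z_{j−1}` with `Z_0` the mean of the
first ten observations and the recursion run from case 1, so the chart
spans every case. The default weight is λ = 0.03. A weight of 0.1 is
a reasonable alternative preset for faster tracking; one standard
recursion has a single smoothing parameter, and 0.03 is the package's
default. `Z_j` is a convex combination of observations and `Z_0`, so
the chart is bounded by the observed range, and the weight of the
observation `m` cases back is exactly `λ(1 − λ)^m`.

**Bernoulli LLR charts.** Each case is dichotomized as
`y_j = 1{TAT_j > threshold}` — strictly greater, so a TAT exactly at
the threshold is in control. Default thresholds are 42 days (6 weeks)
for overall TAT and 21 days (3 weeks) for each component, configured
in days to avoid unit ambiguity. The chart accumulates
`y ln R − ln(1 − p₀ + R p₀)`, the log-likelihood ratio of the
odds-shifted alternative `p₁ = R p₀ / (1 − p₀ + R p₀)` against the
baseline `p₀`. Two one-sided charts are reported as a pair:
R = 1.20 (deterioration) and its reciprocal 0.83 (improvement, a 17%
decrease in the odds). `p₀` defaults to the observed exceedance
proportion of the full series — there is no external benchmark rate
for this assay class — and a degenerate all-0/all-1 sequence requires
an explicit `p₀`. Charts are never reset after a signal and never
floored at zero; `signals` records the cases at which |S_j| enters the
out-of-control region.

**Control-limit calibration.** No analytic ARL is attempted for the
unresetted two-sided chart; `calibrate_control_limit` simulates
Bernoulli(p₀) sequences (default 1000, capped at 20× the target ARL;
censored runs count at the cap, making the estimate conservative for
large h) and returns the smallest h on a 0.25-nat grid whose
in-control ARL meets the target. h = 0 signals immediately (ARL 1 by
convention).

## Phase detection

The learning-curve caseload is operationalized as the global CUSUM
minimum (earliest index on ties); a monotone-rising chart yields 1,
i.e. no learning phase. Segmentation smooths the per-case increments
(with `C_0 = 0`) by a centered moving average of width `min_run`
(default 10 cases), labels maximal non-negative runs improving and
negative runs deteriorating, then merges runs shorter than `min_run`
into the neighbour with the larger absolute cumulative chart change
and coalesces equal labels. The `min_run` convention suppresses
single-case noise; it is a stated package convention, and with heavy
smoothing segment boundaries can shift by a few cases relative to the
raw nadir.

## Synthetic generator

Component day counts are independent NB2 draws with
`log μ = β₀ + β₁ j + Σ step shifts`; steps apply from their case index
onward. Overall TAT is wet + dry plus a batching term: consecutive
cases are grouped into blocks of `batch_size` and each block shares
one waiting delay drawn uniformly from 0..`batch_wait_max` days,
modelling samples accumulated and processed together. Waiting accrues
on the overall clock only (the data do not say where queue time sits);
with `batch_size=1`, `batch_wait_max=0` and no steps the generator
reduces to independent NB2 draws. A fixed seed fixes the entire
series bitwise.

Default configuration (the study conditions the package emulates):
365 cases; wet baseline log-mean 3.1 with steps (case 86, −0.45),
(262, +0.3), (311, −0.3); dry baseline 2.95 with step (55, −0.45);
shared learning slope β₁ = −0.0015/case (IRR 0.9985); NB size k = 6;
batches of 5 with up to 10 waiting days. These produce medians of
roughly 26/11/9 days (overall/wet/dry), an early worse-than-average
phase ending in the mid-80s (wet) and mid-50s (dry) of cases, and a
transient deterioration from case 262. The baselines were sized
analytically to the target medians; k = 6 reproduces interquartile
ranges of the observed width.

What the generator does **not** emulate: case-mix covariates (specimen
type, tumor content), calendar effects (weekends, holidays, reagent
lead times), serial correlation beyond batching, or recording
artefacts. Passing tests therefore demonstrate correctness of the
monitoring computations and estimator calibration under a clean
overdispersed-count model, not robustness to every failure mode of
real laboratory data.

A practical caveat established by the package's own experiments: with
realistic overdispersion (k ≈ 6) the CUSUM nadir is a noisy estimator
of a step-change location. The post-step drift of the chart is the
margin between the series mean and the post-step level (≈1–2 days)
against a per-case standard deviation of ≈5 days, so the realized
nadir can trail the true break by several tens of cases in a
substantial minority of runs. Nadir-based caseload comparisons between
teams should be read with that uncertainty in mind.

## Problem sizes

The Monte-Carlo experiments use 200 replicates of 2000-case series for
CI coverage, 400 replicates of 500-case series for the type-I-error
check, and 200 replicates of 365-case series for breakpoint recovery —
sizes at which the sampling error of the estimated rates (≈1.5–2.5
percentage points) is small relative to the properties being checked.

## Pipeline and formats

Input CSV: header `case_index,wet_days,dry_days,overall_days`, UTF-8.
The pipeline never mutates its input; each stage consumes and produces
fresh structures, and any stage failure aborts the run with the stage
name and cause. Reports serialize with sorted keys and no timestamps,
so identical seeds give byte-identical JSON. Chart series are also
written as per-component CSV (`case_index`, CUSUM, EWMA, both LLR
trajectories); the run log records every resolved default. Plot
rendering is deliberately out of scope: the chart values are the
contract, and any plotting front end can consume the CSVs.
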