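# tatspc — statistical process control for laboratory turnaround times

Laboratory turnaround time (TAT) — the days from sample receipt to the
delivered report — is a key performance indicator for sequencing and
bioinformatics services, and its trajectory over consecutive cases
traces the team's *learning curve*. `tatspc` implements the standard
process-control toolkit for that setting, for laboratory directors,
quality teams and biostatisticians monitoring a molecular-profiling
service:

* **Learning-curve regressions** of TAT on chronological case number
  `j = 1..n`, as two mutual sensitivity analyses:
  * a robust M-estimator line `TAT_j = β₀ + β₁ j + ε_j` fitted by
    iteratively reweighted least squares (Huber start, Tukey biweight
    finish), with β₁ in days/case;
  * a negative-binomial (NB2) count regression
    `log E[TAT_j] = β₀ + β₁ j`, `Var = μ + μ²/k`, fitted by maximum
    likelihood; `IRR = exp(β₁)` is the multiplicative change in
    expected TAT per case.
* **CUSUM of residuals** `C_j = Σ_{i≤j} (E − O_i)` against a fixed
  reference `E` (the series mean by default). The chart falls while
  observed TAT exceeds the reference and rises once performance beats
  it; the global minimum (*nadir*) is read as the caseload needed to
  overcome the learning curve, and rising/falling runs are labelled
  improving/deteriorating phases.
* **EWMA** `Z_j = λ O_j + (1 − λ) Z_{j−1}` (λ = 0.03, initialized with
  the mean of the first ten cases) as a smooth local mean TAT.
* **Bernoulli CUSUM log-likelihood-ratio (LLR) charts** on the binary
  event `TAT > threshold` (42 days overall, 21 days per lab
  component), accumulating
  `S_j = Σ y_i ln R − ln(1 − p₀ + R p₀)` for the paired alternatives
  R = 1.20 (20% higher exceedance odds, deterioration) and
  R = 1/1.20 ≈ 0.83 (17% lower odds, improvement); charts are never
  reset, and control limits can be calibrated by Monte-Carlo average
  run length.
* A **seeded synthetic generator** of TAT series with the structure
  such data exhibit — overdispersed counts, a log-linear learning
  trend, step changes at personnel transitions, batch-processing
  waiting time — so the whole pipeline is testable without access to
  any laboratory's case-level records.

## Worked example

```python
from tatspc import (SyntheticConfig, generate_tat_series,
                    fit_negative_binomial, fit_robust_linear,
                    cusum_chart, segment_trends)

series = generate_tat_series(SyntheticConfig(seed=7))
nb = fit_negative_binomial(series, "overall")
rb = fit_robust_linear(series, "overall")
report = segment_trends(cusum_chart(series, "overall"), min_run=10)
```

Running `python examples/learning_curve_regression.py` and
`python examples/control_charts.py` on this series prints, for the
overall component:

```
robust slope -0.0494 days/case (95% CI -0.0572 to -0.0416, p=1.7e-35)
NB IRR 0.99810 (95% CI 0.99778 to 0.99842, p=2e-30, dispersion k=12.4)
overall: CUSUM reference E = 28.1 days
  learning curve overcome after 87 cases (CUSUM nadir)
```

The robust slope says overall TAT shortens by about 0.05 days with
every additional case; the IRR says the same thing multiplicatively
(each case scales expected TAT by ≈0.998, i.e. a ~0.2% reduction). The
CUSUM nadir at case 87 marks where cumulative performance stopped
worsening relative to the series mean of 28.1 days — the caseload the
team needed to overcome its learning curve. The other examples
(`simulate_series.py`, `llr_monitoring.py`) show the generator's
summary statistics and threshold-exceedance monitoring with a
calibrated control limit.

A thin CLI mirrors the same stages:

```bash
tatspc simulate --n-cases 365 --seed 7 --out-dir runs/demo
tatspc report --input runs/demo/series.csv --out-dir runs/demo/report
```

## Layout

| path | contents |
| --- | --- |
| `src/tatspc/series.py` | `TATSeries` container, CSV input/output, validation |
| `src/tatspc/synthetic.py` | seeded generator, batching, ground-truth echo |
| `src/tatspc/regression.py` | robust IRLS and NB2 maximum-likelihood fits |
| `src/tatspc/charts.py` | CUSUM, EWMA, LLR charts, ARL calibration |
| `src/tatspc/phases.py` | nadir, learning caseload, phase segmentation |
| `src/tatspc/pipeline.py` | full per-component analysis, JSON/CSV reports |
| `src/tatspc/cli.py` | `tatspc` command-line entry point |
| `docs/methods.md` | model assumptions, defaults, numerical choices |
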