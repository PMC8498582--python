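"""CUSUM and EWMA charts with learning-curve phase detection.

The CUSUM accumulates (expected - observed) TAT: it falls while the lab
is slower than its long-run mean and rises once it is faster, so the
global minimum (nadir) marks the case at which the learning curve was
overcome.  The EWMA tracks a smoothed local mean TAT.
"""

from tatspc import (
    SyntheticConfig,
    cusum_chart,
    ewma_chart,
    generate_tat_series,
    segment_trends,
)

series = generate_tat_series(SyntheticConfig(seed=7))

for component in ("overall", "wet", "dry"):
    chart = cusum_chart(series, component)  # reference E = series mean
    report = segment_trends(chart, min_run=10)
    ewma = ewma_chart(series, component, lam=0.03)
    print(f"{component}: CUSUM reference E = {chart.expected:.1f} days")
    print(
        f"  learning curve overcome after {report.learning_caseload} cases "
        f"(CUSUM nadir)"
    )
    for start, end, label in report.segments:
        print(f"  cases {start:3d}-{end:3d}: {label}")
    print(
        f"  EWMA (lam=0.03) starts at {ewma.z0:.1f} days and ends at "
        f"{ewma.values[-1]:.1f} days"
    )
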