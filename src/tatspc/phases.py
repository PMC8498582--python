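"""Learning-curve phase detection from a CUSUM trajectory.

The CUSUM of expected-minus-observed TAT falls while performance is
worse than the reference and rises while it is better.  Its global
minimum — the *nadir* — is therefore read as the case at which the team
overcame its learning curve, and maximal runs of rising/falling chart
are labelled improving/deteriorating phases.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .charts import CUSUMChart
from .series import ValidationError

__all__ = ["PhaseReport", "find_nadir", "segment_trends", "learning_curve_caseload"]

DEFAULT_MIN_RUN = 10

IMPROVING = "improving"
DETERIORATING = "deteriorating"


@dataclass(frozen=True)
class PhaseReport:
    """Learning-curve summary of one CUSUM chart.

    ``segments`` is an ordered list of ``(start_case, end_case, label)``
    triples partitioning case 1..n; adjacent segments always carry
    different labels.  ``learning_caseload`` equals ``nadir_case``: the
    number of cases taken to overcome the learning curve.
    """

    nadir_case: int
    learning_caseload: int
    segments: tuple[tuple[int, int, str], ...]
    min_run: int
    component: str = "overall"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segments"] = [list(s) for s in self.segments]
        return d


def find_nadir(chart: CUSUMChart) -> int:
    """1-based case index of the chart's global minimum (earliest on ties)."""
    if len(chart) == 0:
        raise ValidationError("chart is empty")
    return int(np.argmin(chart.values)) + 1


def learning_curve_caseload(chart: CUSUMChart) -> int:
    """Cases taken to overcome the learning curve (= the CUSUM nadir)."""
    return find_nadir(chart)


def _runs(labels: np.ndarray) -> list[list]:
    """Maximal runs of equal labels as [start0, end0, label] (0-based, inclusive)."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append([start, i - 1, labels[start]])
            start = i
    return runs


def segment_trends(chart: CUSUMChart, min_run: int = DEFAULT_MIN_RUN) -> PhaseReport:
    """Label improving/deteriorating phases of a CUSUM chart.

    Per-case increments (with C_0 = 0) are smoothed by a centered
    moving average of width ``min_run``; maximal runs of non-negative
    smoothed increment become *improving* segments and negative runs
    *deteriorating*.  Runs shorter than ``min_run`` are merged into the
    neighbouring run with the larger absolute cumulative chart change,
    which suppresses single-case noise.
    """
    if min_run < 1:
        raise ValidationError(f"min_run must be >= 1 (got {min_run})")
    n = len(chart)
    if n < 2 * min_run:
        raise ValidationError(
            f"chart has {n} cases; segmentation needs at least {2 * min_run} "
            f"(2 * min_run)"
        )
    c = np.asarray(chart.values, dtype=float)
    inc = np.diff(c, prepend=0.0)
    smoothed = (
        pd.Series(inc).rolling(window=min_run, center=True, min_periods=1).mean().to_numpy()
    )
    labels = np.where(smoothed >= 0, IMPROVING, DETERIORATING)
    runs = _runs(labels)

    def cum_change(run: list) -> float:
        start, end, _ = run
        base = c[start - 1] if start > 0 else 0.0
        return abs(c[end] - base)

    # merge short runs into the neighbour with the larger |cumulative change|
    while len(runs) > 1:
        lengths = [r[1] - r[0] + 1 for r in runs]
        short = [i for i, ln in enumerate(lengths) if ln < min_run]
        if not short:
            break
        i = min(short, key=lambda j: lengths[j])
        if i == 0:
            j = 1
        elif i == len(runs) - 1:
            j = len(runs) - 2
        else:
            j = i - 1 if cum_change(runs[i - 1]) >= cum_change(runs[i + 1]) else i + 1
        lo, hi = min(i, j), max(i, j)
        merged = [runs[lo][0], runs[hi][1], runs[j][2]]
        runs[lo : hi + 1] = [merged]
        # coalesce any now-adjacent equal labels
        k = 0
        while k < len(runs) - 1:
            if runs[k][2] == runs[k + 1][2]:
                runs[k] = [runs[k][0], runs[k + 1][1], runs[k][2]]
                del runs[k + 1]
            else:
                k += 1

    segments = tuple((r[0] + 1, r[1] + 1, str(r[2])) for r in runs)
    nadir = find_nadir(chart)
    return PhaseReport(
        nadir_case=nadir,
        learning_caseload=nadir,
        segments=segments,
        min_run=min_run,
        component=chart.component,
    )
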