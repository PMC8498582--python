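"""Seeded generator of synthetic turnaround-time series.

Emulates the statistical structure of a precision-oncology laboratory's
TAT record: negative-binomial (NB2) day counts per component, a
log-linear learning trend with accumulating caseload, step changes in
the log-mean (an early worse-than-average phase that ends near the
learning-curve nadir, a mid-series deterioration from a personnel
change), and batch processing that adds a shared waiting delay to
consecutive cases.

The default configuration reproduces the qualitative shape of a
365-case molecular-profiling programme: wet-lab medians near 13 days,
dry-lab near 10 days, overall near 27 days, a wet-lab learning curve
overcome in the mid-80s of cases, a dry-lab curve overcome in the 50s,
and a transient deterioration starting around case 262.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import exp
from typing import Sequence

import numpy as np
import pandas as pd

from .series import TATSeries, ValidationError

__all__ = [
    "SyntheticConfig",
    "ParameterSet",
    "generate_tat_series",
    "apply_batching",
    "true_parameters",
]

Changepoints = tuple[tuple[int, float], ...]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a synthetic TAT series.

    Component day counts are drawn independently from NB2 distributions
    with log-mean ``beta0 + beta1 * case_index + step shifts``; the NB2
    size parameter ``dispersion`` (k) gives variance ``mu + mu**2 / k``.
    ``changepoints_*`` are ``(case_index, log_mean_shift)`` pairs applied
    from that case onward.  Batching groups consecutive cases into
    blocks of ``batch_size`` and adds one shared uniform 0..
    ``batch_wait_max`` waiting delay per block to the overall TAT.
    """

    n_cases: int = 365
    beta0_wet: float = 3.1
    beta0_dry: float = 2.95
    beta1: float = -0.0015
    dispersion: float = 6.0
    changepoints_wet: Changepoints = ((86, -0.45), (262, 0.3), (311, -0.3))
    changepoints_dry: Changepoints = ((55, -0.45),)
    batch_size: int = 5
    batch_wait_max: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_cases, (int, np.integer)) and self.n_cases >= 1):
            raise ValidationError(f"n_cases must be a positive integer (got {self.n_cases})")
        if not self.dispersion > 0:
            raise ValidationError(f"dispersion must be > 0 (got {self.dispersion})")
        if not (isinstance(self.batch_size, (int, np.integer)) and self.batch_size >= 1):
            raise ValidationError(f"batch_size must be an integer >= 1 (got {self.batch_size})")
        if not (isinstance(self.batch_wait_max, (int, np.integer)) and self.batch_wait_max >= 0):
            raise ValidationError(
                f"batch_wait_max must be an integer >= 0 (got {self.batch_wait_max})"
            )
        for name in ("changepoints_wet", "changepoints_dry"):
            for case, _shift in getattr(self, name):
                if not 1 <= case <= self.n_cases:
                    raise ValidationError(
                        f"{name} case_index {case} outside [1, {self.n_cases}]"
                    )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["changepoints_wet"] = [list(cp) for cp in self.changepoints_wet]
        d["changepoints_dry"] = [list(cp) for cp in self.changepoints_dry]
        return d


@dataclass(frozen=True)
class ParameterSet:
    """Ground truth of a generating configuration, for recovery tests."""

    beta0_wet: float
    beta0_dry: float
    beta1: float
    irr: float  # per-case incidence-rate ratio exp(beta1)
    dispersion: float
    changepoint_cases_wet: tuple[int, ...]
    changepoint_cases_dry: tuple[int, ...]


def _log_mean(beta0: float, beta1: float, cases: np.ndarray, changepoints: Changepoints) -> np.ndarray:
    eta = beta0 + beta1 * cases.astype(float)
    for case, shift in changepoints:
        eta = eta + shift * (cases >= case)
    return eta


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, k: float) -> np.ndarray:
    # NB2 via its gamma-Poisson mixture; exact for any k > 0
    return rng.negative_binomial(n=k, p=k / (k + mu))


def generate_tat_series(config: SyntheticConfig) -> TATSeries:
    """Draw a full synthetic TAT series from ``config``.

    Overall TAT is wet + dry plus any batch-induced waiting days; the
    same seed always yields a bitwise-identical series.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cases = np.arange(1, config.n_cases + 1)
    mu_wet = np.exp(_log_mean(config.beta0_wet, config.beta1, cases, config.changepoints_wet))
    mu_dry = np.exp(_log_mean(config.beta0_dry, config.beta1, cases, config.changepoints_dry))
    wet = _nb_draw(rng, mu_wet, config.dispersion)
    dry = _nb_draw(rng, mu_dry, config.dispersion)
    frame = pd.DataFrame(
        {
            "case_index": cases,
            "wet_days": wet,
            "dry_days": dry,
            "overall_days": wet + dry,
        }
    )
    series = TATSeries(frame, provenance=f"synthetic seed={config.seed}")
    if config.batch_size > 1 or config.batch_wait_max > 0:
        # waiting-delay stream drawn from the same generator state so one
        # seed fixes the entire series
        series = apply_batching(
            series, config.batch_size, config.batch_wait_max, rng=rng
        )
    return series


def apply_batching(
    series: TATSeries,
    batch_size: int,
    batch_wait_max: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TATSeries:
    """Add shared batch waiting delays to the overall TAT.

    Consecutive cases are grouped into blocks of ``batch_size``; every
    case in a block receives the same waiting delay, drawn uniformly
    from 0..``batch_wait_max`` days.  Ordering and case numbering are
    unchanged.  Waiting accrues on the overall (accession-to-report)
    clock only, reflecting queue time between the component stages.
    """
    if not (isinstance(batch_size, (int, np.integer)) and batch_size >= 1):
        raise ValidationError(f"batch_size must be an integer >= 1 (got {batch_size})")
    if batch_wait_max < 0:
        raise ValidationError(f"batch_wait_max must be >= 0 (got {batch_wait_max})")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(series)
    n_blocks = -(-n // batch_size)
    block_waits = rng.integers(0, batch_wait_max + 1, size=n_blocks)
    waits = np.repeat(block_waits, batch_size)[:n]
    overall = series.component("overall") + waits
    out = series.with_overall(overall)
    return out


def true_parameters(config: SyntheticConfig) -> ParameterSet:
    """Echo the generating truth of ``config`` for recovery tests."""
    config.validate()
    return ParameterSet(
        beta0_wet=config.beta0_wet,
        beta0_dry=config.beta0_dry,
        beta1=config.beta1,
        irr=exp(config.beta1),
        dispersion=config.dispersion,
        changepoint_cases_wet=tuple(c for c, _ in config.changepoints_wet),
        changepoint_cases_dry=tuple(c for c, _ in config.changepoints_dry),
    )
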