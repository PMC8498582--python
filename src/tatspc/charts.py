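"""Statistical process control charts for TAT monitoring.

Three chart families:

* **CUSUM of residuals** — the running sum ``C_j = sum_{k<=j} (E - O_k)``
  of expected-minus-observed TAT over chronologically ordered cases.
  Downward drift means observed TAT exceeds the reference (performance
  worse than expected); upward drift means improvement.
* **EWMA** — the exponentially weighted moving average
  ``Z_j = lam * O_j + (1 - lam) * Z_{j-1}``, initialized with the mean
  of the first ten observations, giving a smooth local estimate of the
  current mean TAT.
* **Bernoulli CUSUM log-likelihood-ratio (LLR) charts** — the
  cumulative LLR comparing a baseline probability p0 of exceeding a
  clinically chosen threshold (42 days overall, 21 days per component)
  against an odds-ratio-shifted alternative (R = 1.20 for
  deterioration, R = 1/1.20 ≈ 0.83 for improvement).  Charts are never
  reset and never floored at zero, so the full trajectory is shown even
  after a control limit is crossed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Optional, Sequence

import numpy as np

from .series import TATSeries, ValidationError

__all__ = [
    "CUSUMChart",
    "EWMAChart",
    "LLRChart",
    "OddsRatioPair",
    "cusum_chart",
    "ewma_chart",
    "dichotomize",
    "llr_increment",
    "exceedance_probability",
    "cusum_llr_chart",
    "calibrate_control_limit",
    "simulate_arl",
    "odds_ratio_pair",
    "DEFAULT_LAM",
    "DEFAULT_INIT_WINDOW",
    "DETERIORATION_ODDS_RATIO",
]

DEFAULT_LAM = 0.03
DEFAULT_INIT_WINDOW = 10
DETERIORATION_ODDS_RATIO = 1.20


@dataclass(frozen=True)
class CUSUMChart:
    """Running-residual CUSUM; ``values[j-1]`` is C_j for case j."""

    values: np.ndarray
    expected: float
    component: str = "overall"

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class EWMAChart:
    """EWMA-smoothed TAT; ``values[j-1]`` is Z_j for case j."""

    values: np.ndarray
    lam: float
    init_window: int
    z0: float
    component: str = "overall"

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class LLRChart:
    """Cumulative Bernoulli log-likelihood ratio chart (nats)."""

    values: np.ndarray
    threshold_days: float
    p0: float
    odds_ratio: float
    control_limit: Optional[float] = None
    signals: tuple[int, ...] = ()
    component: str = "overall"

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class OddsRatioPair:
    """Deterioration/improvement alternatives for the LLR charts."""

    deterioration: float
    improvement: float
    pct_odds_increase: float
    pct_odds_decrease: float


def odds_ratio_pair(deterioration: float = DETERIORATION_ODDS_RATIO) -> OddsRatioPair:
    """The paired alternative hypotheses implied by one deterioration OR.

    A deterioration odds ratio R has the reciprocal 1/R as its
    improvement counterpart; the percent changes in the odds are
    ``100 * (R - 1)`` and ``100 * (1 - 1/R)``.
    """
    if not deterioration > 0:
        raise ValidationError(f"odds ratio must be > 0 (got {deterioration})")
    return OddsRatioPair(
        deterioration=deterioration,
        improvement=1.0 / deterioration,
        pct_odds_increase=100.0 * (deterioration - 1.0),
        pct_odds_decrease=100.0 * (1.0 - 1.0 / deterioration),
    )


def cusum_chart(
    series: TATSeries, component: str = "overall", expected: Optional[float] = None
) -> CUSUMChart:
    """CUSUM of expected-minus-observed TAT.

    ``expected`` defaults to the whole-series mean of the chosen
    component — the fixed reference the cumulative residuals are taken
    against.
    """
    obs = series.component(component).astype(float)
    if expected is None:
        expected = float(obs.mean())
    elif not expected > 0:
        raise ValidationError(f"expected TAT must be > 0 (got {expected})")
    values = np.cumsum(expected - obs)
    return CUSUMChart(values=values, expected=float(expected), component=component)


def ewma_chart(
    series: TATSeries,
    component: str = "overall",
    lam: float = DEFAULT_LAM,
    init_window: int = DEFAULT_INIT_WINDOW,
) -> EWMAChart:
    """EWMA of the TAT series with first-``init_window`` initialization.

    z0 is the mean of the first ``init_window`` observations and the
    recursion runs from case 1, so the chart spans every case.
    """
    if not 0 < lam <= 1:
        raise ValidationError(f"lam must be in (0, 1] (got {lam})")
    if init_window < 1:
        raise ValidationError(f"init_window must be >= 1 (got {init_window})")
    obs = series.component(component).astype(float)
    if len(obs) < init_window:
        raise ValidationError(
            f"series has {len(obs)} cases but the EWMA initialization window "
            f"requires at least {init_window}"
        )
    z0 = float(obs[:init_window].mean())
    values = np.empty(len(obs))
    z = z0
    for j, o in enumerate(obs):
        z = lam * o + (1.0 - lam) * z
        values[j] = z
    return EWMAChart(values=values, lam=lam, init_window=init_window, z0=z0, component=component)


def dichotomize(
    series: TATSeries, component: str = "overall", threshold_days: float = 42
) -> np.ndarray:
    """Binary exceedance sequence: 1 where TAT is strictly above the threshold."""
    if not threshold_days > 0:
        raise ValidationError(f"threshold_days must be > 0 (got {threshold_days})")
    obs = series.component(component)
    return (obs > threshold_days).astype(np.int64)


def exceedance_probability(p0: float, odds_ratio: float) -> float:
    """Alternative exceedance probability p1 implied by an odds ratio.

    Shifting the odds p0/(1-p0) by R gives
    ``p1 = R * p0 / (1 - p0 + R * p0)``.
    """
    _check_p0_r(p0, odds_ratio)
    return odds_ratio * p0 / (1.0 - p0 + odds_ratio * p0)


def _check_p0_r(p0: float, odds_ratio: float) -> None:
    if not 0 < p0 < 1:
        raise ValidationError(f"p0 must lie strictly in (0, 1) (got {p0})")
    if not odds_ratio > 0:
        raise ValidationError(f"odds_ratio must be > 0 (got {odds_ratio})")


def llr_increment(y: int, p0: float, odds_ratio: float) -> float:
    """Per-case Bernoulli log-likelihood-ratio increment (nats).

    ``y * log(p1/p0) + (1-y) * log((1-p1)/(1-p0))`` with p1 the
    odds-shifted alternative; algebraically equal to
    ``y * log(R) - log(1 - p0 + R * p0)``.
    """
    _check_p0_r(p0, odds_ratio)
    return float(y) * log(odds_ratio) - log(1.0 - p0 + odds_ratio * p0)


def cusum_llr_chart(
    exceedances: Sequence[int],
    odds_ratio: float,
    p0: Optional[float] = None,
    control_limit: Optional[float] = None,
    threshold_days: float = float("nan"),
    component: str = "overall",
) -> LLRChart:
    """Cumulative Bernoulli LLR chart over a binary exceedance sequence.

    The chart accumulates ``llr_increment`` without resetting and
    without a zero floor, so crossings of a control limit leave the
    trajectory intact.  When ``p0`` is omitted it is estimated as the
    observed exceedance proportion; a sequence that never (or always)
    exceeds then has no usable baseline and an explicit ``p0`` is
    required.  ``signals`` records the 1-based cases at which |S_j|
    enters the out-of-control region ±``control_limit``.
    """
    y = np.asarray(exceedances, dtype=float)
    if y.ndim != 1 or len(y) == 0:
        raise ValidationError("exceedance sequence must be non-empty and 1-d")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("exceedances must be binary (0/1)")
    if p0 is None:
        phat = float(y.mean())
        if phat in (0.0, 1.0):
            raise ValidationError(
                "observed exceedance proportion is degenerate "
                f"({phat:.0f}); supply an explicit p0"
            )
        p0 = phat
    _check_p0_r(p0, odds_ratio)
    increments = y * log(odds_ratio) - log(1.0 - p0 + odds_ratio * p0)
    values = np.cumsum(increments)
    signals: tuple[int, ...] = ()
    if control_limit is not None:
        if control_limit < 0:
            raise ValidationError(f"control_limit must be >= 0 (got {control_limit})")
        out = np.abs(values) >= control_limit
        entering = out & ~np.concatenate([[False], out[:-1]])
        signals = tuple(int(j) for j in np.flatnonzero(entering) + 1)
    return LLRChart(
        values=values,
        threshold_days=threshold_days,
        p0=float(p0),
        odds_ratio=float(odds_ratio),
        control_limit=control_limit,
        signals=signals,
        component=component,
    )


def simulate_arl(
    h: float,
    p0: float,
    odds_ratio: float,
    n_sim: int = 1000,
    max_len: int = 5000,
    seed: int | None = 0,
) -> float:
    """Monte-Carlo in-control average run length of the unresetted chart.

    Runs ``n_sim`` Bernoulli(p0) sequences and records the first case at
    which |S_j| crosses ±h; runs that never cross within ``max_len``
    cases are counted at ``max_len`` (so the estimate is a lower bound
    for large h).  ``h = 0`` signals immediately: ARL = 1 by convention.
    """
    _check_p0_r(p0, odds_ratio)
    if h < 0:
        raise ValidationError(f"h must be >= 0 (got {h})")
    if h == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    up = log(odds_ratio) - log(1.0 - p0 + odds_ratio * p0)  # increment for y=1
    down = -log(1.0 - p0 + odds_ratio * p0)  # increment for y=0
    y = rng.random((n_sim, max_len)) < p0
    inc = np.where(y, up, down)
    s = np.cumsum(inc, axis=1)
    crossed = np.abs(s) >= h
    first = np.argmax(crossed, axis=1) + 1
    first[~crossed.any(axis=1)] = max_len
    return float(first.mean())


def calibrate_control_limit(
    p0: float,
    odds_ratio: float,
    target_arl: float,
    n_sim: int = 1000,
    seed: int | None = 0,
    grid: Optional[Sequence[float]] = None,
    max_len: Optional[int] = None,
) -> float:
    """Smallest grid value of h whose simulated in-control ARL meets the target.

    The in-control ARL is estimated by :func:`simulate_arl` under
    Bernoulli(p0); the returned h is the smallest grid point with
    ARL >= ``target_arl``.
    """
    if not target_arl > 1:
        raise ValidationError(f"target_arl must be > 1 (got {target_arl})")
    if grid is None:
        grid = np.arange(0.25, 8.0 + 1e-9, 0.25)
    grid = np.sort(np.asarray(grid, dtype=float))
    if max_len is None:
        max_len = int(20 * target_arl)
    arls = []
    for h in grid:
        arl = simulate_arl(h, p0, odds_ratio, n_sim=n_sim, max_len=max_len, seed=seed)
        arls.append(arl)
        if arl >= target_arl:
            return float(h)
    raise ValidationError(
        f"target ARL {target_arl} unattainable on grid up to h={grid[-1]} "
        f"(attainable range 1..{max(arls):.1f})"
    )
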