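import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tatspc import (
    TATSeries,
    ValidationError,
    calibrate_control_limit,
    cusum_chart,
    cusum_llr_chart,
    dichotomize,
    ewma_chart,
    exceedance_probability,
    llr_increment,
    odds_ratio_pair,
    simulate_arl,
)
from conftest import random_series


def _overall_series(values):
    values = np.asarray(values, dtype=int)
    return TATSeries.from_records(np.zeros_like(values), np.zeros_like(values), values)


# ---------------------------------------------------------------------------
# CUSUM
# ---------------------------------------------------------------------------


class TestCUSUM:
    def test_flat_process_is_zero(self):
        chart = cusum_chart(_overall_series([7] * 20), "overall", expected=7)
        assert np.allclose(chart.values, 0.0)

    def test_hand_computed_example(self):
        chart = cusum_chart(_overall_series([3, 1, 2]), "overall", expected=2)
        assert chart.values == pytest.approx([-1.0, 0.0, 0.0])

    def test_default_expected_is_series_mean(self, small_series):
        chart = cusum_chart(small_series, "overall")
        assert chart.expected == pytest.approx(small_series.component("overall").mean())
        # mean reference makes the chart return to zero at the end
        assert chart.values[-1] == pytest.approx(0.0, abs=1e-9)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_telescoping_identity(self, seed):
        """C_n = n*E - sum(O) for any series and reference."""
        rng = np.random.default_rng(seed)
        series = random_series(rng, int(rng.integers(1, 200)))
        expected = float(rng.uniform(1, 60))
        chart = cusum_chart(series, "overall", expected=expected)
        obs = series.component("overall")
        assert chart.values[-1] == pytest.approx(
            len(obs) * expected - obs.sum(), abs=1e-9
        )
        # per-case increments: C_j - C_{j-1} = E - O_j
        increments = np.diff(chart.values, prepend=0.0)
        assert np.allclose(increments, expected - obs, atol=1e-9)

    def test_empty_series_rejected(self):
        import pandas as pd

        with pytest.raises(ValidationError, match="empty"):
            TATSeries(
                pd.DataFrame(columns=["case_index", "wet_days", "dry_days", "overall_days"])
            )


# ---------------------------------------------------------------------------
# EWMA
# ---------------------------------------------------------------------------


def _ewma_loop_oracle(obs, lam, init_window):
    z = np.mean(obs[:init_window])
    out = []
    for o in obs:
        z = lam * o + (1 - lam) * z
        out.append(z)
    return np.array(out)


class TestEWMA:
    def test_constant_series_fixed_point(self):
        chart = ewma_chart(_overall_series([9] * 15), "overall", lam=0.2)
        assert np.allclose(chart.values, 9.0)

    def test_hand_recursion_example(self):
        obs = [1] * 10 + [2]
        chart = ewma_chart(_overall_series(obs), "overall", lam=0.5)
        assert chart.z0 == pytest.approx(1.0)
        assert chart.values[10] == pytest.approx(1.5)

    def test_lam_one_returns_raw_series(self, small_series):
        chart = ewma_chart(small_series, "overall", lam=1.0)
        assert np.allclose(chart.values, small_series.component("overall"))

    def test_matches_loop_oracle_and_bounds(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 400))
            series = random_series(rng, n)
            lam = float(rng.uniform(0.01, 1.0))
            chart = ewma_chart(series, "overall", lam=lam)
            obs = series.component("overall").astype(float)
            assert np.allclose(chart.values, _ewma_loop_oracle(obs, lam, 10), atol=1e-9)
            assert (chart.values >= obs.min() - 1e-9).all()
            assert (chart.values <= obs.max() + 1e-9).all()

    def test_geometric_weights(self):
        """Weight of O_{j-m} in Z_j is lam*(1-lam)**m (direct weighted sum)."""
        rng = np.random.default_rng(5)
        obs = rng.integers(1, 50, size=60).astype(float)
        lam, w = 0.07, 10
        chart = ewma_chart(_overall_series(obs.astype(int)), "overall", lam=lam, init_window=w)
        j = 60
        z0 = obs[:w].mean()
        weights = lam * (1 - lam) ** np.arange(j)  # weight on O_j, O_{j-1}, ...
        direct = (weights * obs[::-1]).sum() + (1 - lam) ** j * z0
        assert chart.values[-1] == pytest.approx(direct, abs=1e-10)

    def test_short_series_error_names_required_length(self):
        with pytest.raises(ValidationError, match="at least 10"):
            ewma_chart(_overall_series([5] * 6), "overall")

    @pytest.mark.parametrize("lam", [0.0, 1.2, -0.1])
    def test_invalid_lam(self, lam):
        with pytest.raises(ValidationError, match="lam"):
            ewma_chart(_overall_series([5] * 15), "overall", lam=lam)


# ---------------------------------------------------------------------------
# Dichotomization and LLR
# ---------------------------------------------------------------------------


class TestDichotomize:
    def test_strict_inequality_at_boundary(self):
        series = _overall_series([42, 43])
        assert list(dichotomize(series, "overall", 42)) == [0, 1]

    def test_elementwise(self):
        series = _overall_series([10, 50, 42, 60])
        assert list(dichotomize(series, "overall", 42)) == [0, 1, 0, 1]


class TestLLRIncrement:
    def test_null_odds_ratio_gives_zero(self):
        assert llr_increment(0, 0.3, 1.0) == pytest.approx(0.0)
        assert llr_increment(1, 0.3, 1.0) == pytest.approx(0.0)

    def test_hand_computed_values(self):
        # p1 = 1.2*0.5 / (0.5 + 1.2*0.5) = 0.6/1.1
        assert llr_increment(1, 0.5, 1.2) == pytest.approx(math.log((0.6 / 1.1) / 0.5), abs=1e-12)
        assert llr_increment(1, 0.5, 1.2) == pytest.approx(0.08701, abs=5e-6)
        assert llr_increment(0, 0.5, 1.2) == pytest.approx(math.log((0.5 / 1.1) / 0.5), abs=1e-12)
        assert llr_increment(0, 0.5, 1.2) == pytest.approx(-0.09531, abs=5e-6)

    @given(
        st.floats(0.01, 0.99),
        st.floats(0.05, 20.0),
        st.integers(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_two_algebraic_forms_agree(self, p0, r, y):
        p1 = exceedance_probability(p0, r)
        direct = y * math.log(p1 / p0) + (1 - y) * math.log((1 - p1) / (1 - p0))
        assert llr_increment(y, p0, r) == pytest.approx(direct, abs=1e-12)

    def test_expected_increment_signs(self):
        """E[increment] < 0 under p0 and > 0 under p1, for R > 1."""
        for p0 in (0.1, 0.3, 0.5):
            r = 1.2
            p1 = exceedance_probability(p0, r)
            up, down = llr_increment(1, p0, r), llr_increment(0, p0, r)
            assert p0 * up + (1 - p0) * down < 0
            assert p1 * up + (1 - p1) * down > 0

    def test_invalid_p0(self):
        with pytest.raises(ValidationError, match="p0"):
            llr_increment(1, 0.0, 1.2)


class TestLLRChart:
    def test_all_zero_exceedances_constant_step(self):
        chart = cusum_llr_chart(np.zeros(25, dtype=int), 1.2, p0=0.2)
        step = -math.log(0.8 + 1.2 * 0.2)
        assert np.allclose(np.diff(chart.values), step)
        assert chart.values[0] == pytest.approx(step)
        assert step < 0

    def test_null_alternative_is_flat(self):
        chart = cusum_llr_chart(np.array([0, 1, 1, 0]), 1.0, p0=0.4)
        assert np.allclose(chart.values, 0.0)

    def test_two_case_example(self):
        chart = cusum_llr_chart(np.array([1, 0]), 1.2, p0=0.5)
        assert chart.values == pytest.approx([0.08701, -0.00830], abs=5e-6)

    def test_degenerate_sequence_requires_explicit_p0(self):
        with pytest.raises(ValidationError, match="explicit p0"):
            cusum_llr_chart(np.zeros(10, dtype=int), 1.2)
        # explicit p0 makes it legal
        chart = cusum_llr_chart(np.zeros(10, dtype=int), 1.2, p0=0.1)
        assert len(chart) == 10

    def test_default_p0_is_observed_proportion(self):
        y = np.array([1, 0, 0, 1, 0])
        chart = cusum_llr_chart(y, 1.2)
        assert chart.p0 == pytest.approx(0.4)

    def test_signals_recorded_without_reset(self):
        y = np.ones(30, dtype=int)
        chart = cusum_llr_chart(y, 1.2, p0=0.2, control_limit=0.5)
        assert chart.signals  # crossing happened
        first = chart.signals[0]
        # trajectory continues past the signal, unresetted
        assert abs(chart.values[first - 1]) >= 0.5
        assert len(chart.values) == 30
        assert np.all(np.diff(chart.values) > 0)

    def test_matches_loop_oracle(self, rng):
        for _ in range(10):
            y = (rng.random(100) < 0.3).astype(int)
            if y.mean() in (0, 1):
                continue
            chart = cusum_llr_chart(y, 0.83)
            s, out = 0.0, []
            for yi in y:
                s += llr_increment(int(yi), chart.p0, 0.83)
                out.append(s)
            assert np.allclose(chart.values, out, atol=1e-9)


class TestOddsRatioPair:
    def test_reciprocal_pairing(self):
        pair = odds_ratio_pair(1.2)
        assert pair.improvement == pytest.approx(1 / 1.2)
        assert round(pair.improvement, 2) == 0.83
        assert pair.pct_odds_increase == pytest.approx(20.0)
        assert round(pair.pct_odds_decrease) == 17


class TestControlLimitCalibration:
    def test_zero_limit_signals_immediately(self):
        assert simulate_arl(0.0, 0.3, 1.2, n_sim=10) == 1.0

    def test_arl_monotone_in_h(self):
        arls = [
            simulate_arl(h, 0.3, 1.2, n_sim=500, max_len=3000, seed=1)
            for h in (0.5, 1.5, 3.0)
        ]
        assert arls[0] < arls[1] < arls[2]

    def test_calibration_self_consistent_across_seeds(self):
        kwargs = dict(p0=0.3, odds_ratio=1.2, target_arl=100, n_sim=2000)
        h1 = calibrate_control_limit(seed=1, **kwargs)
        h2 = calibrate_control_limit(seed=2, **kwargs)
        assert abs(h1 - h2) <= 0.25  # within one grid step

    def test_unattainable_target_reports_range(self):
        with pytest.raises(ValidationError, match="unattainable"):
            calibrate_control_limit(
                0.3, 1.2, target_arl=1e7, n_sim=50, grid=[0.25, 0.5], max_len=500
            )
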