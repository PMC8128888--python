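"""Normalization, reduction-time extraction and tuning-curve assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cochmap.reduction import (
    AmplitudeTimeSeries,
    build_tuning_curve,
    group_average_tc,
    normalize_to_baseline,
    reduction_time,
    reduction_time_table,
)

LN4 = math.log(4.0)


def _series(times, amps, level=10.0, normalized=False, **kw):
    return AmplitudeTimeSeries(
        ear_id=kw.pop("ear_id", "e1"),
        group=kw.pop("group", "control"),
        freq_khz=kw.pop("freq_khz", 4.0),
        level_db_sl=level,
        times_min=np.asarray(times, dtype=float),
        amplitudes=np.asarray(amps, dtype=float),
        normalized=normalized,
    )


def _logistic_series(t50, slope=1.0, times=None, level=10.0, **kw):
    if times is None:
        times = np.arange(-10.0, 45.0 + 0.5, 1.0)
    amps = 1.0 / (1.0 + np.exp((times - t50) / slope))
    return _series(times, amps, level=level, normalized=True, **kw)


class TestNormalize:
    def test_constant_trace(self):
        s = _series(np.arange(-6, 30), np.full(36, 40.0))
        out = normalize_to_baseline(s)
        np.testing.assert_allclose(out.amplitudes, 1.0)
        assert out.normalized

    def test_baseline_mean_divides(self):
        s = _series([-4.0, 2.0, 20.0], [38.0, 42.0, 20.0])
        out = normalize_to_baseline(s)
        assert out.amplitudes[-1] == pytest.approx(0.5)
        mask = (out.times_min >= -5) & (out.times_min <= 5)
        assert out.amplitudes[mask].mean() == pytest.approx(1.0)

    def test_empty_window_rejected(self):
        s = _series([10.0, 11.0, 12.0], [40.0, 40.0, 40.0])
        with pytest.raises(ValueError, match="baseline"):
            normalize_to_baseline(s)


class TestReductionTime:
    def test_step_crossing_midpoint(self):
        times = np.arange(0.0, 20.0)
        amps = np.where(times <= 9, 1.0, 0.0)
        t = reduction_time(_series(times, amps, normalized=True), 0.5,
                           interpolation="linear")
        assert t == pytest.approx(9.5)

    @pytest.mark.parametrize(
        "fraction,expected",
        [(0.5, 10.0), (0.8, 10.0 - LN4), (0.2, 10.0 + LN4)],
    )
    def test_logistic_closed_form(self, fraction, expected):
        s = _logistic_series(10.0, slope=1.0)
        assert reduction_time(s, fraction) == pytest.approx(expected, abs=0.02)

    def test_flat_series_no_reduction(self):
        s = _series(np.arange(10.0), np.ones(10), normalized=True)
        assert math.isnan(reduction_time(s, 0.5))

    def test_requires_normalization(self):
        s = _series(np.arange(10.0), 40.0 * np.ones(10))
        with pytest.raises(ValueError, match="normalized"):
            reduction_time(s, 0.5)

    def test_exact_tie_taken_at_face_value(self):
        s = _series([0.0, 1.0, 2.0, 3.0], [1.0, 0.5, 0.1, 0.05], normalized=True)
        assert reduction_time(s, 0.5) == 1.0

    def test_sustained_rule_rejects_single_noise_dip(self):
        times = np.arange(0.0, 20.0)
        amps = np.ones(20)
        amps[5] = 0.3  # isolated dip
        amps[12:] = 0.0  # true sustained collapse
        t = reduction_time(_series(times, amps, normalized=True), 0.5,
                           k_sustained=2, interpolation="linear")
        assert 11.0 <= t <= 12.0

    def test_monotone_ordering_of_fractions(self):
        s = _logistic_series(15.0, slope=0.8)
        t80 = reduction_time(s, 0.8)
        t50 = reduction_time(s, 0.5)
        t20 = reduction_time(s, 0.2)
        assert t80 <= t50 <= t20

    @settings(derandomize=True, max_examples=30)
    @given(
        delta=st.floats(min_value=-3.0, max_value=3.0),
        t50=st.floats(min_value=8.0, max_value=25.0),
    )
    def test_time_shift_equivariance(self, delta, t50):
        times = np.arange(-10.0, 45.0, 1.0)
        amps = 1.0 / (1.0 + np.exp((times - t50) / 0.9))
        s0 = _series(times, amps, normalized=True)
        s1 = _series(times + delta, amps, normalized=True)
        t0 = reduction_time(s0, 0.5)
        t1 = reduction_time(s1, 0.5)
        assert t1 - t0 == pytest.approx(delta, abs=1e-9)

    def test_early_crossing_flagged(self):
        times = np.arange(-5.0, 10.0)
        amps = np.where(times < -3, 1.0, 0.1)
        with pytest.warns(UserWarning, match="precedes perfusion start"):
            reduction_time(_series(times, amps, normalized=True), 0.5)


class TestTuningCurve:
    def _family(self, tip=15.0, levels=(10.0, 20.0, 30.0), widen=1.5):
        """Logistic family whose edges widen with level."""
        out = []
        for level in levels:
            slope = 0.8 + widen * (level - 10.0) / 10.0 / LN4
            out.append(_logistic_series(tip, slope=slope, level=level))
        return out

    def test_edges_widen_with_level(self):
        tc = build_tuning_curve(self._family())
        assert tc.tip_time_min == pytest.approx(15.0, abs=0.02)
        (l1, (t80_1, t20_1)), (l2, (t80_2, t20_2)) = sorted(tc.edges.items())
        assert t80_2 < t80_1 < t20_1 < t20_2
        assert all(t80 <= t20 for t80, t20 in tc.edges.values())

    def test_tip_only(self):
        tc = build_tuning_curve(self._family(levels=(10.0,)))
        assert tc.edges == {}

    def test_missing_tip_level_rejected(self):
        with pytest.raises(ValueError, match="tip"):
            build_tuning_curve(self._family(levels=(20.0, 30.0)))

    def test_level_without_crossing_omitted(self):
        family = self._family(levels=(10.0, 20.0))
        flat = _series(
            np.arange(-10.0, 45.0), np.ones(55), level=30.0, normalized=True
        )
        with pytest.warns(UserWarning, match="omitted"):
            tc = build_tuning_curve(family + [flat])
        assert 30.0 not in tc.edges
        assert 20.0 in tc.edges


class TestGroupAverage:
    def _tc(self, ear, tip):
        return build_tuning_curve(
            [
                _logistic_series(tip, slope=0.8, level=10.0, ear_id=ear),
                _logistic_series(tip, slope=1.2, level=20.0, ear_id=ear),
            ]
        )

    def test_identical_curves_zero_sem(self):
        avg = group_average_tc([self._tc("a", 15.0), self._tc("b", 15.0)])
        tip_rows = avg[avg.point == "t50"]
        assert tip_rows.mean_min.iloc[0] == pytest.approx(15.0, abs=0.02)
        assert tip_rows.sem_min.iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert (avg.n == 2).all()

    def test_mean_and_sem_arithmetic(self):
        avg = group_average_tc([self._tc("a", 14.0), self._tc("b", 16.0)])
        tip = avg[avg.point == "t50"].iloc[0]
        assert tip.mean_min == pytest.approx(15.0, abs=0.02)
        assert tip.sem_min == pytest.approx(1.0, abs=0.03)

    def test_single_ear_sem_undefined(self):
        avg = group_average_tc([self._tc("a", 15.0)])
        assert avg.sem_min.isna().all()
        assert (avg.n == 1).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            group_average_tc([])


class TestReductionTimeTable:
    def test_only_tip_level_used(self):
        series = [
            _logistic_series(14.0, level=10.0, ear_id="a"),
            _logistic_series(12.0, level=20.0, ear_id="a"),
            _logistic_series(18.0, level=10.0, ear_id="b", group="operated"),
        ]
        df = reduction_time_table(series)
        assert len(df) == 2
        got = dict(zip(df.ear_id, df.t50_min))
        assert got["a"] == pytest.approx(14.0, abs=0.02)
        assert got["b"] == pytest.approx(18.0, abs=0.02)
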