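"""Loess smoothing, slope/intensity statistics, periods, and OLS correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import epochdec as ed
from epochdec.ancestral_events import BiogeoEvent, event_density
from epochdec.paleoclimate import (
    TemperatureSeries,
    correlate,
    fit_loess,
    intensity,
    segment_periods,
    slope_at,
)


def _linear_series(n=101, hi=50.0, slope=-0.2, intercept=20.0):
    ages = np.linspace(0, hi, n)
    return TemperatureSeries(ages, intercept + slope * ages)


class TestLoess:
    def test_reproduces_linear_data_exactly(self):
        curve = fit_loess(_linear_series(), span=0.3)
        probe = np.array([0.0, 7.3, 25.0, 49.0])
        assert np.allclose(curve(probe), 20.0 - 0.2 * probe, atol=1e-6)

    def test_constant_series_fits_flat(self):
        series = TemperatureSeries(np.linspace(0, 30, 60), np.full(60, 7.5))
        curve = fit_loess(series, span=0.5)
        assert np.allclose(curve(np.linspace(0, 30, 11)), 7.5, atol=1e-9)
        assert slope_at(curve, 15.0) == pytest.approx(0.0, abs=1e-9)

    def test_extrapolation_refused(self):
        curve = fit_loess(_linear_series(hi=40.0), span=0.3)
        with pytest.raises(ValueError, match="extrapolation"):
            curve(45.0)

    def test_small_span_tracks_wiggly_truth_better(self):
        ages = np.linspace(0, 50, 260)
        rng = np.random.default_rng(0)
        truth = 8 + 3 * np.sin(ages / 3.0)
        series = TemperatureSeries(ages, truth + rng.normal(0, 0.3, ages.size))
        probe = np.linspace(1, 49, 120)
        rms = {}
        for span in (0.2, 0.8):
            fitted = fit_loess(series, span=span)(probe)
            rms[span] = np.sqrt(np.mean((fitted - (8 + 3 * np.sin(probe / 3.0))) ** 2))
        assert rms[0.2] < rms[0.8]

    def test_span_validation(self):
        with pytest.raises(ValueError):
            fit_loess(_linear_series(), span=0.0)
        with pytest.raises(ValueError):
            fit_loess(_linear_series(n=5), span=0.1)  # windows below 4 points


class TestSlope:
    def test_linear_series_gives_constant_warming_slope(self):
        # T = 20 - 0.2 age: temperature rises toward the present
        curve = fit_loess(_linear_series(), span=0.3)
        for t in (5.0, 20.0, 44.0):
            assert slope_at(curve, t, delta=0.1) == pytest.approx(0.2, abs=1e-6)

    def test_quadratic_slope_matches_closed_form(self):
        a = 0.01
        ages = np.linspace(0, 40, 400)
        curve = fit_loess(TemperatureSeries(ages, a * ages**2), span=0.05)
        for t in (10.0, 25.0):
            assert slope_at(curve, t, delta=0.1) == pytest.approx(-2 * a * t, abs=1e-3)

    def test_boundary_uses_one_sided_difference(self):
        curve = fit_loess(_linear_series(hi=30.0), span=0.3)
        assert slope_at(curve, 0.0, delta=0.1) == pytest.approx(0.2, abs=1e-6)
        assert slope_at(curve, 30.0, delta=0.1) == pytest.approx(0.2, abs=1e-6)

    def test_outside_range_rejected(self):
        curve = fit_loess(_linear_series(hi=30.0), span=0.3)
        with pytest.raises(ValueError):
            slope_at(curve, 31.0)

    @given(st.floats(-50, 50, allow_nan=False))
    @settings(derandomize=True)
    def test_intensity_is_even_and_nonnegative(self, s):
        assert intensity(s) == intensity(-s) >= 0.0


class TestSegmentPeriods:
    def test_four_periods_from_three_boundaries(self):
        periods = segment_periods(52.0, [34, 15, 5], ["Warm I", "Cold I", "Warm II", "Cold II"])
        assert [p.label for p in periods] == ["Warm I", "Cold I", "Warm II", "Cold II"]
        assert periods[0].older == 52.0 and periods[-1].younger == 0.0
        assert periods[1].older == 34 and periods[1].younger == 15

    def test_empty_boundaries_single_period(self):
        periods = segment_periods(52.0, [], ["all"])
        assert len(periods) == 1

    def test_increasing_boundaries_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            segment_periods(52.0, [5, 15], ["a", "b", "c"])

    def test_label_count_must_match(self):
        with pytest.raises(ValueError):
            segment_periods(52.0, [20], ["only-one"])


def _events_at(times):
    return [
        BiogeoEvent("dispersal", float(t), "intercontinental", 1, "EA", f"b{i}")
        for i, t in enumerate(times)
    ]


class TestCorrelate:
    def test_noiseless_linear_relation_recovered_exactly(self):
        # y = 2x + 1 by construction: feed a synthetic density curve whose
        # values at event times realize exactly that line
        times = np.linspace(2, 38, 10)
        curve = fit_loess(
            TemperatureSeries(np.linspace(0, 40, 200), 30 - 0.25 * np.linspace(0, 40, 200)),
            span=0.3,
        )

        class FakeDensity:
            event_type = "dispersal"

            def evaluate(self, ages):
                x = np.array([intensity(slope_at(curve, t)) for t in np.atleast_1d(ages)])
                return 2 * x + 1

        cc = correlate(_events_at(times), FakeDensity(), curve, event_type="dispersal")
        # x is constant on a line, so the regression must be flagged instead
        assert cc.status == "degenerate"

        class FakeDensity2:
            event_type = "dispersal"

            def evaluate(self, ages):
                return 2 * np.atleast_1d(ages) + 1.0

        class FakeCurve:
            age_range = (0.0, 40.0)

            def __call__(self, ages):
                # temperature whose |slope| equals age: T' = -t => T = -t^2/2
                ages = np.atleast_1d(np.asarray(ages, dtype=float))
                return -0.5 * ages**2

        cc2 = correlate(_events_at(times), FakeDensity2(), FakeCurve(), event_type="dispersal")
        assert cc2.status == "ok"
        assert cc2.slope == pytest.approx(2.0, abs=1e-6)
        assert cc2.intercept == pytest.approx(1.0, abs=1e-4)
        assert cc2.r_squared == pytest.approx(1.0, abs=1e-9)
        assert cc2.ci_low <= cc2.slope <= cc2.ci_high

    def test_fewer_than_three_events_flagged_insufficient(self):
        curve = fit_loess(_linear_series(hi=40.0), span=0.3)
        dens = event_density(_events_at([5, 9]), bandwidth=2.0, event_type="dispersal")
        cc = correlate(_events_at([5, 9]), dens, curve, event_type="dispersal")
        assert cc.status == "insufficient"
        assert np.isnan(cc.slope)

    def test_constant_slope_series_flagged_degenerate(self):
        curve = fit_loess(_linear_series(hi=40.0), span=0.3)
        events = _events_at([4, 12, 20, 28, 36])
        dens = event_density(events, bandwidth=2.0, event_type="dispersal")
        cc = correlate(events, dens, curve, event_type="dispersal")
        assert cc.status == "degenerate"

    def test_invariant_to_event_input_order(self):
        class FakeCurve:
            age_range = (0.0, 40.0)

            def __call__(self, ages):
                ages = np.atleast_1d(np.asarray(ages, dtype=float))
                return np.sin(ages / 4.0) * 5

        events = _events_at([3, 30, 11, 22, 7])
        dens = event_density(events, bandwidth=2.0, event_type="dispersal")
        a = correlate(events, dens, FakeCurve(), event_type="dispersal")
        b = correlate(list(reversed(events)), dens, FakeCurve(), event_type="dispersal")
        assert a.slope == pytest.approx(b.slope)
        assert a.p_value == pytest.approx(b.p_value)


def test_temperature_csv_roundtrip(tmp_path):
    series = _linear_series(n=40, hi=20.0)
    path = tmp_path / "temp.csv"
    series.to_csv(path)
    back = TemperatureSeries.from_csv(path)
    assert np.allclose(back.ages, series.ages)
    assert np.allclose(back.temperatures, series.temperatures)
    (tmp_path / "bad.csv").write_text("age,temp\n1,2\n")
    with pytest.raises(ValueError, match="age_ma"):
        TemperatureSeries.from_csv(tmp_path / "bad.csv")
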