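"""Paleotemperature smoothing and climate-change/event-density correlation.

The temperature input is a generic (age Ma, temperature degC) scatter such as a
deep-sea paleotemperature compilation.  A locally weighted degree-1 (tricube)
smoother gives an evaluable curve; the climate-change *intensity* at an age is
the absolute finite-difference slope of that curve, with the sign convention
that a positive slope means warming toward the present.  Event density (from
the kernel density of event times) is regressed on intensity by ordinary least
squares with each event as one degree of freedom, separately per event type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess

from .ancestral_events import BiogeoEvent, EventDensityCurve

__all__ = [
    "TemperatureSeries",
    "LoessCurve",
    "fit_loess",
    "slope_at",
    "intensity",
    "Period",
    "segment_periods",
    "ClimateCorrelation",
    "correlate",
]


@dataclass(frozen=True)
class TemperatureSeries:
    """(age Ma, temperature degC) scatter, any order, ages non-negative."""

    ages: np.ndarray
    temperatures: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        temps = np.asarray(self.temperatures, dtype=float)
        if ages.shape != temps.shape or ages.ndim != 1:
            raise ValueError("ages and temperatures must be 1-D arrays of equal length")
        if np.any(ages < 0):
            raise ValueError("ages must be non-negative (Ma before present)")
        order = np.argsort(ages)
        object.__setattr__(self, "ages", ages[order])
        object.__setattr__(self, "temperatures", temps[order])

    @classmethod
    def from_csv(cls, path) -> "TemperatureSeries":
        df = pd.read_csv(path)
        for col in ("age_ma", "temperature_c"):
            if col not in df.columns:
                raise ValueError(
                    f"temperature CSV must have columns 'age_ma' and 'temperature_c'; "
                    f"found {list(df.columns)}"
                )
        return cls(df["age_ma"].to_numpy(), df["temperature_c"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"age_ma": self.ages, "temperature_c": self.temperatures}
        ).to_csv(path, index=False, float_format="%.10g")

    @property
    def age_range(self) -> tuple[float, float]:
        return float(self.ages.min()), float(self.ages.max())


class LoessCurve:
    """Loess (degree-1, tricube-weighted) fit of a temperature scatter.

    Evaluable at any age within the data range; extrapolation is refused.
    """

    def __init__(self, series: TemperatureSeries, span: float = 0.25):
        if not 0 < span <= 1:
            raise ValueError(f"span must lie in (0, 1], got {span}")
        n = len(series.ages)
        if n < 4 or n * span < 4:
            raise ValueError(
                f"too few points for span {span}: local windows need >= 4 of {n} points"
            )
        self.series = series
        self.span = float(span)

    def __call__(self, ages) -> np.ndarray:
        scalar = np.isscalar(ages)
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        lo, hi = self.series.age_range
        if np.any(ages < lo - 1e-12) or np.any(ages > hi + 1e-12):
            raise ValueError(
                f"age outside the fitted range [{lo:g}, {hi:g}] Ma; extrapolation refused"
            )
        vals = lowess(
            self.series.temperatures,
            self.series.ages,
            frac=self.span,
            it=0,
            xvals=np.clip(ages, lo, hi),
        )
        return float(vals[0]) if scalar else np.asarray(vals, dtype=float)

    @property
    def age_range(self) -> tuple[float, float]:
        return self.series.age_range


def fit_loess(series: TemperatureSeries, span: float = 0.25) -> LoessCurve:
    return LoessCurve(series, span)


def slope_at(curve: LoessCurve, t: float, delta: float = 0.1) -> float:
    """Finite-difference slope dT/dt at age ``t`` (degC per Ma).

    Central difference ``(T(t - delta) - T(t + delta)) / (2 delta)`` -- with age
    decreasing toward the present, a positive value means warming toward the
    present.  Falls back to a one-sided difference at the data boundaries.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    lo, hi = curve.age_range
    if not lo <= t <= hi:
        raise ValueError(f"age {t} outside the fitted range [{lo:g}, {hi:g}] Ma")
    young = max(t - delta, lo)
    old = min(t + delta, hi)
    if old <= young:
        raise ValueError(f"degenerate difference window at t={t} with delta={delta}")
    vals = curve(np.array([young, old]))
    return float((vals[0] - vals[1]) / (old - young))


def intensity(slope: float) -> float:
    """Climate-change intensity: the absolute slope, degC per Ma."""
    if not np.isfinite(slope):
        raise ValueError(f"slope must be finite, got {slope}")
    return abs(float(slope))


@dataclass(frozen=True)
class Period:
    """A labeled age interval (older, younger], oldest bound exclusive upward."""

    label: str
    older: float
    younger: float

    def __post_init__(self):
        if self.older <= self.younger:
            raise ValueError(
                f"period {self.label!r} needs older > younger, got "
                f"({self.older}, {self.younger})"
            )


def segment_periods(
    oldest_age: float,
    boundaries: Sequence[float],
    labels: Sequence[str],
) -> list[Period]:
    """Partition (oldest_age, 0] at user-set boundaries into labeled periods.

    Boundaries are configuration (e.g. warm/cold alternation read off a
    temperature curve by the user), strictly decreasing and inside
    (0, oldest_age); ``len(labels) == len(boundaries) + 1``.
    """
    bounds = [float(b) for b in boundaries]
    if any(b2 >= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError(f"boundaries must be strictly decreasing: {bounds}")
    if bounds and (bounds[0] >= oldest_age or bounds[-1] <= 0):
        raise ValueError(
            f"boundaries {bounds} must lie strictly inside (0, {oldest_age:g})"
        )
    if len(labels) != len(bounds) + 1:
        raise ValueError(
            f"need {len(bounds) + 1} labels for {len(bounds)} boundaries, got {len(labels)}"
        )
    edges = [oldest_age, *bounds, 0.0]
    return [
        Period(label, older, younger)
        for label, older, younger in zip(labels, edges, edges[1:])
    ]


@dataclass(frozen=True)
class ClimateCorrelation:
    """OLS of event density on climate-change intensity for one event type."""

    event_type: str
    n: int
    status: str  # "ok" | "insufficient" | "degenerate"
    slope: float = float("nan")
    intercept: float = float("nan")
    r_squared: float = float("nan")
    p_value: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "event_type": self.event_type,
            "n": self.n,
            "status": self.status,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "ci95": [self.ci_low, self.ci_high],
        }


def correlate(
    events: Sequence[BiogeoEvent],
    density_curve: EventDensityCurve,
    curve: LoessCurve,
    delta: float = 0.1,
    event_type: str | None = None,
) -> ClimateCorrelation:
    """Regress per-event density on per-event climate-change intensity.

    For each event of the requested type: x = |slope| of the temperature curve
    at the event's time, y = the event-density curve evaluated there.  Returns
    the OLS slope with R^2, two-sided p and 95% CI; fewer than 3 events yields
    an "insufficient" result and a zero-variance predictor a "degenerate" one,
    never an exception.
    """
    etype = event_type if event_type is not None else density_curve.event_type
    sel = sorted(
        (ev for ev in events if etype in ("", "all") or ev.event_type == etype),
        key=lambda ev: ev.time,
    )
    n = len(sel)
    if n < 3:
        return ClimateCorrelation(event_type=etype, n=n, status="insufficient")
    times = np.array([ev.time for ev in sel])
    x = np.array([intensity(slope_at(curve, t, delta)) for t in times])
    y = density_curve.evaluate(times)
    table = pd.DataFrame(
        {"time_ma": times, "type": [ev.event_type for ev in sel], "intensity": x, "density": y}
    )
    if np.ptp(x) < 1e-8 * max(1.0, float(np.abs(x).max())):
        return ClimateCorrelation(event_type=etype, n=n, status="degenerate", table=table)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return ClimateCorrelation(
        event_type=etype,
        n=n,
        status="ok",
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        table=table,
    )
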