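"""Light-threshold estimation and monthly soft-evidence construction.

Seagrass growth depends on both light intensity and daily light duration.
Monthly saturation and compensation irradiances (I_k, I_c, umol photons
m^-2 s^-1) are predicted from water temperature with a k-nearest-neighbour
lookup on published photosynthetic records.  High-frequency benthic
irradiance is then classified day by day: a day is *above saturation* when
irradiance exceeds I_k for at least H_sat hours; under the 3-state model a
day failing that test is *below limitation* when irradiance exceeds I_c for
fewer than H_comp hours, and *below saturation* otherwise.  The fraction of
days per calendar month in each state is the soft-evidence vector delta
entered into the DBN.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .network import MONTHS

__all__ = [
    "TWO_STATE",
    "THREE_STATE",
    "LIGHT_STATES",
    "IrradianceThresholdKNN",
    "LightThresholds",
    "DurationThresholds",
    "DailyLightSeries",
    "MonthlyLightEvidence",
    "MissingDataError",
    "estimate_thresholds_knn",
    "hours_in_state",
    "classify_day",
    "classify_days",
    "classify_hours",
    "daily_light_hours",
    "monthly_evidence",
    "build_monthly_evidence",
    "default_threshold_grid",
]

TWO_STATE = "two_state"
THREE_STATE = "three_state"

LIGHT_STATES = {
    TWO_STATE: ("above_saturation", "below_saturation"),
    THREE_STATE: ("above_saturation", "below_saturation", "below_limitation"),
}


class MissingDataError(ValueError):
    """A day or month has no usable samples."""


class IrradianceThresholdKNN(BaseEstimator, RegressorMixin):
    """k-NN regression of (I_k, I_c) on water temperature.

    Distance is absolute temperature difference; ties at the k-th neighbour
    are broken toward the warmer record; the k neighbours' thresholds are
    averaged.  With k=1 this is a nearest-record lookup, which matches the
    piecewise-constant monthly threshold tables this approach produces.

    Parameters
    ----------
    k : int
        Number of neighbours (default 1).
    tie : {"warmer", "cooler"}
        Which record wins an exact distance tie.
    """

    def __init__(self, k: int = 1, tie: str = "warmer"):
        self.k = k
        self.tie = tie

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float)
        if X.size == 0:
            raise ValueError("training table is empty")
        if y.ndim != 2 or y.shape != (X.size, 2):
            raise ValueError("y must be an (n, 2) array of (I_k, I_c)")
        if np.any(~np.isfinite(X)):
            raise ValueError("training temperatures must be finite")
        if np.any(y[:, 0] <= y[:, 1]) or np.any(y[:, 1] <= 0):
            raise ValueError("training rows must satisfy I_k > I_c > 0")
        if not 1 <= self.k <= X.size:
            raise ValueError(f"k={self.k} outside [1, {X.size}]")
        if self.tie not in ("warmer", "cooler"):
            raise ValueError(f"unknown tie rule {self.tie!r}")
        self.temps_ = X
        self.thresholds_ = y
        return self

    def predict(self, X):
        check_is_fitted(self, "temps_")
        X = np.asarray(X, dtype=float).reshape(-1)
        sign = -1.0 if self.tie == "warmer" else 1.0
        out = np.empty((X.size, 2))
        for i, t in enumerate(X):
            d = np.abs(self.temps_ - t)
            order = np.lexsort((sign * self.temps_, d))
            out[i] = self.thresholds_[order[: self.k]].mean(axis=0)
        return out

    @classmethod
    def from_table(cls, training: pd.DataFrame, k: int = 1,
                   tie: str = "warmer") -> "IrradianceThresholdKNN":
        """Fit from a (species, temp_c, ik, ic) training table."""
        required = {"temp_c", "ik", "ic"}
        if not required <= set(training.columns):
            raise ValueError(f"training table needs columns {sorted(required)}")
        return cls(k=k, tie=tie).fit(training["temp_c"].to_numpy(),
                                     training[["ik", "ic"]].to_numpy())


@dataclass(frozen=True)
class LightThresholds:
    """Monthly saturation/compensation irradiances, Jan..Dec order."""

    ik: tuple[float, ...]
    ic: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ik) != 12 or len(self.ic) != 12:
            raise ValueError("need one (I_k, I_c) pair per calendar month")
        for m, (k, c) in enumerate(zip(self.ik, self.ic)):
            if not k > c:
                raise ValueError(f"I_k must exceed I_c ({MONTHS[m]}: {k} <= {c})")

    def for_month(self, month: str) -> tuple[float, float]:
        i = MONTHS.index(month)
        return self.ik[i], self.ic[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": MONTHS, "ik": self.ik, "ic": self.ic})


@dataclass(frozen=True)
class DurationThresholds:
    """Daily light-duration thresholds (hours) defining the light states."""

    model: str
    h_sat: float
    h_comp: float | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.model not in (TWO_STATE, THREE_STATE):
            raise ValueError(f"unknown light model {self.model!r}")
        if not 0 < self.h_sat <= 24:
            raise ValueError(f"H_sat must be in (0, 24], got {self.h_sat}")
        if self.model == THREE_STATE:
            if self.h_comp is None or not 0 < self.h_comp <= 24:
                raise ValueError(
                    f"three-state model needs H_comp in (0, 24], got {self.h_comp}")

    @property
    def states(self) -> tuple[str, ...]:
        return LIGHT_STATES[self.model]


# The published candidate grid: nine 2-state H_sat values and twenty-five
# 3-state (H_sat, H_comp) combinations.
_TWO_STATE_HSAT = (4.0, 5.0, 5.5, 6.0, 7.0, 7.5, 8.0, 8.5, 9.0)
_THREE_STATE_HSAT = (6.0, 7.0, 8.0, 8.5, 9.0)
_THREE_STATE_HCOMP = (8.5, 9.0, 10.0, 11.0, 12.0)


def default_threshold_grid(model: str | None = None) -> list[DurationThresholds]:
    """The default candidate duration thresholds for the sweep."""
    grid: list[DurationThresholds] = []
    if model in (None, TWO_STATE):
        grid += [DurationThresholds(TWO_STATE, h, None, f"Thdl-{i + 1}")
                 for i, h in enumerate(_TWO_STATE_HSAT)]
    if model in (None, THREE_STATE):
        grid += [DurationThresholds(THREE_STATE, hs, hc,
                                    f"Thdl-{i * 5 + j + 1}")
                 for i, hs in enumerate(_THREE_STATE_HSAT)
                 for j, hc in enumerate(_THREE_STATE_HCOMP)]
    if not grid:
        raise ValueError(f"unknown light model {model!r}")
    return grid


def estimate_thresholds_knn(monthly_temps: Sequence[float],
                            training: pd.DataFrame,
                            k: int = 1,
                            tie: str = "warmer") -> LightThresholds:
    """Predict monthly (I_k, I_c) from 12 monthly mean temperatures."""
    temps = np.asarray(monthly_temps, dtype=float)
    if temps.shape != (12,):
        raise ValueError("need exactly 12 monthly temperatures (Jan..Dec)")
    model = IrradianceThresholdKNN.from_table(training, k=k, tie=tie)
    pred = model.predict(temps)
    return LightThresholds(ik=tuple(pred[:, 0]), ic=tuple(pred[:, 1]))


@dataclass
class DailyLightSeries:
    """Regularly sampled benthic irradiance for one site.

    ``data`` has columns ``timestamp`` (datetime64) and ``irradiance``
    (umol photons m^-2 s^-1, non-negative).  The sampling interval is
    inferred from the median timestamp difference when not given.
    """

    site: str
    data: pd.DataFrame
    interval_minutes: float | None = None

    def __post_init__(self) -> None:
        required = {"timestamp", "irradiance"}
        if not required <= set(self.data.columns):
            raise ValueError(f"light series needs columns {sorted(required)}")
        if (self.data["irradiance"] < 0).any():
            raise ValueError("irradiance must be non-negative")
        if self.interval_minutes is None:
            ts = pd.to_datetime(self.data["timestamp"]).sort_values()
            if len(ts) < 2:
                raise ValueError("cannot infer sampling interval from <2 samples")
            dt = ts.diff().dropna().median()
            self.interval_minutes = dt.total_seconds() / 60.0

    @classmethod
    def from_csv(cls, path: str | Path, site: str | None = None) -> "DailyLightSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        if site is None:
            sites = df["site"].unique()
            if len(sites) != 1:
                raise ValueError(f"file holds multiple sites {list(sites)}; "
                                 "pass site=")
            site = sites[0]
        else:
            df = df[df["site"] == site]
        return cls(site=str(site), data=df[["timestamp", "irradiance"]]
                   .reset_index(drop=True))

    def iter_days(self):
        df = self.data.copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        for date, day in df.groupby(df["timestamp"].dt.normalize()):
            yield date, day


def hours_in_state(day: pd.DataFrame, threshold: float,
                   interval_minutes: float) -> float:
    """Hours of the day with irradiance at or above ``threshold``."""
    if len(day) == 0:
        raise MissingDataError("empty day of samples")
    n = int((day["irradiance"].to_numpy() >= threshold).sum())
    return n * interval_minutes / 60.0


def classify_day(day: pd.DataFrame, thresholds: LightThresholds,
                 durations: DurationThresholds, month: str,
                 interval_minutes: float) -> str:
    """Assign one day to a light state.

    Above saturation when hours at/above I_k reach H_sat; otherwise, under
    the 3-state model, below limitation when hours at/above I_c fall short
    of H_comp; below saturation in every remaining case.
    """
    ik, ic = thresholds.for_month(month)
    h_sat = hours_in_state(day, ik, interval_minutes)
    if h_sat >= durations.h_sat:
        return "above_saturation"
    if durations.model == THREE_STATE:
        h_comp = hours_in_state(day, ic, interval_minutes)
        if h_comp < durations.h_comp:
            return "below_limitation"
    return "below_saturation"


def daily_light_hours(series: DailyLightSeries, thresholds: LightThresholds,
                      max_missing_frac: float = 0.2) -> pd.DataFrame:
    """Per-day hours at/above the month's I_k and I_c.

    Days missing more than ``max_missing_frac`` of their expected samples
    are dropped (the record's sampling interval sets the expectation).
    The result (columns date, month, hours_sat, hours_comp) is independent
    of the duration thresholds, so one pass serves a whole candidate grid.
    """
    interval = series.interval_minutes
    expected = 24 * 60 / interval
    ts = pd.to_datetime(series.data["timestamp"])
    irr = series.data["irradiance"].to_numpy()
    month_idx = ts.dt.month.to_numpy() - 1
    ik = np.asarray(thresholds.ik)[month_idx]
    ic = np.asarray(thresholds.ic)[month_idx]
    df = pd.DataFrame({
        "date": ts.dt.normalize(),
        "above_sat": irr >= ik,
        "above_comp": irr >= ic,
    })
    g = df.groupby("date").agg(n=("above_sat", "size"),
                               sat=("above_sat", "sum"),
                               comp=("above_comp", "sum")).reset_index()
    g = g[g["n"] >= (1 - max_missing_frac) * expected]
    if len(g) == 0:
        raise MissingDataError(
            f"no usable days in light record for site {series.site!r}")
    return pd.DataFrame({
        "date": g["date"],
        "month": [MONTHS[d.month - 1] for d in g["date"]],
        "hours_sat": g["sat"] * interval / 60.0,
        "hours_comp": g["comp"] * interval / 60.0,
    })


def classify_hours(hours: pd.DataFrame,
                   durations: DurationThresholds) -> pd.DataFrame:
    """Assign light states given precomputed per-day hours."""
    above = hours["hours_sat"] >= durations.h_sat
    state = np.where(above, "above_saturation", "below_saturation")
    if durations.model == THREE_STATE:
        limited = ~above & (hours["hours_comp"] < durations.h_comp)
        state = np.where(limited, "below_limitation", state)
    out = hours[["date", "month"]].copy()
    out["state"] = state
    return out


def classify_days(series: DailyLightSeries, thresholds: LightThresholds,
                  durations: DurationThresholds,
                  max_missing_frac: float = 0.2) -> pd.DataFrame:
    """Classify every sufficiently sampled day in the record.

    Returns columns date, month, state.
    """
    hours = daily_light_hours(series, thresholds, max_missing_frac)
    return classify_hours(hours, durations)


@dataclass(frozen=True)
class MonthlyLightEvidence:
    """delta(state, month): per-calendar-month light-state probabilities."""

    model: str
    delta: np.ndarray  # (12, n_states), rows on the simplex, Jan..Dec

    def __post_init__(self) -> None:
        d = np.asarray(self.delta, dtype=float)
        if d.shape != (12, len(self.states)):
            raise ValueError(f"delta must be (12, {len(self.states)})")
        if np.any(d < 0) or np.any(np.abs(d.sum(axis=1) - 1) > 1e-9):
            raise ValueError("each month's delta must lie on the simplex")

    @property
    def states(self) -> tuple[str, ...]:
        return LIGHT_STATES[self.model]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"month": MONTHS[m], "state": s, "probability": self.delta[m, j]}
                for m in range(12) for j, s in enumerate(self.states)]
        return pd.DataFrame(rows)


def monthly_evidence(classified: pd.DataFrame,
                     model: str = TWO_STATE) -> MonthlyLightEvidence:
    """Pool classified days by calendar month into delta vectors.

    Months with no classified day raise a missing-month error: the DBN needs
    a full annual cycle of evidence.
    """
    states = LIGHT_STATES[model]
    delta = np.zeros((12, len(states)))
    for m, month in enumerate(MONTHS):
        sub = classified[classified["month"] == month]
        if len(sub) == 0:
            raise MissingDataError(f"no classified days for month {month}")
        counts = sub["state"].value_counts()
        delta[m] = [counts.get(s, 0) / len(sub) for s in states]
    return MonthlyLightEvidence(model=model, delta=delta)


def build_monthly_evidence(series: DailyLightSeries | pd.DataFrame,
                           thresholds: LightThresholds | None,
                           durations: DurationThresholds,
                           max_missing_frac: float = 0.2) -> MonthlyLightEvidence:
    """Full light pipeline: classify days, pool into monthly delta evidence.

    ``series`` may also be a precomputed ``daily_light_hours`` frame (in
    which case ``thresholds`` is ignored), letting a threshold sweep reuse
    one pass over the raw record.
    """
    if isinstance(series, pd.DataFrame):
        hours = series
    else:
        hours = daily_light_hours(series, thresholds, max_missing_frac)
    return monthly_evidence(classify_hours(hours, durations),
                            model=durations.model)
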