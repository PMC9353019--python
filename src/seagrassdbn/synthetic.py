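"""Synthetic site data with the statistical structure the pipeline assumes.

Emulates a temperate-lagoon survey: 10-minute benthic irradiance records
with a half-sinusoid diel curve whose daylength swings seasonally (8-16 h),
multiplicative lognormal sampling noise and day-level attenuation events
(turbidity); a sinusoidal monthly temperature climatology spanning roughly
11-27 degC; photosynthetic (temperature, I_k, I_c) training tables; and
monthly shoot-density observations sampled from a known DBN run under known
light-duration thresholds, so that end-to-end threshold recovery can be
tested without field data.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import DEFAULT_STATE_VALUES, StateValueMap, run_scenario
from .light import (TWO_STATE, DailyLightSeries, DurationThresholds,
                    LightThresholds, build_monthly_evidence,
                    estimate_thresholds_knn)
from .network import MONTHS, NetworkSpec, load_default_network

__all__ = [
    "SiteScenario",
    "znoltei_anchor_training_table",
    "gen_training_table",
    "gen_temperature",
    "gen_light_series",
    "gen_observations",
    "arcachon_like_scenarios",
    "scenario_thresholds",
]


@dataclass(frozen=True)
class SiteScenario:
    """Generating conditions for one synthetic site.

    ``peak_ratio`` scales the clear-day midday irradiance peak relative to
    the month's saturation irradiance I_k, so sites differ in how many
    daily hours clear the saturation threshold; ``attenuation_rate`` is the
    per-day probability of a turbidity event multiplying the whole day by
    ``attenuation_factor``.  ``true_durations`` are the duration thresholds
    under which the observation-generating DBN run is driven.
    """

    site: str
    months: int = 36
    seed: int = 0
    start: str = "2015-12-01"
    peak_ratio: float = 2.0
    peak_by_month: tuple[float, ...] | None = None
    noise_sd: float = 0.25
    attenuation_rate: float = 0.15
    attenuation_factor: float = 0.5
    daylength_mean: float = 12.0
    daylength_amp: float = 4.0
    temp_mean: float = 19.0
    temp_amp: float = 8.0
    temp_noise_sd: float = 0.0
    true_durations: DurationThresholds = field(
        default_factory=lambda: DurationThresholds(TWO_STATE, 6.0, id="true"))
    species: str = "Z. noltei"
    location: str = "PTIT"

    def __post_init__(self) -> None:
        if self.months < 25:
            raise ValueError("scenario must cover >= 25 months so a 24-month "
                             "initialization period fits")
        for name in ("noise_sd", "attenuation_rate", "peak_ratio",
                     "daylength_mean", "temp_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.attenuation_factor <= 1:
            raise ValueError("attenuation_factor must be in [0, 1]")

    def site_config(self) -> dict[str, str]:
        return {"species_presence": self.species, "location_type": self.location}


def znoltei_anchor_training_table() -> pd.DataFrame:
    """Synthetic photosynthetic training table for Z. noltei.

    A three-record stand-in for the published per-temperature
    photosynthetic records (which are not shipped): each anchor carries the
    (I_k, I_c) pair reported for its temperature band, placed so that a
    nearest-neighbour lookup with the warm-tie rule reproduces the monthly
    threshold table at 11-27 degC.
    """
    return pd.DataFrame({
        "species": ["Z. noltei"] * 3,
        "temp_c": [12.5, 17.5, 24.0],
        "ik": [174.0, 305.0, 254.0],
        "ic": [19.0, 35.0, 33.0],
    })


def gen_training_table(n_records: int = 24, seed: int = 0) -> pd.DataFrame:
    """A generic (species, temp_c, ik, ic) table with temperature-linked
    thresholds (I_k strictly increasing in temperature, I_k > I_c)."""
    if n_records < 1:
        raise ValueError("need at least one record")
    rng = np.random.default_rng(seed)
    temps = np.sort(rng.uniform(8.0, 28.0, size=n_records))
    ik = 100.0 + 8.0 * temps
    ic = 10.0 + 1.0 * temps
    return pd.DataFrame({
        "species": ["Z. noltei"] * n_records,
        "temp_c": temps, "ik": ik, "ic": ic,
    })


def gen_temperature(scn: SiteScenario) -> np.ndarray:
    """Monthly mean water temperature, Jan..Dec (degC).

    Sinusoid with a 12-month period, coolest in February and warmest in
    August; the default mean/amplitude spans roughly 11-27 degC.
    """
    m = np.arange(1, 13)
    temps = scn.temp_mean - scn.temp_amp * np.cos(2 * np.pi * (m - 2) / 12.0)
    if scn.temp_noise_sd > 0:
        rng = np.random.default_rng(scn.seed + 1)
        temps = temps + rng.normal(0, scn.temp_noise_sd, size=12)
    return temps


def scenario_thresholds(scn: SiteScenario,
                        training: pd.DataFrame | None = None,
                        k: int = 1) -> LightThresholds:
    """Monthly (I_k, I_c) for the scenario via the k-NN lookup."""
    if training is None:
        training = znoltei_anchor_training_table()
    return estimate_thresholds_knn(gen_temperature(scn), training, k=k)


def _daylength(doy: np.ndarray, scn: SiteScenario) -> np.ndarray:
    return scn.daylength_mean + scn.daylength_amp * np.cos(
        2 * np.pi * (doy - 172) / 365.25)


def gen_light_series(scn: SiteScenario,
                     thresholds: LightThresholds | None = None) -> DailyLightSeries:
    """10-minute benthic irradiance over the scenario months.

    Clear-sky shape is a half-sinusoid over the seasonal daylength with a
    midday peak of ``peak_ratio`` times the month's I_k (or the explicit
    ``peak_by_month``), multiplied by lognormal noise (unit median) and by
    day-level attenuation events; zero at night.
    """
    if thresholds is None:
        thresholds = scenario_thresholds(scn)
    if scn.peak_by_month is not None:
        peaks = np.asarray(scn.peak_by_month, dtype=float)
        if peaks.shape != (12,):
            raise ValueError("peak_by_month needs 12 entries (Jan..Dec)")
    else:
        peaks = scn.peak_ratio * np.asarray(thresholds.ik)

    rng = np.random.default_rng(scn.seed)
    start = pd.Timestamp(scn.start)
    end = start + pd.DateOffset(months=scn.months)
    ts = pd.date_range(start, end, freq="10min", inclusive="left")
    hours = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0
    doy = ts.dayofyear.to_numpy().astype(float)
    month_idx = ts.month.to_numpy() - 1

    L = _daylength(doy, scn)
    sunrise = 12.0 - L / 2.0
    phase = (hours - sunrise) / L
    shape = np.where((phase > 0) & (phase < 1), np.sin(np.pi * phase), 0.0)
    irr = peaks[month_idx] * shape
    if scn.noise_sd > 0:
        irr = irr * rng.lognormal(mean=0.0, sigma=scn.noise_sd, size=len(irr))
    # day-level attenuation events (one Bernoulli per calendar day)
    day_codes = (ts.normalize().asi8 // 86_400_000_000_000)
    day_codes = day_codes - day_codes.min()
    n_days = int(day_codes.max()) + 1
    attenuated = rng.random(n_days) < scn.attenuation_rate
    factor = np.where(attenuated[day_codes], scn.attenuation_factor, 1.0)
    irr = irr * factor

    data = pd.DataFrame({"timestamp": ts, "irradiance": irr})
    return DailyLightSeries(site=scn.site, data=data, interval_minutes=10.0)


def gen_observations(scn: SiteScenario,
                     net: NetworkSpec | None = None,
                     thresholds: LightThresholds | None = None,
                     light: DailyLightSeries | None = None,
                     state_values: StateValueMap = DEFAULT_STATE_VALUES,
                     settle_months: int = 24) -> pd.DataFrame:
    """Monthly shoot-density observations sampled from the generating DBN.

    The true network is rolled out under the scenario's light evidence
    (built with the *true* duration thresholds); after a settling period a
    state is sampled from each month's posterior marginal and a density is
    drawn uniformly within the state's range (the Zero state maps to 0).
    Returns columns site, month_index, calendar_month, shoot_density.
    """
    if net is None:
        n_light = 3 if scn.true_durations.model != TWO_STATE else 2
        net = load_default_network(n_light)
    if thresholds is None:
        thresholds = scenario_thresholds(scn)
    if light is None:
        light = gen_light_series(scn, thresholds)
    evidence = build_monthly_evidence(light, thresholds, scn.true_durations)
    start_month = MONTHS[pd.Timestamp(scn.start).month - 1]
    T = settle_months + scn.months
    traj = run_scenario(net, scn.site_config(), evidence.delta, T,
                        burn_in=settle_months, start_month=start_month)
    resp = traj.response()

    rng = np.random.default_rng(scn.seed + 7)
    rows = []
    for i in range(scn.months):
        p = resp.probs[i]
        state = resp.states[rng.choice(len(p), p=p / p.sum())]
        lo, hi = state_values.ranges[state]
        density = lo if hi == lo else rng.uniform(lo, hi)
        rows.append({
            "site": scn.site,
            "month_index": i + 1,
            "calendar_month": resp.calendar_months[i],
            "shoot_density": density,
        })
    return pd.DataFrame(rows)


def arcachon_like_scenarios(seed: int = 0, months: int = 36,
                            true_durations: DurationThresholds | None = None,
                            ) -> dict[str, SiteScenario]:
    """Four synthetic sites patterned on a temperate-lagoon survey.

    Sites differ in available light: one chronically dim site, two
    mid-range sites and one bright site, so the hours-above-saturation
    distribution straddles the candidate H_sat grid.
    """
    if true_durations is None:
        true_durations = DurationThresholds(TWO_STATE, 6.0, id="true")
    ratios = {"FONT": 1.5, "GAIL": 2.0, "ILE": 2.8, "ROCH": 1.9}
    return {
        site: SiteScenario(site=site, months=months, seed=seed + i,
                           peak_ratio=r, true_durations=true_durations)
        for i, (site, r) in enumerate(sorted(ratios.items()))
    }
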