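"""Validation of simulated shoot-density trajectories against observations.

Monthly observed shoot densities are discretised into the four density
states and smoothed into monthly state probabilities with a Bayesian
cumulative-link (proportional-odds) ordinal regression

    g(y_{s,t}) = beta0_j + beta1 * sin(pi * t / 6) + beta2 * cos(pi * t / 6) + u_s,

where g is the logit link, beta0_j are the ordered global cut points,
beta1 and beta2 the seasonal slopes on a 12-month harmonic of the calendar
month t (the cosine term frees the phase of the seasonal cycle, which need
not peak in March), and u_s a site random intercept.  The fit uses ensemble MCMC with flat
(improper) priors on the cut points and slope, and split-R-hat convergence
diagnostics.  Simulated and observed per-month state probability vectors
are then compared by mean squared error over months and the four states,
and candidate light-duration thresholds are swept to find the per-site
minimum-MSE threshold (with the simpler 2-state light model preferred at
near-ties).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .inference import (DEFAULT_STATE_VALUES, PosteriorTrajectory,
                        StateValueMap, run_scenario)
from .light import (TWO_STATE, DailyLightSeries, DurationThresholds,
                    LightThresholds, build_monthly_evidence,
                    daily_light_hours)
from .network import MONTHS, NetworkSpec

__all__ = [
    "DENSITY_STATES",
    "SeasonalOrdinalRegression",
    "DegenerateDataError",
    "ConvergenceError",
    "fit_ordinal_seasonal",
    "observed_state_probs",
    "mse",
    "trajectory_monthly_mean",
    "SweepResult",
    "threshold_sweep",
]

log = logging.getLogger(__name__)

#: Density states in network order (descending density).
DENSITY_STATES = ("High", "Moderate", "Low", "Zero")
#: The same states in ascending ordinal order used by the regression.
_ORDINAL_ORDER = ("Zero", "Low", "Moderate", "High")


class DegenerateDataError(ValueError):
    """All observations fall in a single density state."""


class ConvergenceError(RuntimeError):
    """The sampler failed the split-R-hat diagnostic."""


def _seasonal(t: np.ndarray) -> np.ndarray:
    """Annual-harmonic design columns sin(pi t/6), cos(pi t/6) -> (n, 2)."""
    w = np.pi * np.asarray(t, dtype=float) / 6.0
    return np.stack([np.sin(w), np.cos(w)], axis=-1)


class SeasonalOrdinalRegression(BaseEstimator):
    """Bayesian cumulative-logit ordinal regression with a seasonal sine.

    Parameters
    ----------
    n_walkers, n_steps, n_burn : int
        Ensemble-sampler geometry.  Posterior draws are the post-burn
        samples of all walkers.
    sigma_prior_scale : float
        Half-normal scale for the site random-effect standard deviation
        (all other parameters carry flat priors).
    rhat_threshold : float
        Maximum tolerated split-R-hat; exceeded -> ConvergenceError when
        ``check_convergence`` is set.
    random_state : int
        Seed for walker initialisation and sampling.

    Fitted attributes
    -----------------
    cutpoints_ : (3,) posterior-mean ordered cut points
    beta1_ : posterior-mean seasonal slope
    beta1_ci_ : (2,) central 95% interval for the slope
    site_effects_ : dict site -> posterior-mean random intercept
    sigma_ : posterior-mean random-effect scale
    rhat_ : dict parameter -> split-R-hat
    posterior_ : dict parameter -> draws (n_draws,) or (n_draws, n_sites)
    """

    def __init__(self, n_walkers: int = 32, n_steps: int = 6000,
                 n_burn: int = 2500, sigma_prior_scale: float = 2.5,
                 rhat_threshold: float = 1.05, check_convergence: bool = True,
                 random_state: int = 0):
        self.n_walkers = n_walkers
        self.n_steps = n_steps
        self.n_burn = n_burn
        self.sigma_prior_scale = sigma_prior_scale
        self.rhat_threshold = rhat_threshold
        self.check_convergence = check_convergence
        self.random_state = random_state

    # ---- model -----------------------------------------------------------

    def _log_prob(self, theta: np.ndarray, month: np.ndarray,
                  site_idx: np.ndarray, y: np.ndarray, n_sites: int) -> float:
        # non-centred random effects: u_s = sigma * z_s with z_s ~ N(0, 1)
        c = theta[:3]
        if not (c[0] < c[1] < c[2]):
            return -np.inf
        beta = theta[3:5]
        z = theta[5:5 + n_sites]
        log_sigma = theta[5 + n_sites]
        if not -10.0 < log_sigma < 5.0:
            return -np.inf
        sigma = np.exp(log_sigma)
        # half-normal prior on sigma (+ log-Jacobian of the log transform)
        lp = -0.5 * (sigma / self.sigma_prior_scale) ** 2 + log_sigma
        lp += -0.5 * np.sum(z ** 2)
        u = sigma * z
        eta = _seasonal(month) @ beta + u[site_idx]
        cum = expit(c[None, :] - eta[:, None])           # (n, 3)
        probs = np.diff(np.concatenate(
            [np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))], axis=1),
            axis=1)                                       # (n, 4) ascending
        p = probs[np.arange(len(y)), y]
        if np.any(p <= 0):
            return -np.inf
        return lp + float(np.sum(np.log(p)))

    # ---- sklearn surface ---------------------------------------------------

    def fit(self, X: pd.DataFrame, y: Sequence[str] | np.ndarray):
        """Fit to observed states.

        X is a frame with columns ``site`` and ``month`` (calendar month
        number 1..12); y gives the observed density state per row, as
        labels from DENSITY_STATES or ordinal codes 0..3 (Zero..High).
        """
        X = pd.DataFrame(X)
        if not {"site", "month"} <= set(X.columns):
            raise ValueError("X needs columns 'site' and 'month'")
        y = np.asarray(y)
        if y.dtype.kind in "UO":
            codes = np.array([_ORDINAL_ORDER.index(s) for s in y])
        else:
            codes = y.astype(int)
        if codes.min() < 0 or codes.max() > 3:
            raise ValueError("ordinal codes must be in 0..3")
        if len(np.unique(codes)) < 2:
            raise DegenerateDataError(
                "all observations fall in one density state; the ordinal "
                "model is not identifiable")
        sites = sorted(X["site"].unique())
        if len(sites) < 2:
            raise ValueError("need observations from at least 2 sites")
        site_idx = X["site"].map({s: i for i, s in enumerate(sites)}).to_numpy()
        month = X["month"].to_numpy(dtype=float)

        n_sites = len(sites)
        ndim = 3 + 2 + n_sites + 1
        rng = np.random.default_rng(self.random_state)

        # moment-style start: cut points from pooled cumulative frequencies
        cum = np.cumsum(np.bincount(codes, minlength=4))[:3] / len(codes)
        cum = np.clip(cum, 0.02, 0.98)
        c0 = np.log(cum / (1 - cum))
        c0 = np.maximum.accumulate(c0 + np.array([0.0, 1e-3, 2e-3]))
        start = np.concatenate([c0, [0.0, 0.0], np.zeros(n_sites), [np.log(0.5)]])
        p0 = start[None, :] + 0.05 * rng.standard_normal((self.n_walkers, ndim))
        p0[:, :3] = np.sort(p0[:, :3], axis=1)  # keep cut points ordered

        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(
            self.n_walkers, ndim, self._log_prob,
            args=(month, site_idx, codes, n_sites), moves=moves)
        sampler.random_state = np.random.RandomState(self.random_state).get_state()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sampler.run_mcmc(p0, self.n_steps, progress=False)

        chain = sampler.get_chain()[self.n_burn:]          # (draw, walker, dim)
        chain = np.swapaxes(chain, 0, 1).copy()            # (walker, draw, dim)
        # report on the natural scale: u_s = sigma * z_s
        sigma_draws = np.exp(chain[:, :, 5 + n_sites])
        chain[:, :, 5:5 + n_sites] *= sigma_draws[:, :, None]
        names = ([f"c{j + 1}" for j in range(3)] + ["beta1", "beta2"] +
                 [f"u[{s}]" for s in sites] + ["log_sigma"])
        self.rhat_ = {}
        for d, name in enumerate(names):
            ds = az.convert_to_dataset(chain[:, :, d])
            self.rhat_[name] = float(az.rhat(ds)["x"].values)
        flat = chain.reshape(-1, ndim)
        self.sites_ = sites
        self.cutpoints_ = flat[:, :3].mean(axis=0)
        self.beta1_ = float(flat[:, 3].mean())
        self.beta2_ = float(flat[:, 4].mean())
        self.beta1_ci_ = tuple(np.percentile(flat[:, 3], [2.5, 97.5]))
        self.site_effects_ = {s: float(flat[:, 5 + i].mean())
                              for i, s in enumerate(sites)}
        self.sigma_ = float(np.exp(flat[:, 5 + n_sites]).mean())
        self.posterior_ = {
            "cutpoints": flat[:, :3],
            "beta1": flat[:, 3],
            "beta2": flat[:, 4],
            "u": flat[:, 5:5 + n_sites],
            "sigma": np.exp(flat[:, 5 + n_sites]),
        }
        max_rhat = max(self.rhat_.values())
        if self.check_convergence and max_rhat > self.rhat_threshold:
            raise ConvergenceError(
                f"split-R-hat diagnostic failed (max {max_rhat:.3f} > "
                f"{self.rhat_threshold}): {self.rhat_}")
        return self

    def predict_state_probs(self, site: str, months: Sequence[int],
                            max_draws: int = 500) -> np.ndarray:
        """Posterior-mean state probabilities, network order (High..Zero).

        An unknown site falls back to the population level (random effect
        zero) with a logged warning.  Returns an array (len(months), 4).
        """
        if not hasattr(self, "posterior_"):
            raise RuntimeError("model is not fitted")
        draws = self.posterior_["beta1"].shape[0]
        step = max(1, draws // max_draws)
        sel = slice(0, None, step)
        c = self.posterior_["cutpoints"][sel]              # (d, 3)
        b = np.stack([self.posterior_["beta1"][sel],
                      self.posterior_["beta2"][sel]], axis=1)   # (d, 2)
        if site in self.sites_:
            u = self.posterior_["u"][sel, self.sites_.index(site)]
        else:
            log.warning("site %r not seen during fitting; using the "
                        "population-level effect", site)
            u = np.zeros(b.shape[0])
        t = np.asarray(months, dtype=float)
        eta = b @ _seasonal(t).T + u[:, None]                    # (d, m)
        cum = expit(c[:, None, :] - eta[:, :, None])             # (d, m, 3)
        pad0 = np.zeros(cum.shape[:2] + (1,))
        pad1 = np.ones(cum.shape[:2] + (1,))
        probs = np.diff(np.concatenate([pad0, cum, pad1], axis=2), axis=2)
        mean = probs.mean(axis=0)                                # (m, 4) ascending
        return mean[:, ::-1]                                     # High..Zero


def fit_ordinal_seasonal(obs: pd.DataFrame,
                         state_values: StateValueMap = DEFAULT_STATE_VALUES,
                         **kwargs) -> SeasonalOrdinalRegression:
    """Discretise observed densities and fit the seasonal ordinal model.

    ``obs`` needs columns site, calendar_month (Jan..Dec labels) or month
    (1..12), and shoot_density (shoots m^-2).
    """
    obs = obs.copy()
    if "month" not in obs.columns:
        obs["month"] = obs["calendar_month"].map(
            {m: i + 1 for i, m in enumerate(MONTHS)})
    states = obs["shoot_density"].map(state_values.discretize)
    X = obs[["site", "month"]]
    return SeasonalOrdinalRegression(**kwargs).fit(X, states.to_numpy())


def observed_state_probs(fit: SeasonalOrdinalRegression, site: str,
                         months: Sequence[int] = range(1, 13)) -> pd.DataFrame:
    """Monthly observed-state probabilities for a site (network state order)."""
    probs = fit.predict_state_probs(site, list(months))
    out = pd.DataFrame(probs, columns=list(DENSITY_STATES))
    out.insert(0, "month", list(months))
    return out


def mse(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Mean squared difference over aligned months and the four states.

    For probability vectors the value lies in [0, 0.5]; two opposite
    indicator vectors attain the maximum.
    """
    p = np.asarray(predicted, dtype=float)
    q = np.asarray(observed, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"misaligned shapes {p.shape} vs {q.shape}")
    if p.size == 0:
        raise ValueError("no overlapping months to compare")
    return float(np.mean((p - q) ** 2))


def trajectory_monthly_mean(traj: PosteriorTrajectory,
                            states: Sequence[str] = DENSITY_STATES) -> np.ndarray:
    """Average the post-burn-in trajectory by calendar month -> (12, 4)."""
    resp = traj.response()
    if resp.calendar_months is None:
        raise ValueError("trajectory lacks calendar month labels")
    reorder = [resp.states.index(s) for s in states]
    out = np.full((12, len(states)), np.nan)
    cm = np.array(resp.calendar_months)
    for m, month in enumerate(MONTHS):
        mask = cm == month
        if mask.any():
            out[m] = resp.probs[mask].mean(axis=0)[reorder]
    return out


@dataclass
class SweepResult:
    """Outcome of a light-threshold sweep."""

    table: pd.DataFrame                       # site, model, threshold id, mse
    best_per_site: pd.DataFrame               # argmin row per (site, model)
    selected_model: str
    selected: pd.DataFrame                    # argmin row per site, chosen model

    def consensus(self) -> pd.Series:
        """The single bay-wide threshold: argmin of the across-site mean MSE
        within the selected light model."""
        sub = self.table[self.table["model"] == self.selected_model]
        mean = (sub.groupby(["threshold_id", "h_sat", "h_comp"], dropna=False)
                ["mse"].mean().reset_index())
        return mean.loc[mean["mse"].idxmin()]

    def to_wide(self) -> pd.DataFrame:
        """Sites as columns, thresholds as rows (the report layout)."""
        meta = (self.table[["model", "threshold_id", "h_sat", "h_comp"]]
                .drop_duplicates())
        wide = (self.table.pivot(index=["model", "threshold_id"],
                                 columns="site", values="mse").reset_index())
        return meta.merge(wide, on=["model", "threshold_id"])


def threshold_sweep(
    nets: Mapping[str, NetworkSpec],
    site_light: Mapping[str, DailyLightSeries],
    site_thresholds: Mapping[str, LightThresholds],
    grid: Sequence[DurationThresholds],
    obs: pd.DataFrame,
    site_config: Mapping[str, Mapping[str, str]] | Mapping[str, str],
    state_values: StateValueMap = DEFAULT_STATE_VALUES,
    burn_in: int = 24,
    response_months: int = 36,
    start_month: str = "Jan",
    parsimony_margin: float = 0.02,
    ordinal_kwargs: Mapping | None = None,
    fitted_ordinal: SeasonalOrdinalRegression | None = None,
) -> SweepResult:
    """Score every candidate duration threshold by per-site MSE.

    For each site and candidate, monthly light evidence is built from the
    site's irradiance record, the DBN is rolled out (burn-in plus a response
    period), and the response-period state probabilities, averaged by
    calendar month, are compared with the observed state probabilities from
    the ordinal seasonal fit.  Selection is the per-site argmin; across
    light models, the 2-state model is preferred unless the 3-state model
    improves the mean MSE by more than ``parsimony_margin``.
    """
    if not grid:
        raise ValueError("threshold grid is empty")
    sites = sorted(site_light)
    if set(site_thresholds) < set(sites):
        raise ValueError("missing monthly irradiance thresholds for some sites")
    per_site_config = site_config
    if sites and not isinstance(next(iter(site_config.values()), None), Mapping):
        per_site_config = {s: site_config for s in sites}

    fit = fitted_ordinal
    if fit is None:
        fit = fit_ordinal_seasonal(obs, state_values, **(ordinal_kwargs or {}))
    observed = {s: observed_state_probs(fit, s)[list(DENSITY_STATES)].to_numpy()
                for s in sites}

    # one pass over each raw light record serves the whole candidate grid
    site_hours = {s: daily_light_hours(site_light[s], site_thresholds[s])
                  for s in sites}
    T = burn_in + response_months
    rows = []
    for thr in grid:
        net = nets[thr.model]
        for s in sites:
            ev = build_monthly_evidence(site_hours[s], None, thr)
            traj = run_scenario(net, per_site_config[s], ev.delta, T,
                                burn_in=burn_in, start_month=start_month)
            pred = trajectory_monthly_mean(traj)
            ok = ~np.isnan(pred).any(axis=1)
            rows.append({
                "site": s, "model": thr.model, "threshold_id": thr.id,
                "h_sat": thr.h_sat, "h_comp": thr.h_comp,
                "mse": mse(pred[ok], observed[s][ok]),
            })
        log.info("scored threshold %s (%s, H_sat=%s, H_comp=%s)",
                 thr.id, thr.model, thr.h_sat, thr.h_comp)
    table = pd.DataFrame(rows)

    best_rows = (table.sort_values("mse")
                 .groupby(["site", "model"], as_index=False).first())
    models = sorted(table["model"].unique())
    if len(models) == 1:
        selected_model = models[0]
    else:
        means = table.groupby("model")["mse"].min()
        # per-site mean of each model's best threshold
        site_best = table.sort_values("mse").groupby(
            ["model", "site"], as_index=False).first()
        model_mean = site_best.groupby("model")["mse"].mean()
        selected_model = TWO_STATE
        other = [m for m in models if m != TWO_STATE][0]
        if model_mean.get(other, np.inf) + parsimony_margin < model_mean.get(
                TWO_STATE, np.inf):
            selected_model = other
    chosen = best_rows[best_rows["model"] == selected_model].reset_index(drop=True)
    return SweepResult(table=table, best_per_site=best_rows,
                       selected_model=selected_model, selected=chosen)
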