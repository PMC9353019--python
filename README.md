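# seagrass-dbn

Adapting a general seagrass ecosystem dynamic Bayesian network (DBN) to a
new site is mostly a quantification problem: the network structure travels,
but the conditional probability tables (CPTs), the light thresholds that
drive the environmental evidence, and the validation against local shoot
density all have to be rebuilt from local knowledge and data.  This package
implements that quantification pipeline for *Zostera* meadows as a tested,
reusable library with a command-line front end.  It is aimed at ecological
modellers who have (a) an expert-elicited rule table per node, (b) a
high-frequency benthic irradiance and temperature record per site, and
(c) monthly shoot-density observations — or who want to exercise the whole
workflow on the built-in synthetic survey generator.

## The model

The DBN steps monthly.  Within a slice, site conditions (species presence,
location type), the time of year and the light state drive physiological
status, seasonal baseline shoot density, density loss and seed recruitment;
shoot density (states High / Moderate / Low / Zero) carries the only
inter-slice edge.  The stages are:

1. **CPT compilation** — expert rules map scenarios over parent states
   (single states, month groups, or NA for "any") to linguistic certainty
   labels (*extremely likely* … *impossible*), numerically
   `{0.99, 5/6, 2/3, 1/2, 1/3, 1/6, 0.01, 0}`.  Each expanded row is
   renormalised to a distribution, preserving elicited odds.
2. **Light thresholds** — monthly saturation and compensation irradiances
   (I_k, I_c, μmol photons m⁻² s⁻¹) are predicted from monthly water
   temperature by k-nearest-neighbour lookup on published photosynthetic
   records (k = 1, ties to the warmer record).
3. **Monthly light evidence** — a day is *above saturation* when irradiance
   ≥ I_k for at least H_sat hours (a 3-state variant adds *below
   limitation* via I_c and H_comp).  The fraction of days per calendar
   month in each state is the soft-evidence vector δ(state, month),
   entered into the DBN as virtual (likelihood) evidence.
4. **Rollout** — exact inference (interface forward–backward over the
   unrolled network) yields the posterior shoot-density marginal per month,
   with a 24-month initialization period, plus a weighted-mean density
   trajectory E[d] = Σ p(state)·midpoint(state) with an IQR from the
   mixture of within-state uniforms.
5. **Validation and threshold selection** — observed densities are
   discretised and smoothed into monthly state probabilities with a
   Bayesian cumulative-logit ordinal regression
   `g(y) = β0_j + β1 sin(πt/6) + β2 cos(πt/6) + u_site`, and each candidate
   (H_sat, H_comp) is scored by the mean squared error between predicted
   and observed state probabilities; the per-site argmin and a bay-wide
   consensus are reported, preferring the 2-state light model at near-ties.

## Worked example

```bash
seagrass-dbn synth --outdir data --seed 1 --months 72   # 4 synthetic sites
seagrass-dbn thresholds --temps data/temperature.csv --out thr.csv
seagrass-dbn evidence --light data/light.csv --thresholds thr.csv \
    --h-sat 6 --out ev.csv
seagrass-dbn simulate --evidence ev.csv --months 60 --start-month Dec \
    --out traj.csv
seagrass-dbn sweep --light data/light.csv --thresholds thr.csv \
    --obs data/observations.csv --start-month Dec --out mse.csv
```

The sweep prints, for this seed:

```
selected light model: two_state
  FONT: H_sat=5.5 H_comp=None MSE=0.0023
  GAIL: H_sat=7.0 H_comp=None MSE=0.0027
  ILE: H_sat=6.0 H_comp=None MSE=0.0030
  ROCH: H_sat=5.5 H_comp=None MSE=0.0038
bay-wide threshold: H_sat=6.0 (mean MSE 0.0043)
```

The survey was generated under H_sat = 6 h: individual sites' minimum-MSE
candidates jitter one grid step around the truth (monthly observations are
noisy draws from the meadow's state distribution), while the bay-wide
consensus — the argmin of the across-site mean MSE — recovers 6 h; on an
unlucky seed it too can land one step off (see `docs/methods.md` on survey
length and power).  `thr.csv` holds the monthly (I_k, I_c) pairs (174/19 in
winter months, 305/35 in spring/autumn, 254/33 in summer), `ev.csv` the
monthly δ vectors, and `traj.csv` the state-probability and weighted-mean
trajectories with the first 24 months flagged as initialization.

Equivalent library calls: `load_default_network`,
`estimate_thresholds_knn`, `build_monthly_evidence`, `run_scenario`,
`fit_ordinal_seasonal`, `threshold_sweep` (see docstrings).

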