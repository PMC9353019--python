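# Methods

## Network representation and CPT compilation

The DBN is a two-slice template: nodes with ordered discrete state spaces,
an acyclic intra-slice graph, and inter-slice edges read as "source at
month t−1 feeds target at month t".  CPTs are compiled from expert rule
tables in which each row is a scenario: one antecedent per parent (a state,
a set of states such as a month group, or NA meaning the row is independent
of that parent) and one linguistic label per child state.  Compilation
enumerates the full Cartesian product of parent states, requires exactly
one matching row per combination (zero matches is a completeness error;
two, an overlap error — surfacing elicitation inconsistencies rather than
silently taking the last rule), replaces labels by numeric weights and
divides each row by its sum.  Elicited label rows need not sum to one
(e.g. 5/6 + 1/6 + 0.01 + 0.01 = 1.02); proportional renormalisation
preserves the elicited odds.  The default label map is

| label | weight |
|---|---|
| extremely likely | 0.99 |
| very likely | 5/6 |
| likely | 2/3 |
| 50/50 | 1/2 |
| unlikely | 1/3 |
| very unlikely | 1/6 |
| extremely unlikely | 0.01 |
| impossible | 0 |

The 0.99/0 endpoints are fixed by symmetry with "extremely unlikely";
the map is configurable but must stay strictly monotone in that ranking.

The shipped default network is a deliberately reduced ten-node slice —
time of year (12 states), species presence (Z. marina / Z. noltei),
location type (subtidal PTST / intertidal PTIT), light (2 or 3 states),
physiological status, baseline shoot density, loss in shoot density, seed
density, recruitment rate from seeds, and shoot density with a self
inter-slice edge.  The baseline-shoot-density table is the published
elicitation for each species' home location type, mirrored to the other
location type for completeness.  The remaining tables are package
defaults written in the same dialect with simple ecological logic: good
light promotes good physiological status, low loss and (with summer seed
density) recruitment; a high-loss month steps the meadow down one density
state; a low-loss month steps it one state toward the seasonal baseline;
recovery from a bare meadow requires recruitment.  Arbitrary networks are
accepted through a YAML definition file with the same sections.

## Light thresholds and monthly evidence

Monthly (I_k, I_c) are predicted from monthly mean water temperature by
k-NN on a (temperature, I_k, I_c) training table: absolute temperature
distance, ties at the k-th neighbour broken toward the warmer record
(temperate-lagoon thresholds rise with warming across the 11–20 °C range),
mean aggregation over the k neighbours; k defaults to 1, matching the
piecewise-constant monthly threshold tables this procedure produces.  The
shipped training anchors are a three-record synthetic stand-in carrying the
published per-temperature-band (I_k, I_c) triplets.

Hours above a threshold are sample counts times the sampling interval (10
minutes by default) — no interpolation below the sampling resolution; both
irradiance and duration comparisons use "≥".  Under the 3-state model the
saturation test is applied first, then the limitation test.  Days missing
more than 20% of their expected samples are excluded (configurable).
Calendar months pool month-of-year across years.  The resulting δ vectors
enter inference as virtual (likelihood) evidence; because the light node's
prior is uniform, the posterior light-state probability in each month
equals δ exactly.

## Inference

Posterior shoot-density marginals given all evidence are computed exactly
by an interface forward–backward sweep: within-slice variables are
eliminated in temporal order, so messages live on the set of nodes with
outgoing inter-slice edges (one four-state node in the default network).
This is variable elimination under a temporal ordering and agrees with full
joint enumeration to < 1e-10 on randomized small networks (tested).  Hard
evidence enters as indicator factors, the cyclic time-of-year indicator as
per-slice hard evidence, soft evidence as likelihood factors.  Slice 1 uses
an unconditional prior (uniform unless the network file specifies one) for
nodes with inter-slice parents; a 24-month initialization period is
excluded from all downstream comparisons, by which point the monthly cycle
is stationary to ~1e-6.  Inconsistent evidence (zero normalisation) raises
rather than returning NaNs.

The weighted-mean trajectory maps states to density ranges — defaults
Zero = {0}, Low = (0, 200], Moderate = (200, 600], High = (600, 1200]
shoots m⁻², configurable; downstream comparisons are on state
probabilities and do not depend on the specific edges.  The expectation
uses range midpoints; the IQR comes from the quantile function of the
probability-weighted mixture of within-range uniforms (a zero-width range
is a point mass).

## Ordinal seasonal validation model

Observed monthly densities are discretised with the same state bins and
smoothed with a Bayesian cumulative-logit (proportional-odds) regression:

    P(y ≤ j) = logistic(c_j − η),   η = β1 sin(πt/6) + β2 cos(πt/6) + u_s

with ordered cut points c_1 < c_2 < c_3, calendar month t, and site random
intercepts u_s ~ N(0, σ²).  The sine and cosine jointly form a free-phase
annual harmonic; with the sine alone the high-density season would be
pinned to a March peak, which measurably distorts the smoothed monthly
probabilities for summer-peaked meadows.  Priors are flat (improper) on
the cut points and slopes and half-normal(2.5) on σ (the conventional
weakly-informative default for group-level standard deviations); the random
effects are sampled non-centred (u_s = σ z_s) to avoid the funnel.
Sampling uses an affine-invariant ensemble (32 walkers, 6000 steps, 2500
burn-in, differential-evolution moves), with split-R̂ computed per
parameter across walkers; fits failing R̂ ≤ 1.05 raise by default.  On
data simulated from the model itself, the posterior mean of β1 recovers
the truth well within its posterior spread (tested), and posterior means
agree with the maximum-likelihood proportional-odds fit on well-identified
data (cross-checked against an independent implementation in the tests).
Observed state probabilities are posterior means of the per-month state
probability vectors; unknown sites fall back to u = 0 with a warning.

## MSE scoring and threshold selection

Predicted and observed monthly state-probability vectors are compared by
the mean of squared differences over months and the four states; identical
trajectories score 0 and opposite indicator vectors 0.5, the maximum for
distributions.  Predictions are the post-initialization trajectory averaged
by calendar month (the cycle is stationary there, so 12 response months
suffice); observations are the ordinal model's monthly probabilities.  The
sweep scores every candidate (H_sat, H_comp) per site, reports the per-site
argmin, prefers the 2-state model unless the 3-state model improves the
across-site mean MSE by more than a parsimony margin (default 0.02), and
reports a bay-wide consensus threshold as the argmin of the across-site
mean MSE.

## Synthetic survey generator

The generator emulates a temperate-lagoon monitoring survey at four sites
(FONT, GAIL, ILE, ROCH; survey start December): 10-minute benthic
irradiance with a half-sinusoid diel curve, seasonal daylength 8–16 h
(solstice-locked), midday peak proportional to the month's I_k
(site-specific ratios 1.5–2.8, so the hours-above-saturation distribution
straddles the 4–9 h candidate grid), unit-median lognormal sampling noise
(σ = 0.25) and day-level attenuation events (rate 0.15, factor 0.5);
a sinusoidal monthly temperature climatology spanning ≈11–27 °C (coolest
February, warmest August); and monthly shoot-density observations produced
by rolling out the true network under evidence built with the true duration
thresholds, sampling a state from each post-settling monthly marginal and
drawing a density uniformly within the state's range.  Everything is
deterministic given the scenario seed.

What the generator does *not* emulate — and what passing tests therefore do
not show about field data: observed states are independent draws from
monthly marginals rather than one autocorrelated meadow trajectory;
there is no turbidity seasonality, tidal modulation, sensor drift or
fouling; temperature and light are statistically independent apart from
their shared seasonality; and density within a state is uniform rather
than clustered.  Conclusions about the pipeline's behaviour on real records
should lean on the structural tests (exactness of inference, evidence
identities, published-value reproduction), not on the synthetic recovery
rates alone.

## Numerical and design choices

- End-to-end threshold recovery is checked on 72-month synthetic surveys:
  with independent state draws per month, roughly six observations per
  calendar month per site are needed before the MSE argmin separates
  adjacent candidates (5.5 vs 6 vs 7 h) from sampling noise; at 36 months
  the experiment recovers the truth in only ~70% of replicates, with misses
  bracketing the truth symmetrically.  The bay-wide consensus (mean MSE
  across sites) is the selection statistic.
- The sweep builds one per-day hours table per site and reuses it across
  the whole candidate grid; candidates differ only in the duration
  comparison.
- CPT rows, evidence vectors and posterior marginals are validated to sum
  to 1 within 1e-9; inference agreement with enumeration is required at
  1e-10.
- Ties and edges: density exactly on a bin edge belongs to the lower
  state; irradiance/duration thresholds use "≥"; k-NN ties go to the
  warmer record.
- Degenerate inputs raise typed errors: empty days, missing months,
  single-state observation sets, unordered cut points, zero-probability
  evidence.

## Known limitations

- The shipped network is a reduced slice of the full source ecosystem
  model; nodes outside the light–growth–recruitment pathway (e.g.
  physical disturbance, grazing) are absent, and physiological status does
  not currently modulate baseline density (the published elicitation rows
  are independent of it).
- The ordinal smoother constrains seasonal structure to one annual
  harmonic; strongly square seasonal profiles are broadened, which slightly
  flattens the MSE surface near the optimum.
- The k-NN threshold model is as good as its training table; with the
  three-anchor default it is a banded lookup, and extrapolation beyond
  8–28 °C returns the nearest band.
- Exact inference scales exponentially in the interface size; the default
  network's interface is one node, but networks with many inter-slice
  edges would need a different engine.
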