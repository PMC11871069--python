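# Methods

## The observation hierarchy

A point count is a 10-minute, 150 m fixed-radius survey in which the
observer records every bird with its radial distance class and the time
interval of first detection. The package models four nested layers per
point `k` and visit `t`:

1. **Superpopulation** `N_super_k ~ Poisson(lambda)` — all individuals
   associated with the point over the closure period.
2. **Presence** `N_pres_kt ~ Binomial(N_super_k, p_p)` — random
   temporary emigration, re-drawn independently at each visit.
3. **Availability** `N_avail_kt ~ Binomial(N_pres_kt, phi)` — the bird
   gives a detectable cue during the count. Availability is estimated
   from time-removal data: the count is treated as `J = 3` equal
   removal periods with geometric first-cue cells
   `pi_a[j] = p_a (1-p_a)^(j-1)` and `phi = 1 - (1-p_a)^J`. The
   unequal nominal interval lengths (3, 2, 5 minutes) are deliberately
   ignored: the estimand is the per-period `p_a` that satisfies the
   `phi` identity, not a per-minute hazard.
4. **Perceptibility** — an available bird at distance `r` is detected
   with half-normal probability `g(r) = exp(-r^2/2 sigma^2)`. With
   birds uniform in the circle (radial density `2r/B^2`), the
   multinomial distance cells are evaluated at bin midpoints by the
   rectangular rule, `pi_d[b] = g(r_b) 2 r_b delta_b / B^2`,
   `p_d = sum_b pi_d[b]`.

Counts and the per-detection categorical distance/interval terms form
one multinomial observation layer (the count binomial plus independent
conditional cells `pi_d[b]/p_d` and `pi_a[j]/phi`).

Defaults throughout (units in meters and probabilities): bins
0-25-50-100-150 m (`B = 150`), `J = 3`, `sigma = 55`, `lambda = 5`, and
scenario levels 0.4/0.6/0.8 for presence and availability — the survey
conditions the simulator emulates. With these defaults the rectangular
rule gives `p_d = 0.2667` (prints as 0.27); the exact integral
`(2 sigma^2/B^2)(1 - exp(-B^2/2 sigma^2)) = 0.2624` is kept as an
analytic oracle, and 1 m bins reproduce it to < 1e-4.

The midpoint (rectangular) rule with arithmetic midpoints is used in
both the simulator and the likelihood, so the two agree exactly; the
~1.6% gap to the exact integral is a property of the published cell
definition, not an approximation error of this package.

Density converts per-point abundance to birds/km²:
`D = lambda / (pi B^2 1e-6)` (70.74 birds/km² at `lambda = 5`).

## Priors

`p_a, p_p ~ Beta(1,1)`; `log sigma ~ Uniform(0, 10)` (the upper bound
`e^10 ~ 22 km` is astronomically vague but taken literally);
`lambda ~ Gamma(0.1, 0.1)` (shape/rate; mean 1, strongly right-skewed
toward 0). Trend-model regression intercepts get Normal(0, sd 10) —
reading the conventional "Normal(0, 0.01)" as a *precision*, since a
literal sd of 0.01 would be highly informative; the refuge-effect
precision gets Gamma(0.001, 0.001); the AR coefficients get a flat
prior on the stationarity region `gamma_i >= 0, sum gamma_i < 1`.

## Static-model inference

The latent layers are marginalized analytically: given `N_super_k`, the
visit counts are i.i.d. `Binomial(N_super_k, theta)` with
`theta = p_p phi p_d`, and the Poisson superpopulation is summed out on
a finite grid (capped at `max(120, 3*max(y)+30)`; tail mass beyond the
cap is negligible for any posterior this data scale supports). Points
with identical sorted visit-count vectors are grouped, so the likelihood
costs O(unique patterns x grid).

Sampling uses 3 covariance-adaptive random-walk Metropolis chains
(Haario-style: proposal shape learned from pooled burn-in history,
per-chain global step tuned to ~28% acceptance; adaptation stops at the
end of burn-in). The sampling coordinates are
`(log(lambda p_p), logit p_p, logit p_a, scaled log sigma)`: with a
single visit the count likelihood constrains only the product
`lambda * p_p`, so making the product a coordinate keeps the weakly
identified direction axis-aligned and well mixed. Results flag
`weakly_identified` when `T = 1` and report the product's posterior
(`lam_p_p`) alongside. The test profile is 4,000 iterations (1,000
burn-in, thin 2) per chain — desk-scale sizes chosen so a fit takes
seconds; a `paper_profile` (650,000 iterations, thin 20) is available
for overnight runs. Convergence: Gelman–Rubin R-hat per parameter
(classic between/within-variance form), flagged at 1.1; effective
sample sizes via arviz. Zero-detection data are accepted and flagged
`prior_dominated`; the Beta(1,1) posteriors are then recovered within
Monte-Carlo error (a prior-recovery test).

The marginalized sampler is validated in the test suite against an
independent JAGS data-augmentation fit of the identical hierarchy
(medians agree to ~0.005 on probabilities, ~1 m on sigma).

## Dynamic (trend) model

Annual abundance follows a stationary AR(p) on the Poisson intensity,

```
lambda_kt = sum_{i=1..p} gamma_i N_{k,t-i} + (1 - sum_i gamma_i) exp(beta0 + delta_r)
```

with lag `i` reading the realized abundance `N_{k,t-i}` (the only
reading under which p = 2 adds information), refuge random effects
`delta_r ~ N(0, 1/sqrt(tau))`, and the first `p` years treated as
initial states whose intensity carries a Gamma(0.1, 0.1) prior
(marginalized to a negative-binomial pmf; hyperparameters
configurable). Each year's observation layer is
`y_kt ~ Binomial(N_kt, phi p_d)` plus the categorical detail terms —
Poisson abundance thinned by availability and perceptibility, with no
presence layer (a bird's year-to-year site association is carried by
the AR process itself).

Because the AR mean depends on realized abundances, the latent `N_kt`
are sampled: discrete random-walk Metropolis updates (steps ±1, ±2)
vectorized across points, then scalar random-walk updates for
`gamma, beta0, delta, p_a, log sigma` (stationarity enforced by
rejection) and a conjugate Gibbs draw for `tau` — under which
`delta -> 0` as `tau -> infinity`, the usual shrinkage limit. AR order
is a user choice (1 or 2); no automatic selection.

**Percent annual change** is reported, per posterior draw of the mean
abundance trajectory, as `100 (exp(b) - 1)` with `b` the least-squares
slope of log mean abundance on year — a convention, since "instantaneous
percentage change" admits several readings; the per-step growth-rate
alternative is exported (`method="step"`). Draws with a non-positive
annual mean are skipped and counted. Note the trajectory is the
*realized* mean abundance, so its fitted slope reflects the realized
sample path; for a flat-truth process the posterior concentrates near
the realized (near-zero) slope, not exactly at zero.

The trend sampler is likewise validated against a JAGS fit of the same
dynamic model (gamma_1 posteriors agree to ~0.005).

## Synthetic data

The simulator draws exactly the hierarchy above — per present bird a
single multinomial over the `(b, j)` detection cells
(`pi_d[b] pi_a[j]`), the available-but-undetected cells, and the
not-available remainder — and retains every latent layer, so each
inference stage can be checked against truth. Per-point RNG streams are
derived from the master seed, so enlarging a survey leaves earlier
points' data untouched. The scenario grid crosses presence
{0.4, 0.6, 0.8} x availability {0.4, 0.6, 0.8} x points
{50, 150, 300, 500} x visits {1, 3} — 72 scenarios. The scenario
availability level is interpreted as the per-interval `p_a` by default
(that is the parameter the estimator reports); an `overall`
interpretation (`phi`) is provided as an option.

The multi-year simulator spins the AR process up to stationarity
(default 50 unrecorded transitions) before the recorded years:
initializing at the regression mean under-disperses the early years
relative to the stationary process the model states (stationary
between-point variance is `mu/(1-gamma^2)`, far above the Poisson `mu`
at high `gamma`), which artificially weakens the identification of
`gamma`.

What the generator does **not** emulate: spatially explicit bird
placement or movement within a count, double counting,
misidentification, observer heterogeneity, covariate-driven `sigma` or
`p_a`, and unequal true interval hazards. Passing tests therefore
certify the estimator under the model's own assumptions — not
robustness to these field realities.

## Scenario evaluation

`evaluate_scenario` runs independent simulate-fit cycles; per replicate
and parameter it records bias (posterior mean minus truth — the
posterior median is carried alongside, and is materially less skewed
for density at weakly identified settings), a 95% credible-interval
coverage indicator, and the convergence flag. Replicate seeds are a
pure function of (master seed, scenario id, replicate index), so grids
are resumable and any replicate reproducible in isolation.
Non-converged replicates are included but flagged; `summarize`
optionally filters them. Failed fits are counted, never fatal. The
violin-style summary is a long-format quantile table
(2.5/25/50/75/97.5%).

A finding worth stating plainly: at low presence/availability with a
single visit, the posterior of density is strongly right-skewed (the
`Gamma(0.1,0.1)`-vs-ridge geometry lets `lambda = product / p_p` reach
large values), so the posterior-*mean* bias is positive there even
though the posterior-median bias hovers near zero. Repeated visits
tighten the presence direction and shrink the skew. Both metrics are
reported so the reader can see this directly; the JAGS cross-checks
confirm the skew is a property of the model's posterior, not of this
implementation's sampler.

Test scale: the in-suite bias study uses 10 replicates per examined
cell with the test MCMC profile; the full-grid, 100-replicate study the
defaults describe is a documented overnight profile
(`pointcount evaluate --profile paper`), not part of the test suite.

## Sample-size calculator

Required points for a target CV reduce to
`k = k0 (CV_obs / CV_target)^2` — the pilot's total detections cancel
and matter only through the observed CV (asserted as a property test).
Rounding is half-up; ceiling systematically over-predicts the published
paired columns. The design surface (`xyz_table`) bins pilot total
counts and observed CVs and reports the median required `k`, classed
into 0-50 / 50-100 / 100-250 / 250-500 / 500-1000 / 1000-2000 / >2000
points (the 250-500 class is included so the classes are exhaustive).
The literature benchmark of minimum sample sizes ships as a versioned
CSV (`pointcount/data/table4_literature.csv`); two entries report an
average without a range, which `literature_lookup` returns as
`range=None`.

## Numerical and degenerate-input choices

- All-zero distance cells in a conditional normalization raise a
  degenerate-input error; zero-count categorical cells are skipped in
  the likelihood (0 * log 0 := 0).
- `closed_form_pd` uses `expm1` to stay accurate in the
  `sigma -> infinity` limit.
- Latent-count tables (`log n!`, binomial coefficients) are precomputed;
  trend latents are capped by the table size (>= 4096), far above any
  abundance this data scale supports.
- MCMC settings require >= 2 chains (diagnostics need them), iterations
  > burn-in, thin >= 1.
- Seeds: every public entry point takes one; identical seed + config
  reproduces byte-identical datasets and draw-identical fits.

## Known limitations

- With `T = 1` the presence probability and superpopulation mean are
  separated only by their priors; the fit flags this rather than
  failing, and the identified product `lambda * p_p` is reported.
- The AR(p) trend model treats years <= p as initial states; very short
  series (years barely above p) identify `gamma` weakly.
- Bias/coverage statements in the test suite are made at reduced
  replicate counts; they check direction and coarse magnitude, not the
  full sampling distribution.
- The package fits intercept-only `sigma` and `p_a`; covariate effects
  and alternative detection kernels (hazard-rate, uniform) are out of
  scope.
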