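# pointcount

Hierarchical Bayesian models for avian point-count surveys that record,
for every bird, the **distance class** and the **time interval** of first
detection — the hybrid of distance sampling and time-removal sampling
used in multispecies breeding-bird monitoring of bottomland hardwood and
riparian forests. The package is aimed at survey designers and analysts
who need to know whether a point-count protocol can estimate density and
trends at a stated precision, and how many points it would take.

## The model

For point `k` and visit `t` within a closed season:

```
N_super_k  ~ Poisson(lambda)                     superpopulation
N_pres_kt  ~ Binomial(N_super_k, p_p)            presence (temporary emigration)
N_avail_kt ~ Binomial(N_pres_kt, phi)            availability (gave a cue)
y_kt       ~ Binomial(N_avail_kt, p_d)           perceptibility (was detected)
```

Availability comes from geometric time-removal cells over `J = 3`
intervals, `pi_a[j] = p_a (1-p_a)^(j-1)`, with overall availability
`phi = 1 - (1-p_a)^J`. Perceptibility comes from a half-normal detection
function `g(r) = exp(-r^2 / 2 sigma^2)` integrated over the survey's
distance bins (0–25, 25–50, 50–100, 100–150 m) by the rectangular rule,
`pi_d[b] = g(r_b) * 2 r_b delta_b / B^2`, and `p_d = sum_b pi_d[b]`.
Each detection contributes categorical distance-class and time-interval
terms with conditional cells `pi_d[b]/p_d` and `pi_a[j]/phi`. Priors are
vague: `p_a, p_p ~ Beta(1,1)`, `log sigma ~ Uniform(0,10)`,
`lambda ~ Gamma(0.1, 0.1)`. Density converts the per-point abundance to
birds/km² over the 150 m survey circle.

A multi-year variant replaces the single-season abundance with a
stationary AR(p) process on the annual Poisson intensity,
`lambda_kt = sum_i gamma_i N_{k,t-i} + (1 - sum_i gamma_i) exp(beta0 +
delta_refuge)`, and derives the percent annual change of the abundance
trajectory.

Inference is MCMC written in-package: the static model marginalizes all
latent count layers analytically and samples the four continuous
parameters with covariance-adaptive random-walk Metropolis chains; the
trend model samples the latent annual abundances by
Metropolis-within-Gibbs. Convergence is monitored with the Gelman–Rubin
statistic (flagging at R-hat > 1.1). Both samplers are cross-validated
against independent JAGS fits of the identical hierarchies in the test
suite.

## Worked example

```python
from pointcount import (ScenarioConfig, simulate_dataset,
                        PointCountModel, McmcSettings)

cfg = ScenarioConfig(p_presence=0.8, availability=0.8,
                     n_points=150, n_visits=3)     # lambda=5, sigma=55 defaults
ds = simulate_dataset(cfg, seed=42)                # 456 detections
res = PointCountModel.from_simulation(ds).fit(McmcSettings(), seed=1)
print(res.summary())
```

```
Hybrid distance-sampling / time-removal point-count model
points: 150   visits: 3   detections: 456
chains: 3   kept draws/chain: 1500   seed: 1

                mean         sd       q2.5     median      q97.5       rhat        ess
parameter
lam           5.2754     1.5067     3.7752     4.8590     9.1449     1.0026   671.4267
p_p           0.7858     0.1522     0.4302     0.8129     0.9881     1.0034   513.4961
p_a           0.8260     0.0185     0.7887     0.8261     0.8607     1.0004   692.4238
sigma        53.9769     1.5561    51.1664    53.8580    57.2992     0.9998   380.7628
phi           0.9946     0.0017     0.9906     0.9947     0.9973     1.0005   692.4238
p_d           0.2575     0.0139     0.2326     0.2564     0.2874     0.9998   380.7628
lam_p_p       3.9453     0.3190     3.3324     3.9414     4.6071     1.0004   236.9086
D            74.6319    21.3150    53.4078    68.7402   129.3733     1.0026   671.4267
N_total     791.3123   226.0000   566.2758   728.8435  1371.7290     1.0026   671.4267

flags: prior_dominated=False, weakly_identified=False, converged=True
```

The generating truth (`lambda = 5`, `p_p = 0.8`, `p_a = 0.8`,
`sigma = 55` m, hence `phi = 0.992`, `p_d ~ 0.267` and density
~70.7 birds/km²) sits inside every 95% credible interval; `p_a` and
`sigma` are sharply identified by the per-detection interval and
distance data, while `lambda` and `p_p` are separated only by the
between-visit information and stay wider.

Survey design from a pilot study:

```python
from pointcount import PilotSummary, required_points
required_points(PilotSummary(n0=50, k0=100, cv_obs=0.30), cv_target=0.15).k_rounded
# 400  -- halving the CV quadruples the required points
```

The same machinery is available from the shell:
`pointcount simulate|fit|trend|evaluate|samplesize|validate` (see
`pointcount --help`).

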