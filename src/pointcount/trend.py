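"""Multi-year dynamic abundance model with AR(p) trend.

Annual abundance at point ``k`` follows a Markovian mean process: the
Poisson intensity in year ``t`` is a convex combination of the realized
abundances of the previous ``p`` years and a log-linear regression
mean,

.. math::

    \\lambda_{kt} = \\sum_{i=1}^{p} \\gamma_i N_{k,t-i}
        + \\Big(1 - \\sum_{i=1}^{p} \\gamma_i\\Big) e^{X_{kt}\\beta},
    \\qquad N_{kt} \\sim \\mathrm{Poisson}(\\lambda_{kt}),

with stationarity enforced through :math:`\\gamma_i \\ge 0,\\;
\\sum_i \\gamma_i < 1`.  The regression mean is intercept plus a
refuge random effect, :math:`\\log \\lambda = \\beta_0 +
\\delta_{r}`, :math:`\\delta_r \\sim N(0, 1/\\sqrt{\\tau})`.  Each
year's birds pass through the availability (``phi`` from the geometric
time-removal cells) and perceptibility (``p_d`` from the half-normal
distance cells) observation layers:
:math:`y_{kt} \\sim \\mathrm{Binomial}(N_{kt}, \\phi\\, p_d)` plus the
per-detection categorical distance/interval terms.

Because the AR mean depends on *realized* abundances, the latent
``N_kt`` cannot be summed out; the sampler is Metropolis-within-Gibbs:
discrete random-walk updates of every ``N_kt`` (vectorized over
points), scalar random-walk updates of the continuous parameters, and
a conjugate Gibbs draw for the refuge-effect precision ``tau``.

The first ``p`` years are initial states with the marginalized
``Gamma(a0, b0)`` intensity prior (a negative-binomial pmf).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .detection import (
    DEFAULT_BINNING,
    DEFAULT_REMOVAL,
    DetectionParams,
    distance_cell_probs,
    removal_cell_probs,
)
from .mcmc import effective_draws, gelman_rubin
from .model import derive_density
from .simulate import SimulatedTrendDataset, validate_records

__all__ = ["TrendModelSpec", "TrendPriors", "TrendModel", "TrendResults", "percent_change"]


@dataclass(frozen=True)
class TrendModelSpec:
    """AR order and initial-state hyperparameters."""

    order: int = 1
    init_gamma: tuple = (0.1, 0.1)  # (a0, b0) for the first-p-years intensity

    def __post_init__(self):
        if self.order not in (1, 2):
            raise ValueError("AR order must be 1 or 2")
        a0, b0 = self.init_gamma
        if not (a0 > 0 and b0 > 0):
            raise ValueError("initial-state hyperparameters must be positive")


@dataclass(frozen=True)
class TrendPriors:
    """Normal(0, precision 0.01) on regression intercepts (sd 10, the
    JAGS convention for 'Normal(0, 0.01)'), Gamma(0.001, 0.001) on the
    refuge-effect precision, and flat stationary-region prior on the
    AR coefficients."""

    intercept_sd: float = 10.0
    tau_gamma: tuple = (0.001, 0.001)


@dataclass(frozen=True)
class TrendMcmcSettings:
    chains: int = 3
    iterations: int = 6000
    burn_in: int = 2000
    thin: int = 2
    seed: int | None = None

    def __post_init__(self):
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")


def percent_change(trajectories, years=None, method="loglinear"):
    """Percent annual change from posterior abundance trajectories.

    Parameters
    ----------
    trajectories : ndarray, shape (n_draws, n_years)
        Posterior draws of mean abundance per year.
    method : {"loglinear", "step"}
        ``loglinear`` (the reported convention): per draw, least-squares
        slope ``b`` of log abundance on year, returned as
        ``100*(exp(b)-1)``.  ``step``: mean of the per-step growth rates
        ``100*(N_{t+1}/N_t - 1)``.

    Returns
    -------
    draws : ndarray
        Percent-change draws (draws with a non-positive annual mean are
        skipped; their count is reported via a warning).
    """
    traj = np.atleast_2d(np.asarray(trajectories, dtype=float))
    if traj.shape[1] < 2:
        raise ValueError("need at least two years")
    ok = np.all(traj > 0, axis=1)
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"{n_bad} draws with non-positive annual means skipped", stacklevel=2)
    traj = traj[ok]
    if method == "loglinear":
        t = np.arange(traj.shape[1], dtype=float) if years is None \
            else np.asarray(years, dtype=float)
        t = t - t.mean()
        b = (np.log(traj) * t).sum(axis=1) / (t ** 2).sum()
        return 100.0 * np.expm1(b)
    if method == "step":
        return 100.0 * (traj[:, 1:] / traj[:, :-1] - 1.0).mean(axis=1)
    raise ValueError("method must be 'loglinear' or 'step'")


class TrendModel:
    """Dynamic AR(p) point-count model bound to multi-year data.

    Parameters
    ----------
    y : ndarray, shape (K, n_years)
        Counts per point and year (zeros included).
    dclass_counts, tinterval_counts : ndarray
        Pooled per-detection class totals, as in the static model.
    point_refuge : ndarray, shape (K,), optional
        Integer refuge index per point (default: one refuge).
    """

    def __init__(self, y, dclass_counts, tinterval_counts, point_refuge=None,
                 spec: TrendModelSpec = TrendModelSpec(),
                 priors: TrendPriors = TrendPriors(),
                 binning=DEFAULT_BINNING, removal=DEFAULT_REMOVAL):
        y = np.asarray(y, dtype=int)
        if y.ndim != 2:
            raise ValueError("y must be (n_points, n_years)")
        if y.shape[1] < 2:
            raise ValueError("a single year of data cannot inform a trend; "
                             "fit the static PointCountModel instead")
        if y.shape[1] <= spec.order:
            raise ValueError("need more years than the AR order")
        self.y = y
        self.spec = spec
        self.priors = priors
        self.binning = binning
        self.removal = removal
        self.dclass_counts = np.asarray(dclass_counts, dtype=float)
        self.tinterval_counts = np.asarray(tinterval_counts, dtype=float)
        if self.dclass_counts.sum() != y.sum() or self.tinterval_counts.sum() != y.sum():
            raise ValueError("per-detection records inconsistent with counts")
        if point_refuge is None:
            point_refuge = np.zeros(y.shape[0], dtype=int)
        self.point_refuge = np.asarray(point_refuge, dtype=int)
        if self.point_refuge.shape != (y.shape[0],):
            raise ValueError("point_refuge must give one refuge index per point")
        self.n_refuges = int(self.point_refuge.max()) + 1
        self.n_points, self.n_years = y.shape
        self._lgam = gammaln(np.arange(max(4096, 8 * (y.max() + 10))) + 1.0)

    @classmethod
    def from_dataframe(cls, detections: pd.DataFrame, n_points: int, n_years: int,
                       point_refuge=None, **kwargs):
        """Build from long-format records with a mandatory ``year``
        column (1..n_years); ``visit`` is ignored (one count per year)."""
        binning = kwargs.get("binning", DEFAULT_BINNING)
        removal = kwargs.get("removal", DEFAULT_REMOVAL)
        problems = validate_records(detections, binning, removal) if len(detections) else []
        if problems:
            raise ValueError("; ".join(problems[:10]))
        if "year" not in detections.columns:
            raise ValueError("trend data need a year column")
        y = np.zeros((n_points, n_years), dtype=int)
        if len(detections):
            pid = detections["point_id"].to_numpy(dtype=int)
            yr = detections["year"].to_numpy(dtype=int)
            if pid.max() > n_points or yr.max() > n_years:
                raise ValueError("point_id/year outside declared dimensions")
            np.add.at(y, (pid - 1, yr - 1), 1)
            mb = np.bincount(detections["distance_class"].to_numpy(int) - 1,
                             minlength=binning.n_bins)
            nj = np.bincount(detections["time_interval"].to_numpy(int) - 1,
                             minlength=removal.J)
        else:
            mb = np.zeros(binning.n_bins)
            nj = np.zeros(removal.J)
        if point_refuge is None and len(detections):
            codes = detections["refuge"].astype("category").cat.codes.to_numpy()
            point_refuge = np.zeros(n_points, dtype=int)
            point_refuge[detections["point_id"].to_numpy(int) - 1] = codes
        return cls(y, mb, nj, point_refuge=point_refuge, **kwargs)

    @classmethod
    def from_simulation(cls, dataset: SimulatedTrendDataset, **kwargs):
        kwargs.setdefault("binning", dataset.binning)
        kwargs.setdefault("removal", dataset.removal)
        return cls.from_dataframe(dataset.detections, dataset.latent_n.shape[0],
                                  dataset.latent_n.shape[1],
                                  point_refuge=dataset.point_refuge, **kwargs)

    # ----------------------------------------------------------- pieces
    def _obs_q(self, p_a, sigma):
        """(phi * p_d, log pieces) of the observation layer."""
        pi_d, p_d = distance_cell_probs(self.binning, DetectionParams(sigma))
        pi_a, phi = removal_cell_probs(p_a, self.removal)
        return pi_d, p_d, pi_a, phi

    def _log_pois(self, n, lam):
        return n * np.log(lam) - lam - self._lgam[n]

    def _log_binom(self, k, n, q):
        return (self._lgam[n] - self._lgam[k] - self._lgam[n - k]
                + k * np.log(q) + (n - k) * np.log1p(-q))

    def _log_nb_init(self, n):
        # N ~ NegBin from Poisson intensity with Gamma(a0, b0) prior
        a0, b0 = self.spec.init_gamma
        return (gammaln(n + a0) - gammaln(a0) - self._lgam[n]
                + a0 * np.log(b0 / (1 + b0)) - n * np.log1p(b0))

    def _lam_mat(self, N, gamma, mu):
        """AR intensities for years order..n_years-1 (0-based columns)."""
        p = self.spec.order
        lam = np.full((self.n_points, self.n_years), np.nan)
        for t in range(p, self.n_years):
            lam[:, t] = sum(gamma[i] * N[:, t - 1 - i] for i in range(p)) \
                + (1 - sum(gamma)) * mu
        return lam

    # ----------------------------------------------------------- sampler
    def fit(self, mcmc: TrendMcmcSettings = TrendMcmcSettings(),
            seed: int | None = None, init: dict | None = None) -> "TrendResults":
        """Run the Metropolis-within-Gibbs sampler.

        ``init`` optionally pins starting values (keys among ``N``,
        ``gamma``, ``beta0``, ``p_a``, ``sigma``), mainly for
        diagnostics; by default chains start from dispersed
        moment-style values.
        """
        if seed is None:
            seed = mcmc.seed
        master = np.random.SeedSequence(seed)
        chain_draws = []
        for c, ss in enumerate(master.spawn(mcmc.chains)):
            chain_draws.append(self._run_chain(np.random.default_rng(ss), mcmc, init=init))
        draws = {k: np.stack([d[k] for d in chain_draws], axis=0)
                 for k in chain_draws[0]}
        return TrendResults(self, draws, mcmc, seed)

    def _run_chain(self, rng, mcmc, init=None):
        p = self.spec.order
        K, Ty = self.n_points, self.n_years
        y = self.y
        init = init or {}
        # initial states
        N = np.array(init["N"], dtype=int) if "N" in init \
            else y + rng.poisson(2.0, size=y.shape).astype(int) + 1
        gamma = np.asarray(init.get("gamma", np.full(p, 0.3 / p) + 0.1 * rng.random(p)),
                           dtype=float).copy()
        beta0 = float(init.get("beta0", np.log(max(N.mean(), 0.5))
                      + 0.1 * rng.standard_normal()))
        delta = np.zeros(self.n_refuges)
        tau = 10.0
        p_a = float(init.get("p_a", np.clip(0.5 + 0.2 * rng.standard_normal(), 0.05, 0.95)))
        logsig = float(np.log(init.get("sigma", np.exp(np.log(55.0)
                       + 0.2 * rng.standard_normal()))))

        names = (["gamma_%d" % (i + 1) for i in range(p)]
                 + ["beta0", "p_a", "sigma", "tau"])
        scales = {n: 0.15 for n in names}
        scales["p_a"] = 0.3
        scales["sigma"] = 0.05
        acc = {n: 0 for n in names}
        batch = {n: 0 for n in names}

        kept = {n: [] for n in names + ["phi", "p_d", "D_mean", "traj", "delta"]}
        sqrt_b = 1.0

        def obs_terms(p_a_, logsig_):
            pi_d, p_d_, pi_a, phi_ = self._obs_q(p_a_, np.exp(logsig_))
            q = phi_ * p_d_
            ll = self._log_binom(y, N, q).sum()
            ll += (self.dclass_counts * np.log(pi_d / p_d_)).sum()
            ll += (self.tinterval_counts * np.log(pi_a / phi_)).sum()
            return ll, p_d_, phi_, q

        n_batches = 0
        for it in range(mcmc.iterations):
            mu = np.exp(beta0 + delta[self.point_refuge])
            gsum = gamma.sum()
            _, p_d_, pi_a, phi_ = self._obs_q(p_a, np.exp(logsig))
            q = phi_ * p_d_

            # ---- latent abundance sweep (vectorized over points)
            for t in range(Ty):
                step = rng.integers(1, 3, size=K) * rng.choice([-1, 1], size=K)
                Nn = N[:, t] + step
                valid = (Nn >= y[:, t]) & (Nn < self._lgam.size - 1)
                Nn = np.where(valid, Nn, N[:, t])
                logr = np.where(valid, 0.0, -np.inf)
                # own prior
                if t < p:
                    logr = logr + self._log_nb_init(Nn) - self._log_nb_init(N[:, t])
                else:
                    lam_t = sum(gamma[i] * N[:, t - 1 - i] for i in range(p)) + (1 - gsum) * mu
                    logr = logr + self._log_pois(Nn, lam_t) - self._log_pois(N[:, t], lam_t)
                # observation
                logr = logr + self._log_binom(y[:, t], Nn, q) \
                    - self._log_binom(y[:, t], N[:, t], q)
                # downstream AR terms
                for i in range(p):
                    td = t + 1 + i
                    if td < Ty:
                        others = sum(gamma[j] * N[:, td - 1 - j] for j in range(p)
                                     if td - 1 - j != t)
                        base = (1 - gsum) * mu + (others if np.ndim(others) else 0.0)
                        logr = logr + self._log_pois(N[:, td], gamma[i] * Nn + base) \
                            - self._log_pois(N[:, td], gamma[i] * N[:, t] + base)
                take = np.log(rng.random(K)) < logr
                N[take, t] = Nn[take]

            # ---- AR process loglik helper for current N
            def process_ll(gamma_, beta0_, delta_):
                if np.any(gamma_ < 0) or gamma_.sum() >= 1:
                    return -np.inf
                mu_ = np.exp(beta0_ + delta_[self.point_refuge])
                lam = self._lam_mat(N, gamma_, mu_)
                return self._log_pois(N[:, p:], lam[:, p:]).sum()

            cur_pll = process_ll(gamma, beta0, delta)

            # gamma_i
            for i in range(p):
                gn = gamma.copy()
                gn[i] = gamma[i] + scales[f"gamma_{i+1}"] * rng.standard_normal()
                pll = process_ll(gn, beta0, delta)
                if np.log(rng.random()) < pll - cur_pll:
                    gamma, cur_pll = gn, pll
                    acc[f"gamma_{i+1}"] += 1
                batch[f"gamma_{i+1}"] += 1

            # beta0
            bn = beta0 + scales["beta0"] * rng.standard_normal()
            pll = process_ll(gamma, bn, delta) \
                - 0.5 * (bn / self.priors.intercept_sd) ** 2
            cur0 = cur_pll - 0.5 * (beta0 / self.priors.intercept_sd) ** 2
            if np.log(rng.random()) < pll - cur0:
                beta0 = bn
                cur_pll = process_ll(gamma, beta0, delta)
                acc["beta0"] += 1
            batch["beta0"] += 1

            # refuge effects + tau (Gibbs)
            if self.n_refuges > 1:
                for r in range(self.n_refuges):
                    dn = delta.copy()
                    dn[r] = delta[r] + 0.2 * rng.standard_normal()
                    pll = process_ll(gamma, beta0, dn) - 0.5 * tau * dn[r] ** 2
                    cur0 = cur_pll - 0.5 * tau * delta[r] ** 2
                    if np.log(rng.random()) < pll - cur0:
                        delta = dn
                        cur_pll = process_ll(gamma, beta0, delta)
                a_t, b_t = self.priors.tau_gamma
                tau = rng.gamma(a_t + self.n_refuges / 2.0,
                                1.0 / (b_t + 0.5 * (delta ** 2).sum()))

            # availability and detection scale
            cur_obs, _, _, _ = obs_terms(p_a, logsig)
            pa_n = p_a + scales["p_a"] * rng.standard_normal()
            if 0 < pa_n < 1:
                prop_obs, _, _, _ = obs_terms(pa_n, logsig)
                pr = (-0.5 * (logit(pa_n) / self.priors.intercept_sd) ** 2
                      - np.log(pa_n * (1 - pa_n)))
                cu = (-0.5 * (logit(p_a) / self.priors.intercept_sd) ** 2
                      - np.log(p_a * (1 - p_a)))
                if np.log(rng.random()) < prop_obs + pr - cur_obs - cu:
                    p_a, cur_obs = pa_n, prop_obs
                    acc["p_a"] += 1
            batch["p_a"] += 1

            ls_n = logsig + scales["sigma"] * rng.standard_normal()
            prop_obs, _, _, _ = obs_terms(p_a, ls_n)
            pr = -0.5 * (ls_n / self.priors.intercept_sd) ** 2
            cu = -0.5 * (logsig / self.priors.intercept_sd) ** 2
            if np.log(rng.random()) < prop_obs + pr - cur_obs - cu:
                logsig = ls_n
                acc["sigma"] += 1
            batch["sigma"] += 1

            # step-size adaptation during burn-in
            if it < mcmc.burn_in and (it + 1) % 50 == 0:
                n_batches += 1
                sqrt_b = np.sqrt(n_batches)
                for n in names:
                    if n == "tau" or batch[n] == 0:
                        continue
                    rate = acc[n] / batch[n]
                    scales[n] *= np.exp((rate - 0.35) / sqrt_b)
                    acc[n] = batch[n] = 0

            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                _, p_d_, _, phi_ = self._obs_q(p_a, np.exp(logsig))
                for i in range(p):
                    kept[f"gamma_{i+1}"].append(gamma[i])
                kept["beta0"].append(beta0)
                kept["p_a"].append(p_a)
                kept["sigma"].append(np.exp(logsig))
                kept["tau"].append(tau)
                kept["phi"].append(phi_)
                kept["p_d"].append(p_d_)
                kept["traj"].append(N.mean(axis=0))
                kept["D_mean"].append(derive_density(N.mean(), self.binning))
                kept["delta"].append(delta.copy())

        return {k: np.asarray(v) for k, v in kept.items()}


class TrendResults:
    """Posterior draws and summaries for the dynamic model.

    ``draws`` maps parameter names to arrays of shape (chains, draws)
    — plus ``traj`` (chains, draws, n_years), the posterior of mean
    abundance per point per year, and ``delta`` (chains, draws,
    n_refuges)."""

    RHAT_THRESHOLD = 1.1

    def __init__(self, model, draws, mcmc, seed):
        self.model = model
        self.draws = draws
        self.mcmc = mcmc
        self.seed = seed
        rh = self.rhat()
        self.flags = {"converged": bool(max(rh.values()) <= self.RHAT_THRESHOLD)}
        if not self.flags["converged"]:
            worst = max(rh, key=rh.get)
            warnings.warn(f"chains may not have converged: R-hat({worst}) = "
                          f"{rh[worst]:.3f}", stacklevel=2)

    def _scalar_params(self):
        return [k for k, v in self.draws.items() if v.ndim == 2]

    def rhat(self):
        return {k: gelman_rubin(self.draws[k]) for k in self._scalar_params()}

    def ess(self):
        return {k: effective_draws(self.draws[k]) for k in self._scalar_params()}

    def summary_frame(self) -> pd.DataFrame:
        rh, es = self.rhat(), self.ess()
        rows = []
        for k in self._scalar_params():
            f = self.draws[k].ravel()
            q = np.percentile(f, [2.5, 50, 97.5])
            rows.append((k, f.mean(), f.std(ddof=1), q[0], q[1], q[2], rh[k], es[k]))
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd", "q2.5", "median",
                                           "q97.5", "rhat", "ess"]).set_index("parameter")

    def summary(self) -> str:
        sf = self.summary_frame()
        pc = self.percent_change()
        q = np.percentile(pc, [2.5, 50, 97.5])
        return "\n".join([
            f"AR({self.model.spec.order}) dynamic point-count model",
            f"points: {self.model.n_points}   years: {self.model.n_years}   "
            f"refuges: {self.model.n_refuges}   detections: {int(self.model.y.sum())}",
            "",
            sf.to_string(float_format=lambda v: f"{v:10.4f}"),
            "",
            f"percent annual change: {q[1]:+.2f}%/yr (95% CI {q[0]:+.2f} to {q[2]:+.2f})",
            "flags: " + ", ".join(f"{k}={v}" for k, v in self.flags.items()),
        ])

    def trajectory(self) -> np.ndarray:
        """Flattened posterior draws of mean abundance per year."""
        t = self.draws["traj"]
        return t.reshape(-1, t.shape[-1])

    def annual_density(self) -> pd.DataFrame:
        """Posterior summary of density (birds/km^2) per year."""
        dens = derive_density(self.trajectory(), self.model.binning)
        q = np.percentile(dens, [2.5, 50, 97.5], axis=0)
        return pd.DataFrame({"year": np.arange(1, self.model.n_years + 1),
                             "mean": dens.mean(axis=0), "q2.5": q[0],
                             "median": q[1], "q97.5": q[2]})

    def percent_change(self, method="loglinear") -> np.ndarray:
        return percent_change(self.trajectory(), method=method)

    def credible_interval(self, param, level=0.95):
        a = (1.0 - level) / 2.0
        f = self.draws[param].ravel()
        return tuple(np.percentile(f, [100 * a, 100 * (1 - a)]))
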