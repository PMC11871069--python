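"""Single-season hybrid distance-sampling / time-removal abundance model.

The data-generating hierarchy per point ``k`` and visit ``t`` is

.. math::

    N^{super}_k \\sim \\mathrm{Poisson}(\\lambda), \\qquad
    N^{pres}_{kt} \\sim \\mathrm{Binomial}(N^{super}_k, p_p), \\qquad
    N^{avail}_{kt} \\sim \\mathrm{Binomial}(N^{pres}_{kt}, \\phi),

with each available bird detected with probability ``p_d`` and, on
detection, assigned a distance class (conditional cells
:math:`\\pi_{d,b}/p_d`) and a removal interval (:math:`\\pi_{a,j}/\\phi`).
The observed count is :math:`y_{kt} \\sim \\mathrm{Binomial}(p_d,
N^{avail}_{kt})`; together with the per-detection categorical terms this
is one multinomial observation layer.

Fitting marginalizes the latent layers analytically: given
:math:`N^{super}_k`, the visit counts are i.i.d.
:math:`\\mathrm{Binomial}(N^{super}_k, \\theta)` with
:math:`\\theta = p_p\\,\\phi\\,p_d`, and the Poisson superpopulation is
summed out over a finite grid.  The resulting four-parameter posterior
:math:`(\\lambda, p_p, p_a, \\sigma)` is sampled with adaptive
random-walk Metropolis chains; availability, perceptibility, density
and totals are derived per draw.

With a single visit (T=1) the product :math:`\\lambda p_p` alone enters
the count likelihood, so ``lam`` and ``p_p`` are separately informed
only by their priors; the results object flags this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, gammaln, logit, logsumexp

from .detection import (
    DEFAULT_BINNING,
    DEFAULT_REMOVAL,
    DetectionParams,
    DistanceBinning,
    TimeRemovalScheme,
    distance_cell_probs,
    removal_cell_probs,
)
from .mcmc import adaptive_metropolis, effective_draws, gelman_rubin
from .simulate import SimulatedDataset, validate_records

__all__ = [
    "PriorSpec",
    "McmcSettings",
    "PointCountModel",
    "PointCountResults",
    "derive_density",
]


@dataclass(frozen=True)
class PriorSpec:
    """Vague priors of the reference analysis, all overridable.

    ``p_a, p_p ~ Beta(1,1)``, ``log(sigma) ~ Uniform(0, 10)`` (sigma in
    meters, so the upper bound e^10 ~ 22 km is effectively flat), and
    ``lambda ~ Gamma(0.1, 0.1)`` (shape, rate).
    """

    p_a_beta: tuple = (1.0, 1.0)
    p_p_beta: tuple = (1.0, 1.0)
    log_sigma_bounds: tuple = (0.0, 10.0)
    lam_gamma: tuple = (0.1, 0.1)

    def __post_init__(self):
        for name in ("p_a_beta", "p_p_beta", "lam_gamma"):
            a, b = getattr(self, name)
            if not (a > 0 and b > 0):
                raise ValueError(f"{name} hyperparameters must be positive")
        lo, hi = self.log_sigma_bounds
        if not hi > lo:
            raise ValueError("log_sigma upper bound must exceed lower bound")


@dataclass(frozen=True)
class McmcSettings:
    """Sampler settings.

    The defaults are the desk-scale test profile (3 chains x 4,000
    iterations).  ``paper_profile()`` reproduces the reference
    analysis' 650,000-iteration configuration for overnight runs.
    """

    chains: int = 3
    iterations: int = 4000
    burn_in: int = 1000
    thin: int = 2
    seed: int | None = None

    def __post_init__(self):
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")

    @classmethod
    def test_profile(cls, seed=None):
        return cls(seed=seed)

    @classmethod
    def paper_profile(cls, seed=None):
        return cls(chains=3, iterations=650_000, burn_in=55_000, thin=20, seed=seed)


def derive_density(lam_draws, binning: DistanceBinning = DEFAULT_BINNING):
    """Density in birds/km^2 from per-point abundance draws.

    ``D = lambda / (pi * B^2 * 1e-6)`` -- the survey plot is the circle
    of truncation radius ``B`` meters.
    """
    area_km2 = np.pi * binning.B ** 2 * 1e-6
    return np.asarray(lam_draws, dtype=float) / area_km2


class PointCountModel:
    """Single-season model bound to observed point-count data.

    Parameters
    ----------
    y : ndarray, shape (K, T)
        Detected counts per point and visit (zeros included).
    dclass_counts : ndarray, shape (n_bins,)
        Detections per distance class, pooled over points and visits.
    tinterval_counts : ndarray, shape (J,)
        Detections per removal interval, pooled likewise.
    """

    def __init__(self, y, dclass_counts, tinterval_counts,
                 binning: DistanceBinning = DEFAULT_BINNING,
                 removal: TimeRemovalScheme = DEFAULT_REMOVAL,
                 priors: PriorSpec = PriorSpec()):
        y = np.asarray(y, dtype=int)
        if y.ndim != 2:
            raise ValueError("y must be (n_points, n_visits)")
        if np.any(y < 0):
            raise ValueError("counts must be non-negative")
        self.y = y
        self.binning = binning
        self.removal = removal
        self.priors = priors
        self.dclass_counts = np.asarray(dclass_counts, dtype=float)
        self.tinterval_counts = np.asarray(tinterval_counts, dtype=float)
        if self.dclass_counts.size != binning.n_bins:
            raise ValueError("distance-class counts do not match the binning")
        if self.tinterval_counts.size != removal.J:
            raise ValueError("time-interval counts do not match the removal scheme")
        if self.dclass_counts.sum() != y.sum() or self.tinterval_counts.sum() != y.sum():
            raise ValueError("per-detection records inconsistent with counts")
        self._prepare()

    # ---------------------------------------------------------- constructors
    @classmethod
    def from_dataframe(cls, detections: pd.DataFrame, n_points: int, n_visits: int,
                       binning=DEFAULT_BINNING, removal=DEFAULT_REMOVAL,
                       priors=PriorSpec()):
        """Build from long-format detection records.

        ``detections`` needs columns ``point_id`` (1..n_points),
        ``visit`` (1..n_visits), ``distance_class`` and
        ``time_interval``; points and visits without records contribute
        zero counts.
        """
        problems = validate_records(detections, binning, removal) if len(detections) else []
        if problems:
            raise ValueError("; ".join(problems[:10]))
        y = np.zeros((n_points, n_visits), dtype=int)
        if len(detections):
            pid = detections["point_id"].to_numpy(dtype=int)
            vis = detections["visit"].to_numpy(dtype=int)
            if pid.max() > n_points or vis.max() > n_visits or pid.min() < 1 or vis.min() < 1:
                raise ValueError("point_id/visit outside declared survey dimensions")
            np.add.at(y, (pid - 1, vis - 1), 1)
            mb = np.bincount(detections["distance_class"].to_numpy(dtype=int) - 1,
                             minlength=binning.n_bins)
            nj = np.bincount(detections["time_interval"].to_numpy(dtype=int) - 1,
                             minlength=removal.J)
        else:
            mb = np.zeros(binning.n_bins)
            nj = np.zeros(removal.J)
        return cls(y, mb, nj, binning, removal, priors)

    @classmethod
    def from_simulation(cls, dataset: SimulatedDataset, priors=PriorSpec()):
        cfg = dataset.config
        return cls.from_dataframe(dataset.detections, cfg.n_points, cfg.n_visits,
                                  cfg.binning, cfg.removal, priors)

    # ---------------------------------------------------------- likelihood
    def _prepare(self):
        """Group points by their (sorted) visit-count vector and
        precompute the N-grid combinatorial terms."""
        K, T = self.y.shape
        self.n_points, self.n_visits = K, T
        ysort = np.sort(self.y, axis=1)
        uniq, counts = np.unique(ysort, axis=0, return_counts=True)
        self._group_w = counts.astype(float)
        self._group_s = uniq.sum(axis=1).astype(float)
        ymax = int(self.y.max()) if self.y.size else 0
        self._n_grid = np.arange(max(120, 3 * ymax + 30) + 1)
        N = self._n_grid[None, :]
        yk = uniq[:, :, None]
        # sum_t log C(N, y_t) - log N!  (the lgamma(N+1) from the Poisson
        # pmf cancels T-1 of the binomial coefficients' numerators)
        with np.errstate(invalid="ignore"):
            comb = gammaln(N + 1) - gammaln(yk + 1) - gammaln(N - yk + 1)
        self._C = np.where(N >= uniq.max(axis=1)[:, None],
                           np.nan_to_num(comb, nan=-np.inf).sum(axis=1) - gammaln(N + 1),
                           -np.inf)

    def _unpack(self, z):
        # sampling coordinates: (log(lam*p_p), logit p_p, logit p_a,
        # logit of scaled log-sigma).  The first coordinate is the
        # well-identified product, so the weakly identified p_p
        # direction is axis-aligned and the walk mixes along it.
        p_p = expit(z[:, 1])
        lam = np.exp(z[:, 0]) / p_p
        p_a = expit(z[:, 2])
        lo, hi = self.priors.log_sigma_bounds
        w = expit(z[:, 3])
        sigma = np.exp(lo + (hi - lo) * w)
        return lam, p_p, p_a, sigma, w

    def _log_post(self, z):
        lam, p_p, p_a, sigma, w = self._unpack(z)
        C = z.shape[0]
        a_l, b_l = self.priors.lam_gamma
        lp = (a_l * np.log(b_l) - gammaln(a_l) + (a_l - 1) * np.log(lam) - b_l * lam
              + np.log(lam))                                     # + Jacobian d lam/d z
        for p, (a, b) in ((p_p, self.priors.p_p_beta), (p_a, self.priors.p_a_beta)):
            lp += ((a - 1) * np.log(p) + (b - 1) * np.log1p(-p) - betaln(a, b)
                   + np.log(p) + np.log1p(-p))
        lp += np.log(w) + np.log1p(-w)                           # flat log-sigma, Jacobian only

        # detection-level categorical terms
        mids, widths, B = self.binning.midpoints, self.binning.widths, self.binning.B
        g = np.exp(-(mids[None, :] ** 2) / (2.0 * sigma[:, None] ** 2))
        pi_d = g * (2.0 * mids * widths / B ** 2)[None, :]
        p_d = pi_d.sum(axis=1)
        j = np.arange(self.removal.J)
        pi_a = p_a[:, None] * (1.0 - p_a[:, None]) ** j[None, :]
        phi = 1.0 - (1.0 - p_a) ** self.removal.J
        mb, nj_ = self.dclass_counts, self.tinterval_counts
        if mb.sum() > 0:
            bmask = mb > 0
            with np.errstate(divide="ignore"):
                lp += (mb[bmask][None, :] * np.log(pi_d[:, bmask])).sum(axis=1) \
                    - mb.sum() * np.log(p_d)
            jmask = nj_ > 0
            lp += (nj_[jmask][None, :] * np.log(pi_a[:, jmask])).sum(axis=1) \
                - nj_.sum() * np.log(phi)

        # count hierarchy, superpopulation summed out on the N grid
        theta = p_p * phi * p_d
        N = self._n_grid[None, None, :]
        core = (N * np.log(lam)[:, None, None] - lam[:, None, None]
                + self._C[None, :, :]
                + self._group_s[None, :, None] * np.log(theta)[:, None, None]
                + (self.n_visits * N - self._group_s[None, :, None])
                * np.log1p(-theta)[:, None, None])
        lp += (self._group_w[None, :] * logsumexp(core, axis=2)).sum(axis=1)
        return lp

    # ---------------------------------------------------------- fitting
    def _initial_states(self, n_chains, rng):
        mb, nj = self.dclass_counts, self.tinterval_counts
        total = self.y.sum()
        # moment-style starting values, jittered per chain
        if total > 0 and nj[0] > 0:
            later = nj[1:].sum()
            p_a0 = np.clip(1.0 - (later / max(nj[0], 1.0)) ** (1.0 / max(self.removal.J - 1, 1)),
                           0.1, 0.9) if self.removal.J > 1 else 0.5
        else:
            p_a0 = 0.5
        s0 = float(np.exp(np.mean(self.priors.log_sigma_bounds)))
        if total > 0:
            best = -np.inf
            for s in np.exp(np.linspace(*self.priors.log_sigma_bounds, 60)):
                pi, pd_ = distance_cell_probs(self.binning, DetectionParams(s))
                with np.errstate(divide="ignore"):
                    ll = float((mb * np.log(pi / pd_)).sum())
                if ll > best:
                    best, s0 = ll, s
        _, pd0 = distance_cell_probs(self.binning, DetectionParams(s0))
        _, phi0 = removal_cell_probs(p_a0, self.removal)
        p_p0 = 0.7
        lam0 = max(self.y.mean() / (p_p0 * phi0 * pd0), 0.05) if total > 0 else 1.0
        lo, hi = self.priors.log_sigma_bounds
        w0 = np.clip((np.log(s0) - lo) / (hi - lo), 0.02, 0.98)
        z0 = np.array([np.log(lam0 * p_p0), logit(p_p0), logit(p_a0), logit(w0)])
        return z0[None, :] + 0.3 * rng.standard_normal((n_chains, 4))

    def _proposal_scales(self):
        # rough posterior widths: the product/availability/scale axes
        # tighten with the detection total, the presence axis is wide
        c = 1.0 / np.sqrt(self.y.sum() + 10.0)
        return np.clip(np.array([2.0 * c, 0.8, 5.0 * c, 3.0 * c]), 0.01, None)

    def fit(self, mcmc: McmcSettings = McmcSettings(), seed: int | None = None) -> "PointCountResults":
        """Sample the posterior; returns a :class:`PointCountResults`."""
        if seed is None:
            seed = mcmc.seed
        rng = np.random.default_rng(seed)
        z0 = self._initial_states(mcmc.chains, rng)
        # nudge any zero-density starts back toward the center
        for _ in range(50):
            bad = ~np.isfinite(self._log_post(z0))
            if not bad.any():
                break
            z0[bad] = z0[~bad].mean(axis=0) + 0.05 * rng.standard_normal((bad.sum(), 4))
        draws_z, acc = adaptive_metropolis(
            self._log_post, z0, mcmc.iterations, mcmc.burn_in, mcmc.thin, rng,
            scales=self._proposal_scales())
        C, n_kept, _ = draws_z.shape
        flat = draws_z.reshape(C * n_kept, 4)
        lam, p_p, p_a, sigma, _ = self._unpack(flat)
        shape = (C, n_kept)
        phi = 1.0 - (1.0 - p_a) ** self.removal.J
        mids, widths, B = self.binning.midpoints, self.binning.widths, self.binning.B
        pi_d = np.exp(-(mids[None, :] ** 2) / (2.0 * sigma[:, None] ** 2)) \
            * (2.0 * mids * widths / B ** 2)[None, :]
        p_d = pi_d.sum(axis=1)
        draws = {
            "lam": lam.reshape(shape),
            "p_p": p_p.reshape(shape),
            "p_a": p_a.reshape(shape),
            "sigma": sigma.reshape(shape),
            "phi": phi.reshape(shape),
            "p_d": p_d.reshape(shape),
            "lam_p_p": (lam * p_p).reshape(shape),
            "D": derive_density(lam, self.binning).reshape(shape),
            "N_total": (lam * self.n_points).reshape(shape),
        }
        return PointCountResults(self, draws, mcmc, seed, acc)


class PointCountResults:
    """Posterior summaries, diagnostics and flags for a fitted model.

    Attributes
    ----------
    draws : dict of ndarray (chains, draws)
        Posterior draws per parameter, including the derived
        availability ``phi``, perceptibility ``p_d``, density ``D``
        (birds/km^2) and expected superpopulation total ``N_total``.
    flags : dict
        ``prior_dominated`` (no detections), ``weakly_identified``
        (single-visit data: only ``lam * p_p`` enters the count
        likelihood) and ``converged`` (all R-hat <= threshold).
    """

    RHAT_THRESHOLD = 1.1

    def __init__(self, model, draws, mcmc, seed, accept_rate):
        self.model = model
        self.draws = draws
        self.mcmc = mcmc
        self.seed = seed
        self.accept_rate = accept_rate
        self.flags = {
            "prior_dominated": bool(model.y.sum() == 0),
            "weakly_identified": model.n_visits == 1,
        }
        self._summary = None
        if self.flags["prior_dominated"]:
            warnings.warn("no detections: posterior is prior-dominated", stacklevel=2)
        rh = self.rhat()
        self.flags["converged"] = bool(max(rh.values()) <= self.RHAT_THRESHOLD)
        if not self.flags["converged"]:
            worst = max(rh, key=rh.get)
            warnings.warn(f"chains may not have converged: R-hat({worst}) = "
                          f"{rh[worst]:.3f} > {self.RHAT_THRESHOLD}", stacklevel=2)

    def rhat(self) -> dict:
        return {p: gelman_rubin(d) for p, d in self.draws.items()}

    def ess(self) -> dict:
        return {p: effective_draws(d) for p, d in self.draws.items()}

    def summary_frame(self) -> pd.DataFrame:
        if self._summary is None:
            rh, es = self.rhat(), self.ess()
            rows = []
            for p, d in self.draws.items():
                f = d.ravel()
                q = np.percentile(f, [2.5, 50, 97.5])
                rows.append((p, f.mean(), f.std(ddof=1), q[0], q[1], q[2], rh[p], es[p]))
            self._summary = pd.DataFrame(
                rows, columns=["parameter", "mean", "sd", "q2.5", "median", "q97.5",
                               "rhat", "ess"]).set_index("parameter")
        return self._summary

    def summary(self) -> str:
        sf = self.summary_frame()
        lines = [
            "Hybrid distance-sampling / time-removal point-count model",
            f"points: {self.model.n_points}   visits: {self.model.n_visits}   "
            f"detections: {int(self.model.y.sum())}",
            f"chains: {self.mcmc.chains}   kept draws/chain: {self.draws['lam'].shape[1]}"
            f"   seed: {self.seed}",
            "",
            sf.to_string(float_format=lambda v: f"{v:10.4f}"),
            "",
            "flags: " + ", ".join(f"{k}={v}" for k, v in self.flags.items()),
        ]
        return "\n".join(lines)

    def credible_interval(self, param, level=0.95):
        a = (1.0 - level) / 2.0
        f = self.draws[param].ravel()
        return tuple(np.percentile(f, [100 * a, 100 * (1 - a)]))

    def to_report(self) -> dict:
        """Machine-readable run report."""
        sf = self.summary_frame().reset_index()
        return {
            "model": "static",
            "seed": self.seed,
            "settings": {"chains": self.mcmc.chains, "iterations": self.mcmc.iterations,
                         "burn_in": self.mcmc.burn_in, "thin": self.mcmc.thin},
            "n_points": self.model.n_points,
            "n_visits": self.model.n_visits,
            "n_detections": int(self.model.y.sum()),
            "flags": self.flags,
            "posterior": sf.to_dict(orient="records"),
        }
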