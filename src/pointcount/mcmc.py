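"""Small MCMC toolkit: adaptive random-walk Metropolis and chain diagnostics.

The samplers here are deliberately plain: the models in this package
have a handful of continuous parameters with unimodal, well-behaved
posteriors once the latent count layers are marginalized, and a
random-walk Metropolis chain with Robbins-Monro step-size adaptation
mixes well at desk scale.  Chains are vectorized: the target function
evaluates all chains' states in one call.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gelman_rubin", "effective_draws", "adaptive_metropolis"]

_TARGET_ACCEPT = 0.28  # near-optimal for low-dimensional joint RW proposals


def gelman_rubin(chains) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    Parameters
    ----------
    chains : array_like, shape (m, n)
        ``m >= 2`` parallel chains of equal length ``n >= 10``.

    Returns
    -------
    float
        ``sqrt(((n-1)/n * W + B/n) / W)`` where ``W`` is the mean
        within-chain variance and ``B/n`` the variance of the chain
        means.  Approaches 1 from above as chains mix and lengthen.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("diagnostic requires >= 2 chains of equal length")
    m, n = x.shape
    if n < 10:
        raise ValueError("chains too short for a meaningful diagnostic")
    chain_means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = chain_means.var(ddof=1)
    if W == 0:
        return 1.0 if B_over_n == 0 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def effective_draws(chains) -> float:
    """Effective sample size across chains (bulk ESS via arviz)."""
    import arviz as az

    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected (chains, draws)")
    return float(az.ess(x))


def adaptive_metropolis(log_post, x0, n_iter, burn_in, thin=1, rng=None,
                        scales=None, adapt_every=50):
    """Vectorized random-walk Metropolis with step-size adaptation.

    Parameters
    ----------
    log_post : callable
        Maps an array of chain states ``(C, D)`` to log posterior
        densities ``(C,)``; may return ``-inf`` for invalid states.
    x0 : ndarray, shape (C, D)
        Initial state of each chain.
    n_iter, burn_in, thin : int
        Total iterations, iterations discarded (adaptation happens only
        here, keeping the kept chain Markovian), and thinning stride.
    scales : ndarray (D,) or (C, D), optional
        Initial per-dimension proposal standard deviations.

    Returns
    -------
    draws : ndarray, shape (C, n_kept, D)
    accept_rate : ndarray, shape (C,)
    """
    rng = np.random.default_rng(rng)
    x = np.array(x0, dtype=float)
    C, D = x.shape
    if scales is None:
        scales = np.full(D, 0.2)
    L = np.diag(np.asarray(scales, dtype=float))  # proposal Cholesky factor
    log_s = np.zeros(C)                           # per-chain global step multiplier

    lp = log_post(x)
    if not np.all(np.isfinite(lp)):
        raise ValueError("initial states have zero posterior density")

    history = []
    kept = []
    n_acc = np.zeros(C)
    batch_acc = np.zeros(C)
    batch = 0
    for it in range(n_iter):
        step = rng.standard_normal((C, D)) @ L.T
        prop = x + np.exp(log_s)[:, None] * step
        lp_prop = log_post(prop)
        accept = np.log(rng.random(C)) < lp_prop - lp
        x[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        if it < burn_in:
            history.append(x.copy())
            batch_acc += accept
            if (it + 1) % adapt_every == 0:
                batch += 1
                rate = batch_acc / adapt_every
                log_s += (rate - _TARGET_ACCEPT) / np.sqrt(batch)
                batch_acc[:] = 0.0
                if len(history) * C >= 10 * D:
                    # Haario-style: learn proposal shape from the pooled
                    # recent burn-in states of all chains
                    pool = np.concatenate(history[-2000:], axis=0)
                    cov = np.cov(pool.T) + 1e-8 * np.eye(D)
                    L = np.linalg.cholesky(2.38 ** 2 / D * cov)
        else:
            n_acc += accept
            if (it - burn_in) % thin == 0:
                kept.append(x.copy())
    draws = np.stack(kept, axis=1)
    return draws, n_acc / max(n_iter - burn_in, 1)
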