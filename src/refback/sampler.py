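"""Differential-evolution MCMC (DE-MCMC) for diffusion-model posteriors.

Proposals for chain k are crossover steps ``x_k + gamma (x_r1 - x_r2) +
jitter`` using two other randomly chosen chains, with ``gamma =
2.38/sqrt(2 d)`` by default and occasional gamma = 1 steps for mode
jumping.  During burn-in a migration step (probability 0.05 per
iteration) cycles states around a random subset of chains, which helps
absorb outlier chains.  The hierarchical sampler alternates DE updates
of subject-level parameters (conditional on the group) with DE updates
of the group-level truncated-normal hyper-parameters (conditional on
the subjects), in the style of hierarchical samplers for evidence-
accumulation models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .priors import Priors


class InitializationError(RuntimeError):
    pass


@dataclass
class SamplerConfig:
    """Tuning knobs for DE-MCMC.

    ``n_chains`` defaults to 3x the number of free parameters;
    ``gamma`` to 2.38/sqrt(2 d).
    """

    n_chains: int | None = None
    n_burn: int = 500
    n_keep: int = 1000
    thin: int = 1
    gamma: float | None = None
    jitter: float = 1e-3
    p_migrate: float = 0.05
    gamma_one_prob: float = 0.1

    def chains_for(self, d: int) -> int:
        k = self.n_chains if self.n_chains is not None else 3 * d
        return max(k, 4)

    def gamma_for(self, d: int) -> float:
        return self.gamma if self.gamma is not None else 2.38 / math.sqrt(2 * d)


def _pick_pair(K: int, k: int, rng) -> tuple[int, int]:
    r1 = rng.integers(K - 1)
    if r1 >= k:
        r1 += 1
    r2 = rng.integers(K - 2)
    for taken in sorted((k, r1)):
        if r2 >= taken:
            r2 += 1
    return int(r1), int(r2)


def _migrate(x: np.ndarray, lp: np.ndarray, logpost, rng) -> None:
    """DMC-style migration: cycle states around a random chain subset."""
    K = x.shape[0]
    size = int(rng.integers(1, K)) + 1
    ring = rng.permutation(K)[:size]
    prev_states = x[ring[np.arange(size) - 1]].copy()
    for i, k in enumerate(ring):
        prop = prev_states[i]
        lpp = logpost(prop)
        if math.log(rng.uniform()) < lpp - lp[k]:
            x[k] = prop
            lp[k] = lpp


def de_mcmc(logpost, x0: np.ndarray, config: SamplerConfig, rng: np.random.Generator):
    """Sample a d-dimensional posterior with K interacting chains.

    ``x0`` is (K, d) with finite log posterior at every row.  Returns
    ``(draws, logp)`` with shapes (K, n_keep, d) and (K, n_keep).
    """
    x = np.array(x0, dtype=float)
    K, d = x.shape
    gamma = config.gamma_for(d)
    lp = np.array([logpost(x[k]) for k in range(K)])
    if not np.all(np.isfinite(lp)):
        raise InitializationError("non-finite log posterior at start points")
    draws = np.empty((K, config.n_keep, d))
    lps = np.empty((K, config.n_keep))
    n_iter = config.n_burn + config.n_keep * config.thin
    for it in range(n_iter):
        burn = it < config.n_burn
        if burn and rng.uniform() < config.p_migrate:
            _migrate(x, lp, logpost, rng)
        else:
            for k in range(K):
                r1, r2 = _pick_pair(K, k, rng)
                g = 1.0 if rng.uniform() < config.gamma_one_prob else gamma
                prop = x[k] + g * (x[r1] - x[r2]) + config.jitter * rng.uniform(-1, 1, d)
                lpp = logpost(prop)
                if lpp > -np.inf and math.log(rng.uniform()) < lpp - lp[k]:
                    x[k] = prop
                    lp[k] = lpp
        if not burn and (it - config.n_burn) % config.thin == 0:
            j = (it - config.n_burn) // config.thin
            draws[:, j] = x
            lps[:, j] = lp
    return draws, lps


def hierarchical_de_mcmc(
    subject_loglik,
    theta0: np.ndarray,
    priors: Priors,
    config: SamplerConfig,
    rng: np.random.Generator,
    support_ok=None,
):
    """Alternating subject-/group-level DE-MCMC.

    Parameters
    ----------
    subject_loglik : callable
        ``subject_loglik(s, theta) -> float`` data log-likelihood of
        subject ``s``.
    theta0 : (S, d) array
        Per-subject start points (e.g. moment-based estimates).
    priors : Priors
        Subject-level support and the priors placed on the hyper-means;
        hyper-SDs get the half-normal prior from ``priors``.
    support_ok : callable, optional
        Joint support predicate for a subject parameter vector.

    Returns a dict with ``theta`` draws (K, n_keep, S, d), ``mu`` and
    ``sd`` group draws (K, n_keep, d).
    """
    S, d = theta0.shape
    K = config.chains_for(d)
    gamma = config.gamma_for(d)
    lo, hi = priors.lower, priors.upper
    if support_ok is None:
        support_ok = lambda th: True  # noqa: E731

    def tn_sum(theta_row, mu, sd):
        # quadratic part only: normalization constants cancel in the
        # subject-level MH ratio because both sides share the chain's hyper
        z = (theta_row - mu) / sd
        return -0.5 * float(z @ z)

    def _log_z(mu, sd):
        from scipy.special import ndtr

        return np.log(ndtr((hi - mu) / sd) - ndtr((lo - mu) / sd))

    m0, s0 = priors.mu, priors.sigma
    hsc = priors.hyper_sd_scale

    def group_update(theta_k, mu_k, sd_k, rng):
        """Metropolis-within-Gibbs on (hyper-mean, hyper-SD), per parameter.

        Independence proposals from the untruncated conjugate
        conditionals, corrected by exact MH for the truncation constants
        and the half-normal hyper-SD prior; vectorized over parameters.
        """
        th_sum = theta_k.sum(axis=0)
        # --- hyper-mean step (given sd) ---
        var_hat = 1.0 / (S / sd_k**2 + 1.0 / s0**2)
        m_hat = var_hat * (th_sum / sd_k**2 + m0 / s0**2)
        prop = rng.normal(m_hat, np.sqrt(var_hat))

        def mu_target(mu):
            t = -S * _log_z(mu, sd_k)
            t = t - ((theta_k - mu) ** 2).sum(axis=0) / (2 * sd_k**2)
            t = t - (mu - m0) ** 2 / (2 * s0**2)
            return t

        ok = (prop > lo) & (prop < hi)
        logr = np.full(d, -np.inf)
        logq_cur = -((mu_k - m_hat) ** 2) / (2 * var_hat)
        logq_prop = -((prop - m_hat) ** 2) / (2 * var_hat)
        logr[ok] = (mu_target(prop) - mu_target(mu_k) + logq_cur - logq_prop)[ok]
        acc = np.log(rng.uniform(size=d)) < logr
        mu_k = np.where(acc, prop, mu_k)
        # --- hyper-SD step (given mu) ---
        sse = ((theta_k - mu_k) ** 2).sum(axis=0)
        a_n = S / 2.0 + 1.0
        b_n = sse / 2.0 + 1e-8
        var_prop = b_n / rng.gamma(a_n, 1.0, size=d)

        def sd_target(var):
            sd = np.sqrt(var)
            return (
                -S * np.log(sd)
                - S * _log_z(mu_k, sd)
                - sse / (2 * var)
                - 0.5 * (sd / hsc) ** 2
                - 0.5 * np.log(var)  # Jacobian of the sd -> var map
            )

        def logq_ig(var):
            return -(a_n + 1.0) * np.log(var) - b_n / var

        cur_var = sd_k**2
        logr = sd_target(var_prop) - sd_target(cur_var) + logq_ig(cur_var) - logq_ig(var_prop)
        acc = np.log(rng.uniform(size=d)) < logr
        sd_k = np.where(acc, np.sqrt(var_prop), sd_k)
        return mu_k, sd_k

    # initialize chains around the subject start points
    theta = np.empty((K, S, d))
    ll = np.empty((K, S))
    for k in range(K):
        for s in range(S):
            for attempt in range(200):
                cand = theta0[s] * (1 + 0.05 * rng.standard_normal(d)) + 0.01 * rng.standard_normal(d)
                cand = np.clip(cand, lo + 1e-4, hi - 1e-4)
                if not support_ok(cand):
                    continue
                v = subject_loglik(s, cand)
                if np.isfinite(v):
                    theta[k, s] = cand
                    ll[k, s] = v
                    break
            else:
                raise InitializationError(f"could not initialize subject {s}")
    mu = np.empty((K, d))
    sd = np.empty((K, d))
    emp_mu = theta0.mean(axis=0)
    emp_sd = np.maximum(theta0.std(axis=0), 0.05)
    for k in range(K):
        mu[k] = np.clip(
            emp_mu * (1 + 0.05 * rng.standard_normal(d)), lo + 1e-4, hi - 1e-4
        )
        sd[k] = emp_sd * np.exp(0.2 * rng.standard_normal(d))

    def scale_move(k, rng):
        """Joint rescale of subject deviations and hyper-SD (funnel breaker).

        theta_s -> mu + c*(theta_s - mu), sd -> c*sd with per-parameter
        log-normal factors c.  Z-scores are invariant, so the move slides
        along the funnel axis; accepted by exact MH with the Jacobian
        c^(S+1) per parameter.
        """
        c = np.exp(0.05 * rng.standard_normal(d))
        new_sd = c * sd[k]
        new_theta = mu[k] + c * (theta[k] - mu[k])
        if np.any(new_theta <= lo) or np.any(new_theta >= hi):
            return
        for s in range(S):
            if not support_ok(new_theta[s]):
                return
        new_ll = np.array([subject_loglik(s, new_theta[s]) for s in range(S)])
        if not np.all(np.isfinite(new_ll)):
            return
        logr = (
            float(new_ll.sum() - ll[k].sum())
            + float(np.sum(np.log(c)))  # -S log c from the TN norm + (S+1) log c Jacobian
            - S * float(np.sum(_log_z(mu[k], new_sd) - _log_z(mu[k], sd[k])))
            + priors.log_hyper_sd(new_sd)
            - priors.log_hyper_sd(sd[k])
        )
        if math.log(rng.uniform()) < logr:
            theta[k] = new_theta
            sd[k] = new_sd
            ll[k] = new_ll

    n_keep = config.n_keep
    theta_draws = np.empty((K, n_keep, S, d))
    mu_draws = np.empty((K, n_keep, d))
    sd_draws = np.empty((K, n_keep, d))
    ll_draws = np.empty((K, n_keep, S))
    n_iter = config.n_burn + n_keep * config.thin
    for it in range(n_iter):
        burn = it < config.n_burn
        # group-level update
        for k in range(K):
            mu[k], sd[k] = group_update(theta[k], mu[k], sd[k], rng)
        if it % 3 == 0:
            for k in range(K):
                scale_move(k, rng)
        # subject-level updates
        migrate_now = burn and rng.uniform() < config.p_migrate
        for s in range(S):
            if migrate_now:
                size = int(rng.integers(1, K)) + 1
                ring = rng.permutation(K)[:size]
                prev = theta[ring[np.arange(size) - 1], s].copy()
                prev_ll = ll[ring[np.arange(size) - 1], s].copy()
                for i, k in enumerate(ring):
                    cand = prev[i]
                    if not support_ok(cand):
                        continue
                    cur = ll[k, s] + tn_sum(theta[k, s], mu[k], sd[k])
                    new = prev_ll[i] + tn_sum(cand, mu[k], sd[k])
                    if math.log(rng.uniform()) < new - cur:
                        theta[k, s] = cand
                        ll[k, s] = prev_ll[i]
                continue
            for k in range(K):
                r1, r2 = _pick_pair(K, k, rng)
                g = 1.0 if rng.uniform() < config.gamma_one_prob else gamma
                prop = (
                    theta[k, s]
                    + g * (theta[r1, s] - theta[r2, s])
                    + config.jitter * rng.uniform(-1, 1, d)
                )
                if np.any(prop <= lo) or np.any(prop >= hi) or not support_ok(prop):
                    continue
                new_ll = subject_loglik(s, prop)
                cur = ll[k, s] + tn_sum(theta[k, s], mu[k], sd[k])
                new = new_ll + tn_sum(prop, mu[k], sd[k])
                if np.isfinite(new) and math.log(rng.uniform()) < new - cur:
                    theta[k, s] = prop
                    ll[k, s] = new_ll
        if not burn and (it - config.n_burn) % config.thin == 0:
            j = (it - config.n_burn) // config.thin
            theta_draws[:, j] = theta
            mu_draws[:, j] = mu
            sd_draws[:, j] = sd
            ll_draws[:, j] = ll
    return {"theta": theta_draws, "mu": mu_draws, "sd": sd_draws, "loglik": ll_draws}
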