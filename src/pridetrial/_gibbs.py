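"""Numba kernel for the Metropolis-within-Gibbs sampler.

All heavy MCMC work lives here as nopython-compiled loops: component-wise
Gaussian random-walk Metropolis updates for the dose effects ``beta_k``, the
patient random effects ``W_i`` and (flexible-allocation scheme) the scaling
parameter ``alpha_2``; the random-effect variance ``sigma^2`` is drawn exactly
from its conjugate inverse-gamma conditional, or by Metropolis on ``log sigma``
under a half-Cauchy prior.  Proposal scales adapt during burn-in toward a
30-45% acceptance rate and are frozen afterwards, so retained draws target the
exact posterior.  Everything is deterministic given the integer seed.
"""

import numpy as np
from numba import njit

# variance-prior modes
INV_GAMMA = 0
HALF_CAUCHY = 1

_ADAPT_WINDOW = 50
_ACC_LO = 0.30
_ACC_HI = 0.45


@njit(cache=True, inline="always")
def _log1pexp(x):
    # numerically stable log(1 + exp(x))
    if x > 35.0:
        return x
    if x < -35.0:
        return 0.0
    return np.log1p(np.exp(x))


@njit(cache=True)
def _cond_beta(b, k, y, treated, z2, W, alpha2, mu_k, sigma_beta2):
    """Log full conditional of beta_k (up to a constant)."""
    n = y.shape[0]
    out = -((b - mu_k) ** 2) / (2.0 * sigma_beta2)
    for i in range(n):
        if treated[i, k]:
            a = alpha2 if z2[i, k] else 1.0
            lp = b + a * W[i]
            out += y[i, k] * lp - _log1pexp(lp)
    return out


@njit(cache=True)
def _cond_W(w, i, y, treated, z2, beta, alpha2, sigma2):
    """Log full conditional of W_i (up to a constant)."""
    K = y.shape[1]
    out = -(w * w) / (2.0 * sigma2)
    for k in range(K):
        if treated[i, k]:
            a = alpha2 if z2[i, k] else 1.0
            lp = beta[k] + a * w
            out += y[i, k] * lp - _log1pexp(lp)
    return out


@njit(cache=True)
def _cond_alpha2(a2, y, treated, z2, beta, W, sigma_alpha2):
    """Log full conditional of alpha_2 over down-retreated cells."""
    n, K = y.shape
    out = -((a2 - 1.0) ** 2) / (2.0 * sigma_alpha2)
    for i in range(n):
        for k in range(K):
            if treated[i, k] and z2[i, k]:
                lp = beta[k] + a2 * W[i]
                out += y[i, k] * lp - _log1pexp(lp)
    return out


@njit(cache=True)
def _cond_log_sigma(ls, W, tau):
    """Log conditional of log(sigma) under Half-Cauchy(0, tau), incl. Jacobian."""
    n = W.shape[0]
    sigma = np.exp(ls)
    s2 = sigma * sigma
    sw2 = 0.0
    for i in range(n):
        sw2 += W[i] * W[i]
    return -(n * ls + sw2 / (2.0 * s2) + np.log(tau * tau + s2)) + ls


@njit(cache=True)
def gibbs_kernel(
    y,
    treated,
    z2,
    mu,
    sigma_beta2,
    var_prior_mode,
    eta,
    tau,
    sigma_alpha2,
    sample_W,
    sample_alpha2,
    fixed_sigma2,
    n_samples,
    burn_in,
    seed,
):
    """Run the full MH-within-Gibbs chain; returns retained draws.

    Parameters are raw arrays/scalars so the whole loop compiles:
    ``y``/``treated``/``z2`` are (n, K) float64/bool/bool; ``fixed_sigma2 <= 0``
    means "sample sigma^2".  Returns (beta_draws, W_draws, sigma2_draws,
    alpha2_draws).
    """
    np.random.seed(seed)
    n, K = y.shape

    beta = mu.copy()
    W = np.zeros(n)
    sigma2 = fixed_sigma2 if fixed_sigma2 > 0.0 else 1.0
    log_sigma = 0.5 * np.log(sigma2)
    alpha2 = 1.0

    step_beta = np.full(K, 0.5)
    step_W = np.full(n, 0.5)
    step_a = 0.5
    step_s = 0.5
    acc_beta = np.zeros(K)
    acc_W = np.zeros(n)
    acc_a = 0.0
    acc_s = 0.0

    beta_out = np.empty((n_samples, K))
    W_out = np.empty((n_samples, n))
    sigma2_out = np.empty(n_samples)
    alpha2_out = np.empty(n_samples)

    total = burn_in + n_samples
    for it in range(total):
        # --- dose effects ------------------------------------------------
        for k in range(K):
            prop = beta[k] + step_beta[k] * np.random.normal()
            logr = _cond_beta(prop, k, y, treated, z2, W, alpha2, mu[k], sigma_beta2) - _cond_beta(
                beta[k], k, y, treated, z2, W, alpha2, mu[k], sigma_beta2
            )
            if np.log(np.random.random()) < logr:
                beta[k] = prop
                acc_beta[k] += 1.0

        # --- patient effects --------------------------------------------
        if sample_W:
            for i in range(n):
                prop = W[i] + step_W[i] * np.random.normal()
                logr = _cond_W(prop, i, y, treated, z2, beta, alpha2, sigma2) - _cond_W(
                    W[i], i, y, treated, z2, beta, alpha2, sigma2
                )
                if np.log(np.random.random()) < logr:
                    W[i] = prop
                    acc_W[i] += 1.0

            # --- random-effect variance ---------------------------------
            if fixed_sigma2 <= 0.0:
                if var_prior_mode == INV_GAMMA:
                    sw2 = 0.0
                    for i in range(n):
                        sw2 += W[i] * W[i]
                    shape = eta + 0.5 * n
                    rate = eta + 0.5 * sw2
                    sigma2 = rate / np.random.gamma(shape, 1.0)
                else:  # half-Cauchy on sigma, MH on log sigma
                    prop = log_sigma + step_s * np.random.normal()
                    logr = _cond_log_sigma(prop, W, tau) - _cond_log_sigma(log_sigma, W, tau)
                    if np.log(np.random.random()) < logr:
                        log_sigma = prop
                        acc_s += 1.0
                    sigma2 = np.exp(2.0 * log_sigma)

        # --- flexible-allocation scaling ---------------------------------
        if sample_alpha2:
            prop = alpha2 + step_a * np.random.normal()
            logr = _cond_alpha2(prop, y, treated, z2, beta, W, sigma_alpha2) - _cond_alpha2(
                alpha2, y, treated, z2, beta, W, sigma_alpha2
            )
            if np.log(np.random.random()) < logr:
                alpha2 = prop
                acc_a += 1.0

        # --- burn-in step adaptation -------------------------------------
        if it < burn_in and (it + 1) % _ADAPT_WINDOW == 0:
            for k in range(K):
                rate = acc_beta[k] / _ADAPT_WINDOW
                if rate < _ACC_LO:
                    step_beta[k] *= 0.8
                elif rate > _ACC_HI:
                    step_beta[k] *= 1.25
                acc_beta[k] = 0.0
            for i in range(n):
                rate = acc_W[i] / _ADAPT_WINDOW
                if rate < _ACC_LO:
                    step_W[i] *= 0.8
                elif rate > _ACC_HI:
                    step_W[i] *= 1.25
                acc_W[i] = 0.0
            if acc_a / _ADAPT_WINDOW < _ACC_LO:
                step_a *= 0.8
            elif acc_a / _ADAPT_WINDOW > _ACC_HI:
                step_a *= 1.25
            acc_a = 0.0
            if acc_s / _ADAPT_WINDOW < _ACC_LO:
                step_s *= 0.8
            elif acc_s / _ADAPT_WINDOW > _ACC_HI:
                step_s *= 1.25
            acc_s = 0.0

        if it >= burn_in:
            j = it - burn_in
            beta_out[j] = beta
            W_out[j] = W
            sigma2_out[j] = sigma2
            alpha2_out[j] = alpha2

    return beta_out, W_out, sigma2_out, alpha2_out
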