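"""Bayesian hierarchical logistic toxicity model with patient random effects.

The model underlying the PRIDE ("patient retreat in dose escalation") and
PRIDE-FA (flexible allocation) schemes.  Patient ``i`` treated at dose ``k``
experiences a dose-limiting toxicity (DLT) with probability

    logit p_ik = beta_k + alpha_{Z_ik} * W_i

where ``beta_k`` is the dose effect (prior N(mu_k, sigma_beta^2), with
``mu_k = logit c_k`` for an increasing skeleton ``c``), ``W_i ~ N(0, sigma^2)``
is a patient random effect capturing intra-patient correlation across
treatment cycles, and ``alpha_{Z}`` rescales the random effect for
down-retreated assignments (Z=2) under the flexible-allocation scheme
(``alpha_1 = 1`` always; ``alpha_2 ~ N(1, sigma_alpha^2)``, fixed at 1 under
plain PRIDE).  The variance gets either a conjugate Inv-Gamma(eta, eta) prior
on ``sigma^2`` or a Half-Cauchy(0, tau) prior on ``sigma``.

Posterior inference is Metropolis-Hastings within Gibbs
(:class:`IntraPatientToxicityModel`.fit), with full conditionals exposed here
as plain functions so they can be checked independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from . import _gibbs
from .data import TrialData

__all__ = [
    "HierPriors",
    "PosteriorDraws",
    "PosteriorResults",
    "IntraPatientToxicityModel",
    "dlt_probability",
    "log_likelihood",
    "log_cond_beta",
    "log_cond_W",
    "sample_sigma2",
    "log_cond_sigma_halfcauchy",
    "log_cond_alpha2",
    "sample_posterior",
    "posterior_dose_rates",
]


# ----------------------------------------------------------------------
# priors
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class HierPriors:
    """Hyperparameters of the hierarchical model.

    Attributes
    ----------
    c : tuple of float
        Increasing prior skeleton of expected DLT rates; ``mu_k = logit(c_k)``.
    sigma_beta2 : float
        Prior variance of each dose effect (default 10, weakly informative).
    variance_prior : {"inv_gamma", "half_cauchy"}
        Prior family for the random-effect scale.
    eta : float
        Inv-Gamma(eta, eta) hyperparameter for ``sigma^2`` (default 1).
    tau : float
        Half-Cauchy scale for ``sigma`` (used when
        ``variance_prior == "half_cauchy"``).
    sigma_alpha2 : float
        Prior variance of the down-retreat scaling ``alpha_2 ~ N(1, .)``.
    """

    c: tuple
    sigma_beta2: float = 10.0
    variance_prior: Literal["inv_gamma", "half_cauchy"] = "inv_gamma"
    eta: float = 1.0
    tau: float = 1.0
    sigma_alpha2: float = 1.0

    def __post_init__(self):
        c = np.asarray(self.c, dtype=float)
        if np.any(np.diff(c) <= 0) or np.any(c <= 0) or np.any(c >= 1):
            raise ValueError("skeleton c must be strictly increasing in (0,1)")
        for name in ("sigma_beta2", "eta", "tau", "sigma_alpha2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.variance_prior not in ("inv_gamma", "half_cauchy"):
            raise ValueError("variance_prior must be 'inv_gamma' or 'half_cauchy'")

    @classmethod
    def default(cls, n_doses: int, **kwargs) -> "HierPriors":
        """Default skeleton: expected rates equally spaced from 0.1 to 0.5."""
        c = tuple(np.linspace(0.1, 0.5, n_doses))
        return cls(c=c, **kwargs)

    @property
    def mu(self) -> np.ndarray:
        """Prior means of the dose effects on the logit scale."""
        return logit(np.asarray(self.c, dtype=float))

    @property
    def n_doses(self) -> int:
        return len(self.c)


# ----------------------------------------------------------------------
# likelihood and full conditionals (reference implementations)
# ----------------------------------------------------------------------
def dlt_probability(beta_k: float, W_i: float, alpha: float = 1.0) -> float:
    """DLT probability expit(beta_k + alpha * W_i)."""
    return float(expit(beta_k + alpha * W_i))


def _alpha_matrix(data: TrialData, alpha2: float) -> np.ndarray:
    return np.where(data.assign_type == 2, alpha2, 1.0)


def log_likelihood(
    data: TrialData, beta: np.ndarray, W: np.ndarray, alpha2: float = 1.0
) -> float:
    """Bernoulli log likelihood summed over treated (patient, dose) cells."""
    beta = np.asarray(beta, dtype=float)
    W = np.asarray(W, dtype=float)
    if beta.shape != (data.n_doses,):
        raise ValueError(f"beta must have length {data.n_doses}")
    if W.shape != (data.n_patients,):
        raise ValueError(f"W must have length {data.n_patients}")
    a = _alpha_matrix(data, alpha2)
    lp = beta[None, :] + a * W[:, None]
    cell = data.y * lp - np.logaddexp(0.0, lp)
    return float(np.sum(cell * data.treated))


def log_cond_beta(
    k: int, data: TrialData, W: np.ndarray, alpha2: float, priors: HierPriors
) -> Callable[[float], float]:
    """Log full conditional of beta_k (up to a constant), as a function."""
    if not 0 <= k < data.n_doses:
        raise IndexError("dose index out of range")
    W = np.asarray(W, dtype=float)
    mask = data.treated[:, k]
    yk = data.y[mask, k].astype(float)
    aW = (_alpha_matrix(data, alpha2)[:, k] * W)[mask]
    mu_k = priors.mu[k]

    def logdens(b: float) -> float:
        lp = b + aW
        lik = np.sum(yk * lp - np.logaddexp(0.0, lp))
        return float(lik - (b - mu_k) ** 2 / (2.0 * priors.sigma_beta2))

    return logdens


def log_cond_W(
    i: int,
    data: TrialData,
    beta: np.ndarray,
    sigma2: float,
    alpha2: float,
    priors: HierPriors,
) -> Callable[[float], float]:
    """Log full conditional of the patient effect W_i (up to a constant)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    beta = np.asarray(beta, dtype=float)
    mask = data.treated[i, :]
    yi = data.y[i, mask].astype(float)
    bi = beta[mask]
    ai = _alpha_matrix(data, alpha2)[i, mask]

    def logdens(w: float) -> float:
        lp = bi + ai * w
        lik = np.sum(yi * lp - np.logaddexp(0.0, lp))
        return float(lik - w * w / (2.0 * sigma2))

    return logdens


def sample_sigma2(W: np.ndarray, eta: float):
    """Exact conjugate conditional of sigma^2: Inv-Gamma(eta + n/2, eta + sum W^2 / 2).

    Returns a frozen ``scipy.stats.invgamma`` distribution; with empty ``W``
    this is the Inv-Gamma(eta, eta) prior.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    W = np.asarray(W, dtype=float)
    shape = eta + 0.5 * W.size
    rate = eta + 0.5 * float(np.sum(W**2))
    return stats.invgamma(shape, scale=rate)


def log_cond_sigma_halfcauchy(W: np.ndarray, tau: float) -> Callable[[float], float]:
    """Log conditional kernel of sigma under a Half-Cauchy(0, tau) prior.

    Higher value = higher density; returns -inf for sigma <= 0.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    W = np.asarray(W, dtype=float)
    n = W.size
    sw2 = float(np.sum(W**2))

    def logdens(sigma: float) -> float:
        if sigma <= 0:
            return -np.inf
        return -(n * np.log(sigma) + sw2 / (2.0 * sigma**2) + np.log(tau**2 + sigma**2))

    return logdens


def log_cond_alpha2(
    data: TrialData, beta: np.ndarray, W: np.ndarray, priors: HierPriors
) -> Callable[[float], float]:
    """Log full conditional of the down-retreat scaling alpha_2.

    Only cells with assignment type Z=2 contribute likelihood terms; with no
    such cells this is the N(1, sigma_alpha^2) log prior kernel.
    """
    beta = np.asarray(beta, dtype=float)
    W = np.asarray(W, dtype=float)
    mask = data.treated & (data.assign_type == 2)
    ii, kk = np.nonzero(mask)
    yv = data.y[ii, kk].astype(float)
    bv = beta[kk]
    wv = W[ii]

    def logdens(a2: float) -> float:
        lp = bv + a2 * wv
        lik = np.sum(yv * lp - np.logaddexp(0.0, lp))
        return float(lik - (a2 - 1.0) ** 2 / (2.0 * priors.sigma_alpha2))

    return logdens


# ----------------------------------------------------------------------
# posterior draws
# ----------------------------------------------------------------------
@dataclass
class PosteriorDraws:
    """Retained MCMC draws: beta (S, K), W (S, n), sigma2 (S,), alpha2 (S,)."""

    beta: np.ndarray
    W: np.ndarray
    sigma2: np.ndarray
    alpha2: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_doses(self) -> int:
        return self.beta.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"beta_{k+1}": self.beta[:, k] for k in range(self.n_doses)}
        cols.update({f"W_{i+1}": self.W[:, i] for i in range(self.W.shape[1])})
        cols["sigma2"] = self.sigma2
        cols["alpha2"] = self.alpha2
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def posterior_dose_rates(
    draws: PosteriorDraws,
    marginalize: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-draw DLT rate at each dose, shape (S, K).

    By default the reference-patient rate ``p_k = expit(beta_k)`` (W = 0, the
    median patient).  With ``marginalize=True`` each draw instead averages
    ``expit(beta_k + W)`` over ``W ~ N(0, sigma^2)`` by Monte Carlo (64
    deviates per draw), i.e. the population-averaged rate.
    """
    if not marginalize:
        return expit(draws.beta)
    rng = rng or np.random.default_rng(0)
    S, K = draws.beta.shape
    z = rng.standard_normal((S, 64))
    w = z * np.sqrt(draws.sigma2)[:, None]
    return expit(draws.beta[:, :, None] + w[:, None, :]).mean(axis=2)


# ----------------------------------------------------------------------
# model / results
# ----------------------------------------------------------------------
class PosteriorResults:
    """Posterior summary object returned by ``IntraPatientToxicityModel.fit``."""

    def __init__(self, model: "IntraPatientToxicityModel", draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    def dose_rates(self, marginalize: bool = False) -> np.ndarray:
        """Per-draw per-dose DLT rates (S, K)."""
        return posterior_dose_rates(
            self.draws, marginalize=marginalize, rng=np.random.default_rng(0)
        )

    def prob_above(self, phi: float, marginalize: bool = False) -> np.ndarray:
        """Posterior Pr(p_k > phi) at every dose."""
        return (self.dose_rates(marginalize) > phi).mean(axis=0)

    def summary(self) -> pd.DataFrame:
        """Posterior means, SDs and 95% intervals for the dose rates and scales."""
        rates = self.dose_rates()
        rows = []
        for k in range(self.draws.n_doses):
            rows.append(
                dict(
                    parameter=f"p_{k+1}",
                    mean=rates[:, k].mean(),
                    sd=rates[:, k].std(),
                    q2_5=np.quantile(rates[:, k], 0.025),
                    q97_5=np.quantile(rates[:, k], 0.975),
                )
            )
        for name, v in (("sigma2", self.draws.sigma2), ("alpha2", self.draws.alpha2)):
            rows.append(
                dict(
                    parameter=name,
                    mean=v.mean(),
                    sd=v.std(),
                    q2_5=np.quantile(v, 0.025),
                    q97_5=np.quantile(v, 0.975),
                )
            )
        return pd.DataFrame(rows).set_index("parameter")

    def effective_sample_size(self) -> pd.Series:
        """Crude ESS per dose effect from the lag-autocorrelation sum."""
        out = {}
        for k in range(self.draws.n_doses):
            x = self.draws.beta[:, k]
            x = x - x.mean()
            S = x.size
            var = np.dot(x, x) / S
            if var == 0:
                out[f"beta_{k+1}"] = float(S)
                continue
            rho_sum = 0.0
            for lag in range(1, min(200, S // 2)):
                rho = np.dot(x[:-lag], x[lag:]) / ((S - lag) * var)
                if rho < 0.05:
                    break
                rho_sum += rho
            out[f"beta_{k+1}"] = S / (1.0 + 2.0 * rho_sum)
        return pd.Series(out)


class IntraPatientToxicityModel:
    """Hierarchical logistic DLT model for intra-patient dose escalation.

    Parameters
    ----------
    data : TrialData
        Observed patient x dose outcomes.
    priors : HierPriors, optional
        Defaults to the equally spaced 0.1..0.5 skeleton for ``data.n_doses``.
    scheme : {"pride", "pride_fa"}
        Under plain PRIDE ``alpha_2`` is fixed at 1; under PRIDE-FA it is
        sampled (down-retreated assignments rescale the random effect).
    random_effects : bool
        ``False`` clamps all W_i at 0, giving the correlation-free pooled
        model used by the AIDE/IPDE baselines.
    """

    def __init__(
        self,
        data: TrialData,
        priors: HierPriors | None = None,
        scheme: Literal["pride", "pride_fa"] = "pride",
        random_effects: bool = True,
    ):
        if scheme not in ("pride", "pride_fa"):
            raise ValueError("scheme must be 'pride' or 'pride_fa'")
        self.data = data
        self.priors = priors or HierPriors.default(data.n_doses)
        if self.priors.n_doses != data.n_doses:
            raise ValueError("priors skeleton length must match dose count")
        self.scheme = scheme
        self.random_effects = random_effects

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_doses: int | None = None, **kwargs):
        """Build from a long-format table (patient_id, dose_level, outcome, ...)."""
        return cls(TrialData.from_long(df, n_doses=n_doses), **kwargs)

    def fit(
        self,
        n_samples: int = 2000,
        burn_in: int | None = None,
        seed: int = 0,
        fixed_sigma2: float | None = None,
    ) -> PosteriorResults:
        """Run the MH-within-Gibbs sampler and return retained draws.

        ``burn_in`` defaults to ``n_samples``.  ``fixed_sigma2`` holds the
        random-effect variance at a known value (no sigma^2 updates).
        Deterministic for a fixed seed.
        """
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        draws = sample_posterior(
            self.data,
            self.priors,
            scheme=self.scheme,
            n_samples=n_samples,
            seed=seed,
            burn_in=burn_in,
            fixed_sigma2=fixed_sigma2,
            random_effects=self.random_effects,
        )
        return PosteriorResults(self, draws)


def sample_posterior(
    data: TrialData,
    priors: HierPriors,
    scheme: str = "pride",
    n_samples: int = 2000,
    seed: int = 0,
    burn_in: int | None = None,
    fixed_sigma2: float | None = None,
    random_effects: bool = True,
) -> PosteriorDraws:
    """Functional entry point to the Gibbs sampler (see the model class)."""
    if burn_in is None:
        burn_in = n_samples
    mode = (
        _gibbs.HALF_CAUCHY if priors.variance_prior == "half_cauchy" else _gibbs.INV_GAMMA
    )
    beta, W, sigma2, alpha2 = _gibbs.gibbs_kernel(
        data.y.astype(np.float64),
        data.treated,
        (data.assign_type == 2),
        priors.mu.astype(np.float64),
        float(priors.sigma_beta2),
        mode,
        float(priors.eta),
        float(priors.tau),
        float(priors.sigma_alpha2),
        bool(random_effects),
        scheme == "pride_fa",
        -1.0 if fixed_sigma2 is None else float(fixed_sigma2),
        int(n_samples),
        int(burn_in),
        int(seed) % (2**31 - 1),
    )
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(W))):
        raise RuntimeError("sampler produced non-finite draws")
    return PosteriorDraws(beta=beta, W=W, sigma2=sigma2, alpha2=alpha2)
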