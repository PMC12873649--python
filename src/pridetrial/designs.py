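"""BOIN and CRM plug-ins for the intra-patient retreatment schemes.

Both engines consume the same patient x dose data as the CFO engine and show
that the retreatment machinery is portable:

* BOIN compares a DLT-rate estimate at the current dose against closed-form
  escalation/de-escalation boundaries (lambda_e, lambda_d).  The standard
  design uses the raw rate y_k/n_k; the retreatment variant substitutes the
  posterior estimate from the hierarchical random-effects model.
* CRM fits a two-parameter logistic curve logit p_k = beta_0 + beta_1 d_k
  through "effective doses" d_k backsolved from a prior skeleton; the
  random-effects variant adds the patient effect W_i to the linear predictor
  so repeated cycles on one patient stay correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .cfo import DE_ESCALATE, ESCALATE, STAY
from .data import TrialData

__all__ = [
    "BoinBoundaries",
    "boin_boundaries",
    "boin_decide",
    "CrmPriors",
    "CrmRandomEffectsModel",
    "CrmResults",
    "crm_random_effects_update",
]


# ----------------------------------------------------------------------
# BOIN
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class BoinBoundaries:
    lambda_e: float
    lambda_d: float

    def __post_init__(self):
        if not 0 < self.lambda_e < self.lambda_d < 1:
            raise ValueError("need 0 < lambda_e < lambda_d < 1")


def boin_boundaries(phi: float, phi1: float | None = None, phi2: float | None = None) -> BoinBoundaries:
    """Optimal BOIN interval boundaries for target rate phi.

    Defaults to the conventional alternatives phi1 = 0.6*phi (clearly
    under-dosed) and phi2 = 1.4*phi (clearly over-dosed); lambda_e and
    lambda_d are the likelihood-ratio cutpoints between those hypotheses.
    """
    if not 0 < phi < 1:
        raise ValueError("phi must be in (0,1)")
    phi1 = 0.6 * phi if phi1 is None else phi1
    phi2 = 1.4 * phi if phi2 is None else phi2
    lam_e = np.log((1 - phi1) / (1 - phi)) / np.log(phi * (1 - phi1) / (phi1 * (1 - phi)))
    lam_d = np.log((1 - phi) / (1 - phi2)) / np.log(phi2 * (1 - phi) / (phi * (1 - phi2)))
    return BoinBoundaries(lambda_e=float(lam_e), lambda_d=float(lam_d))


def boin_decide(rate_estimate: float, boundaries: BoinBoundaries) -> str:
    """Escalate iff estimate <= lambda_e; de-escalate iff estimate > lambda_d."""
    if not 0 <= rate_estimate <= 1:
        raise ValueError("rate estimate must be in [0,1]")
    if rate_estimate <= boundaries.lambda_e:
        return ESCALATE
    if rate_estimate > boundaries.lambda_d:
        return DE_ESCALATE
    return STAY


# ----------------------------------------------------------------------
# CRM with patient random effects
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class CrmPriors:
    """Priors for the two-parameter logistic CRM.

    beta_0 ~ N(0, var_beta0); log beta_1 ~ N(0, var_log_beta1) (beta_1 > 0 by
    construction, preserving monotonicity); W_i and sigma^2 as in the
    hierarchical model.
    """

    var_beta0: float = 4.0
    var_log_beta1: float = 1.0
    eta: float = 1.0


class CrmResults:
    """Posterior draws and summaries from the random-effects CRM fit."""

    def __init__(self, model, beta0, beta1, W, sigma2):
        self.model = model
        self.beta0 = beta0
        self.beta1 = beta1
        self.W = W
        self.sigma2 = sigma2

    def dose_rates(self) -> np.ndarray:
        """Per-draw reference-patient rates expit(beta0 + beta1 d_k), (S, K)."""
        return expit(self.beta0[:, None] + self.beta1[:, None] * self.model.effective_doses[None, :])

    def select_dose(self, phi: float) -> int:
        """0-based dose whose posterior mean rate is closest to the target."""
        means = self.dose_rates().mean(axis=0)
        return int(np.argmin(np.abs(means - phi)))


class CrmRandomEffectsModel:
    """Two-parameter logistic CRM with patient random effects.

    logit p_ik = beta_0 + beta_1 d_k + W_i with d_k = logit(skeleton_k) (the
    standard effective-dose convention at prior means beta_0 = 0, beta_1 = 1).
    ``random_effects=False`` clamps W at 0, recovering the ordinary CRM.
    """

    def __init__(
        self,
        data: TrialData,
        skeleton,
        priors: CrmPriors | None = None,
        random_effects: bool = True,
    ):
        skeleton = np.asarray(skeleton, dtype=float)
        if np.any(np.diff(skeleton) <= 0):
            raise ValueError("skeleton must be strictly increasing")
        if len(skeleton) != data.n_doses:
            raise ValueError("skeleton length must match dose count")
        self.data = data
        self.skeleton = skeleton
        self.effective_doses = logit(skeleton)
        self.priors = priors or CrmPriors()
        self.random_effects = random_effects

    def _log_post(self, beta0, log_beta1, W, sigma2):
        pr = self.priors
        d = self.data
        lp = beta0 + np.exp(log_beta1) * self.effective_doses[None, :] + W[:, None]
        lik = float(np.sum((d.y * lp - np.logaddexp(0.0, lp)) * d.treated))
        out = lik - beta0**2 / (2 * pr.var_beta0) - log_beta1**2 / (2 * pr.var_log_beta1)
        if self.random_effects:
            out -= float(np.sum(W**2)) / (2 * sigma2)
        return out

    def fit(self, n_samples: int = 2000, burn_in: int | None = None, seed: int = 0) -> CrmResults:
        """MH-within-Gibbs over (beta_0, log beta_1, W, sigma^2)."""
        if burn_in is None:
            burn_in = n_samples
        rng = np.random.default_rng(seed)
        d = self.data
        n = d.n_patients
        pr = self.priors

        beta0, log_beta1, sigma2 = 0.0, 0.0, 1.0
        W = np.zeros(n)
        steps = {"b0": 0.5, "b1": 0.5}
        step_W = np.full(n, 0.5)

        out0 = np.empty(n_samples)
        out1 = np.empty(n_samples)
        outW = np.empty((n_samples, n))
        outs2 = np.empty(n_samples)

        def cond_fixed(b0, lb1):
            lp = b0 + np.exp(lb1) * self.effective_doses[None, :] + W[:, None]
            lik = float(np.sum((d.y * lp - np.logaddexp(0.0, lp)) * d.treated))
            return lik - b0**2 / (2 * pr.var_beta0) - lb1**2 / (2 * pr.var_log_beta1)

        for it in range(burn_in + n_samples):
            prop = beta0 + steps["b0"] * rng.standard_normal()
            if np.log(rng.random()) < cond_fixed(prop, log_beta1) - cond_fixed(beta0, log_beta1):
                beta0 = prop
            prop = log_beta1 + steps["b1"] * rng.standard_normal()
            if np.log(rng.random()) < cond_fixed(beta0, prop) - cond_fixed(beta0, log_beta1):
                log_beta1 = prop
            if self.random_effects and n > 0:
                b1 = np.exp(log_beta1)
                for i in range(n):
                    mask = d.treated[i]
                    if not mask.any():
                        W[i] = rng.normal(0.0, np.sqrt(sigma2))
                        continue
                    yi = d.y[i, mask].astype(float)
                    di = self.effective_doses[mask]

                    def cw(w):
                        lp = beta0 + b1 * di + w
                        return float(np.sum(yi * lp - np.logaddexp(0.0, lp))) - w * w / (2 * sigma2)

                    prop = W[i] + step_W[i] * rng.standard_normal()
                    if np.log(rng.random()) < cw(prop) - cw(W[i]):
                        W[i] = prop
                shape = pr.eta + 0.5 * n
                rate = pr.eta + 0.5 * float(np.sum(W**2))
                sigma2 = rate / rng.gamma(shape)
            if it >= burn_in:
                j = it - burn_in
                out0[j], out1[j] = beta0, np.exp(log_beta1)
                outW[j] = W
                outs2[j] = sigma2
        return CrmResults(self, out0, out1, outW, outs2)


def crm_random_effects_update(
    data: TrialData,
    skeleton,
    phi: float,
    priors: CrmPriors | None = None,
    n_samples: int = 2000,
    seed: int = 0,
    random_effects: bool = True,
) -> tuple[CrmResults, int]:
    """Fit the random-effects CRM and return (results, selected 0-based dose)."""
    res = CrmRandomEffectsModel(
        data, skeleton, priors=priors, random_effects=random_effects
    ).fit(n_samples=n_samples, seed=seed)
    return res, res.select_dose(phi)
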