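"""Hierarchical toxicity model: likelihood, full conditionals, sampler."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit

from pridetrial.data import TrialData
from pridetrial.model import (
    HierPriors,
    IntraPatientToxicityModel,
    dlt_probability,
    log_cond_W,
    log_cond_alpha2,
    log_cond_beta,
    log_cond_sigma_halfcauchy,
    log_likelihood,
    posterior_dose_rates,
    sample_posterior,
    sample_sigma2,
)

from conftest import random_trial_data


# ----------------------------------------------------------------------
# likelihood
# ----------------------------------------------------------------------
@pytest.mark.parametrize(
    "beta_k, W_i, alpha, expected",
    [
        (0.0, 0.0, 1.0, 0.5),
        (logit(0.33), 0.0, 1.0, 0.33),
        (1.0, 0.5, 2.0, expit(2.0)),
    ],
)
def test_dlt_probability_closed_form(beta_k, W_i, alpha, expected):
    assert dlt_probability(beta_k, W_i, alpha) == pytest.approx(expected, abs=1e-12)


def test_dlt_probability_monotone():
    base = dlt_probability(0.2, 0.1)
    assert dlt_probability(0.3, 0.1) > base
    assert dlt_probability(0.2, 0.2) > base


def test_log_likelihood_empty_is_zero():
    d = TrialData(y=np.zeros((2, 3), dtype=np.int8), treated=np.zeros((2, 3), dtype=bool))
    assert log_likelihood(d, np.zeros(3), np.zeros(2)) == 0.0


def test_log_likelihood_single_cell():
    d = TrialData(y=np.array([[0]]), treated=np.array([[True]]))
    assert log_likelihood(d, np.zeros(1), np.zeros(1)) == pytest.approx(-np.log(2))


def test_log_likelihood_matches_per_cell_oracle(toy_data, rng):
    """Cell-additivity: sum of independent Bernoulli log-masses over treated cells."""
    for _ in range(5):
        beta = rng.normal(size=3)
        W = rng.normal(size=3)
        a2 = rng.uniform(0.2, 2.0)
        total = 0.0
        for i in range(3):
            for k in range(3):
                if toy_data.treated[i, k]:
                    a = a2 if toy_data.assign_type[i, k] == 2 else 1.0
                    p = expit(beta[k] + a * W[i])
                    total += np.log(p) if toy_data.y[i, k] else np.log1p(-p)
        assert log_likelihood(toy_data, beta, W, a2) == pytest.approx(total, abs=1e-12)


def test_log_likelihood_cell_additivity_random(rng):
    for _ in range(10):
        d = random_trial_data(rng, n=5, K=4, with_z2=True)
        beta = rng.normal(size=4)
        W = rng.normal(size=5)
        a2 = rng.uniform(0.5, 1.5)
        oracle = 0.0
        for i in range(5):
            for k in range(4):
                if d.treated[i, k]:
                    a = a2 if d.assign_type[i, k] == 2 else 1.0
                    p = expit(beta[k] + a * W[i])
                    oracle += np.log(p) if d.y[i, k] else np.log1p(-p)
        assert log_likelihood(d, beta, W, a2) == pytest.approx(oracle, abs=1e-10)


def test_log_likelihood_dimension_mismatch(toy_data):
    with pytest.raises(ValueError):
        log_likelihood(toy_data, np.zeros(2), np.zeros(3))
    with pytest.raises(ValueError):
        log_likelihood(toy_data, np.zeros(3), np.zeros(4))


# ----------------------------------------------------------------------
# full conditionals
# ----------------------------------------------------------------------
def test_log_cond_beta_reduces_to_prior_without_data():
    d = TrialData(y=np.zeros((1, 2), dtype=np.int8), treated=np.array([[True, False]]))
    pri = HierPriors.default(2)
    f = log_cond_beta(1, d, np.zeros(1), 1.0, pri)  # dose 2 untreated
    mu = pri.mu[1]
    for b in (-2.0, 0.0, 1.5):
        expected = -((b - mu) ** 2) / (2 * pri.sigma_beta2)
        assert f(b) == pytest.approx(expected, abs=1e-12)


def test_log_cond_beta_consistent_with_joint(toy_data, rng):
    """Differences of the conditional equal differences of likelihood + prior."""
    pri = HierPriors.default(3)
    W = rng.normal(size=3)
    k, a2 = 1, 1.3
    f = log_cond_beta(k, toy_data, W, a2, pri)
    beta = np.array([-1.0, 0.2, 0.8])

    def joint(bk):
        b = beta.copy()
        b[k] = bk
        return log_likelihood(toy_data, b, W, a2) - (bk - pri.mu[k]) ** 2 / (
            2 * pri.sigma_beta2
        )

    assert f(0.7) - f(-0.4) == pytest.approx(joint(0.7) - joint(-0.4), abs=1e-10)


def test_log_cond_beta_mode_near_empirical_logit():
    """Flat prior, 1/2 DLTs at the dose, W = 0: conditional mode ~ logit(0.5) = 0."""
    y = np.array([[1], [0]], dtype=np.int8)
    d = TrialData(y=y, treated=np.ones((2, 1), dtype=bool))
    pri = HierPriors(c=(0.3,), sigma_beta2=1e6)
    f = log_cond_beta(0, d, np.zeros(2), 1.0, pri)
    res = minimize_scalar(lambda b: -f(b), bounds=(-5, 5), method="bounded")
    assert abs(res.x) < 1e-3


def test_log_cond_W_pure_prior_without_doses():
    d = TrialData(y=np.zeros((2, 2), dtype=np.int8),
                  treated=np.array([[True, False], [False, False]]))
    pri = HierPriors.default(2)
    f = log_cond_W(1, d, np.zeros(2), 2.5, 1.0, pri)
    for w in (-1.0, 0.4):
        assert f(w) == pytest.approx(-w * w / (2 * 2.5), abs=1e-12)


def test_log_cond_W_tolerant_patient_mode_negative():
    """Three DLT-free cycles pull the patient-effect mode below zero."""
    d = TrialData(y=np.zeros((1, 3), dtype=np.int8), treated=np.ones((1, 3), dtype=bool))
    pri = HierPriors.default(3)
    f = log_cond_W(0, d, logit(np.array([0.2, 0.3, 0.4])), 1.0, 1.0, pri)
    res = minimize_scalar(lambda w: -f(w), bounds=(-5, 5), method="bounded")
    assert res.x < 0


def test_log_cond_W_consistent_with_joint(toy_data, rng):
    pri = HierPriors.default(3)
    beta = rng.normal(size=3)
    i, s2, a2 = 1, 0.7, 1.4
    f = log_cond_W(i, toy_data, beta, s2, a2, pri)

    def joint(wi):
        W = np.zeros(3)
        W[i] = wi
        return log_likelihood(toy_data, beta, W, a2) - wi * wi / (2 * s2)

    # other patients' W contribute constants that cancel in differences
    assert f(0.9) - f(-0.3) == pytest.approx(joint(0.9) - joint(-0.3), abs=1e-10)


@pytest.mark.parametrize(
    "eta, W, shape, rate",
    [
        (1.0, (0.0, 0.0), 2.0, 1.0),
        (1.0, (1.0, 1.0), 2.0, 2.0),
        (2.0, (1.0, 2.0, 3.0), 3.5, 9.0),
    ],
)
def test_sample_sigma2_conjugate_parameters(eta, W, shape, rate):
    dist = sample_sigma2(np.array(W), eta)
    assert dist.kwds["scale"] == pytest.approx(rate)
    assert dist.args[0] == pytest.approx(shape)


def test_sample_sigma2_empty_is_prior():
    dist = sample_sigma2(np.array([]), 1.5)
    assert dist.args[0] == pytest.approx(1.5)
    assert dist.kwds["scale"] == pytest.approx(1.5)


def test_halfcauchy_kernel_tail_decreasing():
    f = log_cond_sigma_halfcauchy(np.array([]), tau=1.0)
    vals = [f(s) for s in (5.0, 10.0, 50.0)]
    assert vals[0] > vals[1] > vals[2]
    assert f(-1.0) == -np.inf and f(0.0) == -np.inf


def test_halfcauchy_kernel_matches_density_product():
    """Kernel differences equal log differences of HalfCauchy(tau) x prod N(0, s^2)."""
    W = np.array([0.8, -1.1, 0.3])
    tau = 1.7
    f = log_cond_sigma_halfcauchy(W, tau)

    def direct(s):
        return stats.halfcauchy.logpdf(s, scale=tau) + stats.norm.logpdf(W, 0, s).sum()

    for s1, s2 in [(0.5, 1.2), (0.9, 3.0)]:
        assert f(s1) - f(s2) == pytest.approx(direct(s1) - direct(s2), abs=1e-9)


def test_halfcauchy_kernel_mode_matches_grid():
    W = np.array([1.0, 1.0])
    f = log_cond_sigma_halfcauchy(W, 1.0)
    grid = np.linspace(0.01, 5, 20000)
    smax = grid[np.argmax([f(s) for s in grid])]
    res = minimize_scalar(lambda s: -f(s), bounds=(0.01, 5), method="bounded")
    assert res.x == pytest.approx(smax, abs=1e-3)


def test_log_cond_alpha2_prior_kernel_without_z2():
    d = TrialData(y=np.zeros((1, 2), dtype=np.int8), treated=np.array([[True, True]]))
    pri = HierPriors.default(2, sigma_alpha2=0.5)
    f = log_cond_alpha2(d, np.zeros(2), np.zeros(1), pri)
    for a in (0.0, 1.0, 2.3):
        assert f(a) == pytest.approx(-((a - 1) ** 2) / (2 * 0.5), abs=1e-12)


def test_log_cond_alpha2_consistent_with_restricted_likelihood(toy_data, rng):
    pri = HierPriors.default(3)
    beta = rng.normal(size=3)
    W = rng.normal(size=3)
    f = log_cond_alpha2(toy_data, beta, W, pri)
    mask = toy_data.treated & (toy_data.assign_type == 2)

    def restricted(a2):
        out = -((a2 - 1) ** 2) / (2 * pri.sigma_alpha2)
        for i, k in zip(*np.nonzero(mask)):
            p = expit(beta[k] + a2 * W[i])
            out += np.log(p) if toy_data.y[i, k] else np.log1p(-p)
        return out

    for a in (0.3, 1.0, 1.8):
        assert f(a) == pytest.approx(restricted(a), abs=1e-10)


def test_log_cond_alpha2_degenerate_prior_concentrates_at_one(toy_data):
    pri = HierPriors.default(3, sigma_alpha2=1e-8)
    f = log_cond_alpha2(toy_data, np.zeros(3), np.ones(3), pri)
    assert f(1.0) > f(1.01) and f(1.0) > f(0.99)


# ----------------------------------------------------------------------
# sampler
# ----------------------------------------------------------------------
def test_sampler_seed_determinism(toy_data):
    pri = HierPriors.default(3)
    a = sample_posterior(toy_data, pri, n_samples=200, seed=42)
    b = sample_posterior(toy_data, pri, n_samples=200, seed=42)
    assert np.array_equal(a.beta, b.beta)
    assert np.array_equal(a.W, b.W)
    assert np.array_equal(a.sigma2, b.sigma2)
    c = sample_posterior(toy_data, pri, n_samples=200, seed=43)
    assert not np.array_equal(a.beta, c.beta)


def test_prior_recovery_on_empty_data():
    """No data: beta_k draws ~ N(mu_k, sigma_beta^2), sigma^2 ~ IG(eta, eta)."""
    d = TrialData.empty(3)
    pri = HierPriors.default(3)
    draws = sample_posterior(d, pri, n_samples=5000, seed=7)
    thin = slice(None, None, 10)  # MH draws are autocorrelated
    for k in range(3):
        z = (draws.beta[thin, k] - pri.mu[k]) / np.sqrt(pri.sigma_beta2)
        assert stats.kstest(z, "norm").pvalue > 0.01
    # sigma^2 comes from the exact conjugate draw: IG(eta, eta) with n = 0
    assert stats.kstest(draws.sigma2, stats.invgamma(1, scale=1).cdf).pvalue > 0.01
    # PRIDE keeps alpha2 pinned at 1
    assert np.all(draws.alpha2 == 1.0)


def test_prior_recovery_alpha2_pride_fa():
    d = TrialData.empty(2)
    pri = HierPriors.default(2, sigma_alpha2=1.0)
    draws = sample_posterior(d, pri, scheme="pride_fa", n_samples=4000, seed=3)
    a = draws.alpha2[::10]
    assert stats.kstest((a - 1.0), "norm").pvalue > 0.01


def test_posterior_prob_matches_quadrature_oracle():
    """2-patient fixture: Pr(p_1 > phi) vs 3-D grid integration, sigma^2 fixed."""
    y = np.array([[0, 0], [1, 0]], dtype=np.int8)
    treated = np.array([[True, False], [True, False]])
    d = TrialData(y=y, treated=treated)
    pri = HierPriors(c=(0.2, 0.4))
    phi, s2 = 0.33, 1.0

    # quadrature over (beta1, W1, W2); dose 2 is untouched and integrates out
    b = np.linspace(-12, 8, 400)
    w = np.linspace(-6, 6, 120)
    B, W1, W2 = np.meshgrid(b, w, w, indexing="ij")
    lp1 = B + W1
    lp2 = B + W2
    loglik = (0 * lp1 - np.logaddexp(0, lp1)) + (lp2 - np.logaddexp(0, lp2))
    logpost = (
        loglik
        - (B - pri.mu[0]) ** 2 / (2 * pri.sigma_beta2)
        - W1**2 / (2 * s2)
        - W2**2 / (2 * s2)
    )
    post = np.exp(logpost - logpost.max())
    marg_b = post.sum(axis=(1, 2))
    oracle = marg_b[expit(b) > phi].sum() / marg_b.sum()

    model = IntraPatientToxicityModel(d, priors=pri)
    res = model.fit(n_samples=4000, seed=11, fixed_sigma2=s2)
    mcmc = res.prob_above(phi)[0]
    assert mcmc == pytest.approx(oracle, abs=0.03)


def test_parameter_recovery_200_patients():
    """Posterior means of expit(beta_k) within 0.05 of truth on average."""
    rng = np.random.default_rng(5)
    K = 5
    true_p = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    true_beta = logit(true_p)
    sigma2_true = 0.5
    n = 200
    y = np.zeros((n, K), dtype=np.int8)
    treated = np.zeros((n, K), dtype=bool)
    for i in range(n):
        Wi = rng.normal(0, np.sqrt(sigma2_true))
        doses = rng.choice(K, size=rng.integers(1, 4), replace=False)
        for k in doses:
            treated[i, k] = True
            y[i, k] = rng.random() < expit(true_beta[k] + Wi)
    d = TrialData(y=y, treated=treated)
    res = IntraPatientToxicityModel(d).fit(n_samples=2000, seed=1)
    est = res.dose_rates().mean(axis=0)
    assert np.mean(np.abs(est - true_p)) < 0.05


def test_pride_equals_pride_fa_without_down_retreats(rng):
    """Identical log posteriors when no Z=2 cells exist and alpha2 = 1."""
    d = random_trial_data(rng, n=4, K=3, with_z2=False)
    pri = HierPriors.default(3)
    beta = rng.normal(size=3)
    W = rng.normal(size=4)
    assert log_likelihood(d, beta, W, alpha2=1.0) == pytest.approx(
        log_likelihood(d, beta, W, alpha2=2.7), abs=1e-12
    )  # alpha2 enters only through Z=2 cells
    for k in range(3):
        f1 = log_cond_beta(k, d, W, 1.0, pri)
        f2 = log_cond_beta(k, d, W, 2.7, pri)
        assert f1(0.3) == pytest.approx(f2(0.3), abs=1e-12)


def test_posterior_dose_rates_identities():
    from pridetrial.model import PosteriorDraws

    c = np.array([0.1, 0.3, 0.5])
    beta = np.tile(logit(c), (4, 1))
    draws = PosteriorDraws(
        beta=beta, W=np.zeros((4, 2)), sigma2=np.ones(4), alpha2=np.ones(4)
    )
    rates = posterior_dose_rates(draws)
    assert np.allclose(rates, c)
    assert np.all(np.diff(rates, axis=1) >= 0)


def test_results_summary_and_ess(toy_data):
    res = IntraPatientToxicityModel(toy_data).fit(n_samples=300, seed=0)
    summ = res.summary()
    assert "p_1" in summ.index and "sigma2" in summ.index
    assert (summ.loc[[f"p_{k}" for k in (1, 2, 3)], "mean"] <= 1).all()
    ess = res.effective_sample_size()
    assert (ess > 0).all()
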