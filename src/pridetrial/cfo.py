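"""Calibration-free odds (CFO) decision engine.

The CFO design frames each dose-movement decision as a contest between the
current dose C and its neighbours L and R.  For each dose the odds of
over-toxicity are

    O_k = Pr(p_k > phi | data) / Pr(p_k <= phi | data),     Obar_k = 1 / O_k.

A large O_C / Obar_L favours de-escalating to L; a large Obar_C / O_R favours
escalating to R.  Each odds ratio is compared to a threshold (gamma_L resp.
gamma_R) and the two binary verdicts combine as:

    de-esc?  esc?   move
    yes      yes    stay
    yes      no     de-escalate
    no       yes    escalate
    no       no     stay

Also here: the threshold calibration by exhaustive beta-binomial enumeration,
the trial-level safety / dose-elimination rule, and final MTD selection via
isotonic regression (pool-adjacent-violators).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "OddsTriple",
    "GammaThresholds",
    "compute_odds",
    "odds_from_counts",
    "cfo_decide",
    "calibrate_gammas",
    "check_safety",
    "prob_toxic",
    "select_mtd",
]

DE_ESCALATE, STAY, ESCALATE = "de_escalate", "stay", "escalate"


@dataclass(frozen=True)
class OddsTriple:
    """Posterior over-toxicity odds at the left, current and right doses.

    ``O_L``/``O_R`` are None when the corresponding neighbour does not exist
    (current dose at a boundary).
    """

    O_L: float | None
    O_C: float
    O_R: float | None


@dataclass(frozen=True)
class GammaThresholds:
    """Decision thresholds for the two CFO odds-ratio comparisons."""

    gamma_L: float = 1.0
    gamma_R: float = 1.0

    def __post_init__(self):
        if self.gamma_L <= 0 or self.gamma_R <= 0:
            raise ValueError("gamma thresholds must be positive")


def _odds_from_fraction(frac_above: float, S: int) -> float:
    lo, hi = 1.0 / (S + 1), S / (S + 1.0)
    f = min(max(frac_above, lo), hi)
    return f / (1.0 - f)


def compute_odds(rate_samples: np.ndarray, current: int, phi: float) -> OddsTriple:
    """Odds of over-toxicity at the current dose and its neighbours.

    ``rate_samples`` is the (S, K) matrix of posterior DLT-rate draws;
    ``current`` is 0-based.  Empirical tail fractions of exactly 0 or 1 are
    clipped to [1/(S+1), S/(S+1)] before forming the odds.
    """
    rate_samples = np.asarray(rate_samples, dtype=float)
    S, K = rate_samples.shape
    if not 0 <= current < K:
        raise IndexError("current dose out of range")

    def odds_at(k: int) -> float:
        frac = float(np.mean(rate_samples[:, k] > phi))
        return _odds_from_fraction(frac, S)

    return OddsTriple(
        O_L=odds_at(current - 1) if current > 0 else None,
        O_C=odds_at(current),
        O_R=odds_at(current + 1) if current < K - 1 else None,
    )


def prob_toxic(y: int, n: int, phi: float) -> float:
    """Beta-binomial posterior Pr(p > phi) with a Beta(phi, 1-phi) prior."""
    return float(stats.beta.sf(phi, phi + y, 1.0 - phi + n - y))


def odds_from_counts(
    y_k: np.ndarray, n_k: np.ndarray, current: int, phi: float
) -> OddsTriple:
    """Exact beta-binomial odds for the standard (no-retreat) CFO baseline.

    Uses the conjugate Beta(phi, 1-phi) prior at each dose independently; tail
    probabilities are clipped as in :func:`compute_odds` with a nominal
    S = 2000.
    """
    K = len(n_k)

    def odds_at(k: int) -> float:
        return _odds_from_fraction(prob_toxic(int(y_k[k]), int(n_k[k]), phi), 2000)

    return OddsTriple(
        O_L=odds_at(current - 1) if current > 0 else None,
        O_C=odds_at(current),
        O_R=odds_at(current + 1) if current < K - 1 else None,
    )


def cfo_decide(odds: OddsTriple, gammas: GammaThresholds) -> str:
    """Apply the CFO decision table; a missing neighbour's condition is 'no'."""
    deesc = odds.O_L is not None and odds.O_C * odds.O_L > gammas.gamma_L
    esc = odds.O_R is not None and 1.0 / (odds.O_C * odds.O_R) > gammas.gamma_R
    if deesc and not esc:
        return DE_ESCALATE
    if esc and not deesc:
        return ESCALATE
    return STAY


# ----------------------------------------------------------------------
# threshold calibration
# ----------------------------------------------------------------------
def _log_odds_ratio_deesc(y_L, n_L, y_C, n_C, phi):
    # statistic O_C / Obar_L = O_C * O_L on the log scale
    oC = _odds_from_fraction(prob_toxic(y_C, n_C, phi), 2000)
    oL = _odds_from_fraction(prob_toxic(y_L, n_L, phi), 2000)
    return np.log(oC) + np.log(oL)


@lru_cache(maxsize=4096)
def _calibrate_pair(n_lo: int, n_hi: int, phi: float, delta: float) -> float:
    """Threshold for one pairwise comparison (lower dose vs higher dose).

    Enumerates every (y_lo, y_hi) outcome pair and picks the threshold on the
    statistic O_hi * O_lo (log scale) minimising type-I + type-II error under
    the two simple alternatives:

      move-down appropriate:  (p_lo, p_hi) = (phi, phi + delta)
      move-down inappropriate:(p_lo, p_hi) = (phi - delta, phi)

    Returns the optimal cutoff on the product-statistic scale O_hi * O_lo;
    the escalation comparison uses its reciprocal (the decision statistic
    Obar_C / O_R is the reciprocal of the product).
    """
    if n_lo < 1 and n_hi < 1:
        return 1.0
    y_lo = np.arange(n_lo + 1)
    y_hi = np.arange(n_hi + 1)
    stat = np.array(
        [
            [_log_odds_ratio_deesc(yl, n_lo, yh, n_hi, phi) for yh in y_hi]
            for yl in y_lo
        ]
    )
    p_hi_null = min(phi + delta, 0.99)
    p_lo_alt = max(phi - delta, 0.01)
    # joint pmfs over the grid
    pm_down = np.outer(stats.binom.pmf(y_lo, n_lo, phi), stats.binom.pmf(y_hi, n_hi, p_hi_null))
    pm_stay = np.outer(stats.binom.pmf(y_lo, n_lo, p_lo_alt), stats.binom.pmf(y_hi, n_hi, phi))
    flat = stat.ravel()
    order = np.argsort(flat)
    cand = np.concatenate(([flat[order[0]] - 1.0], (flat[order][:-1] + flat[order][1:]) / 2.0, [flat[order[-1]] + 1.0]))
    best_err, best_g = np.inf, 0.0
    for g in cand:
        deesc = flat > g
        err = pm_down.ravel()[~deesc].sum() + pm_stay.ravel()[deesc].sum()
        if err < best_err:
            best_err, best_g = err, g
    return float(np.exp(best_g))


def calibrate_gammas(
    n_L: int, n_C: int, n_R: int, phi: float, delta: float = 0.1
) -> GammaThresholds:
    """Calibrate (gamma_L, gamma_R) for the current sample-size configuration.

    Each threshold minimises the total probability of an incorrect move under
    the two simple hypotheses p = phi vs p = phi +/- delta with beta-binomial
    evidence (Beta(phi, 1-phi) priors).  A side with zero observations
    contributes its prior odds (a constant), so the enumeration still applies
    at the escalation frontier; only a comparison with no data on both sides
    falls back to a threshold of 1.  Deterministic and cached.
    """
    g_L = _calibrate_pair(int(n_L), int(n_C), float(phi), float(delta))
    g_R = _calibrate_pair(int(n_C), int(n_R), float(phi), float(delta))
    # escalation tests Obar_C/O_R = 1/(O_C*O_R) > gamma_R, so invert the cutoff
    return GammaThresholds(gamma_L=g_L, gamma_R=1.0 / g_R)


# ----------------------------------------------------------------------
# safety and MTD selection
# ----------------------------------------------------------------------
def check_safety(y1: int, n1: int, phi: float, cutoff: float = 0.95) -> str:
    """Trial-level safety check at a dose: 'terminate' iff Pr(p > phi) > cutoff.

    Uses the beta-binomial posterior with a Beta(phi, 1-phi) prior; with no
    observations the trial continues.  Applied to the lowest dose it is the
    early-termination rule; applied to any dose it is the elimination rule
    (the dose and all higher ones are dropped).
    """
    if not 0 <= y1 <= n1:
        raise ValueError("need 0 <= y1 <= n1")
    if n1 == 0:
        return "continue"
    return "terminate" if prob_toxic(y1, n1, phi) > cutoff else "continue"


def select_mtd(
    y_k: np.ndarray,
    n_k: np.ndarray,
    phi: float,
    eliminated: set[int] | frozenset[int] = frozenset(),
) -> int | None:
    """Final MTD: isotonic (PAVA) estimates closest to the target rate.

    Pool-adjacent-violators regression of the raw rates y_k/n_k with weights
    n_k over tested doses; untested and eliminated doses are excluded from
    selection.  Ties in |estimate - phi| break toward the lower dose when the
    tied estimate exceeds phi (safety) and toward the higher dose otherwise.
    Returns the 0-based dose index, or None if no dose is selectable.
    """
    y_k = np.asarray(y_k, dtype=float)
    n_k = np.asarray(n_k, dtype=float)
    tested = n_k > 0
    candidates = [k for k in range(len(n_k)) if tested[k] and k not in eliminated]
    if not candidates:
        return None
    idx = np.nonzero(tested)[0]
    rates = y_k[idx] / n_k[idx]
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(idx.astype(float), rates, sample_weight=n_k[idx])
    est = dict(zip(idx.tolist(), fitted.tolist()))
    dist = {k: abs(est[k] - phi) for k in candidates}
    dmin = min(dist.values())
    eps = 1e-12
    tied = sorted(k for k in candidates if abs(dist[k] - dmin) < eps)
    if len(tied) == 1:
        return tied[0]
    at = [k for k in tied if abs(est[k] - phi) <= eps]
    if at:  # exact hits on the target: lowest such dose
        return at[0]
    below = [k for k in tied if est[k] < phi]
    above = [k for k in tied if est[k] > phi]
    if below and not above:
        return below[-1]  # all under target: efficacy, take the highest
    if above and not below:
        return above[0]  # all over target: safety, take the lowest
    return below[-1]  # straddle: prefer the under-target side
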