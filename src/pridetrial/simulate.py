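"""Discrete-event simulation of an intra-patient dose-escalation trial.

The event loop mirrors the conduct of a phase I trial on a weekly clock:
patients arrive every ``interarrival_weeks``; a cohort starts treatment
simultaneously once all members are available; its DLT assessment closes
``assessment_weeks`` later; at that decision epoch the design's model is
refitted, dose-elimination and early-stopping rules fire, the dose for the
next cohort is chosen, and the scheduler fills the next cohort's slots
(untreated enrollees first, then retreatment candidates by longest washout,
then new enrollment).  The trial stops when the effective sample size (total
treatment cycles) reaches its cap, when any dose accrues the per-dose cap (if
enabled), or when the lowest dose is deemed overly toxic; the MTD is then
chosen by isotonic regression over the pooled per-dose counts.

One uniform deviate is pre-drawn per (patient, cycle) and consumed in
assignment order, so schemes that differ only in allocation see a common
outcome stream — paired comparisons (e.g. sample-size reduction against the
standard CFO baseline) run on matched randomness by sharing the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import cfo as cfo_engine
from .cfo import DE_ESCALATE, ESCALATE
from .data import TrialData
from .designs import CrmRandomEffectsModel, boin_boundaries, boin_decide
from .model import HierPriors, IntraPatientToxicityModel
from .scenarios import Scenario
from .scheduler import Cycle, PatientRecord, form_cohort

__all__ = ["DesignConfig", "TrialResult", "simulate_outcome", "run_trial", "run_operating_characteristics"]

SCHEMES = ("pride", "pride_fa", "aide", "ipde", "cfo_standard")
ENGINES = ("cfo", "boin", "crm")


@dataclass(frozen=True)
class DesignConfig:
    """Trial design settings (defaults follow the simulation-study setup)."""

    phi: float = 0.33
    n_doses: int = 5
    max_effective: int = 24
    per_dose_cap: int | None = 12  # None disables the per-dose stopping rule
    cohort_size: int = 3
    start_dose: int = 1  # 1-based
    elimination_cutoff: float = 0.95
    stop_cutoff: float = 0.95
    assessment_weeks: int = 3
    interarrival_weeks: int = 2
    max_cycles: int = 3
    scheme: str = "pride"
    engine: str = "cfo"
    n_posterior: int = 2000
    min_washout_weeks: float = 0.0
    correlated_outcomes: bool = False
    sigma2_true: float = 1.0
    marginalize_rates: bool = False

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.engine not in ENGINES:
            raise ValueError(f"engine must be one of {ENGINES}")
        if not 0 < self.phi < 1:
            raise ValueError("phi must be in (0,1)")
        for name in ("n_doses", "max_effective", "cohort_size", "start_dose", "max_cycles"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        return cls(**d)


@dataclass
class TrialResult:
    """Outcome of one simulated trial."""

    selected_dose: int | None  # 0-based
    effective_per_dose: np.ndarray  # raw treatment-cycle counts per dose
    dlt_per_dose: np.ndarray
    patient_max_dose: tuple  # highest dose (0-based) per distinct treated patient
    distinct_patients: int
    effective_patients: int
    duration_weeks: float
    dlt_count: int
    terminated_early: bool
    decision_trace: list = field(default_factory=list)
    ledger: "pd.DataFrame | None" = None  # per-cycle patient ledger (opt-in)

    @property
    def highest_dose_counts(self) -> np.ndarray:
        """Distinct-patient counts per dose under the highest-dose-matter rule."""
        out = np.zeros(len(self.effective_per_dose), dtype=int)
        for d in self.patient_max_dose:
            out[d] += 1
        return out


# ----------------------------------------------------------------------
def simulate_outcome(true_probs, patient_effect, dose: int, rng) -> int:
    """One Bernoulli DLT draw for a patient at a dose.

    With ``patient_effect`` None the marginal probability ``true_probs[dose]``
    is used; otherwise the draw is correlated within patient via
    expit(logit(p) + W_i).
    """
    return _outcome_from_uniform(true_probs[dose], patient_effect, float(rng.random()))


def _outcome_from_uniform(p: float, w: float | None, u: float) -> int:
    if w is not None and 0.0 < p < 1.0:
        p = float(expit(logit(p) + w))
    return int(u < p)


# ----------------------------------------------------------------------
def _trial_data_from_pool(pool: list[PatientRecord], K: int) -> TrialData:
    treated_patients = [p for p in pool if p.treated]
    n = len(treated_patients)
    y = np.zeros((n, K), dtype=np.int8)
    treated = np.zeros((n, K), dtype=bool)
    z = np.zeros((n, K), dtype=np.int8)
    for row, p in enumerate(treated_patients):
        for c in p.history:
            if c.outcome is None:
                continue
            treated[row, c.dose] = True
            y[row, c.dose] = c.outcome
            z[row, c.dose] = c.z
    return TrialData(y=y, treated=treated, assign_type=z)


def _decide_next_dose(
    config: DesignConfig,
    priors: HierPriors,
    data: TrialData,
    current: int,
    highest_allowed: int,
    fit_seed: int,
) -> tuple[int, dict]:
    """Refit the scheme's model and apply the engine's rule; returns (dose, trace)."""
    y_k, n_k = data.y_k, data.n_k
    phi = config.phi
    trace: dict = dict(current_dose=current + 1)

    needs_fit = not (config.scheme == "cfo_standard" and config.engine != "crm")
    rates = None
    if needs_fit:
        model = IntraPatientToxicityModel(
            data,
            priors=priors,
            scheme="pride_fa" if config.scheme == "pride_fa" else "pride",
            random_effects=config.scheme in ("pride", "pride_fa"),
        )
        if config.engine != "crm":
            res = model.fit(n_samples=config.n_posterior, seed=fit_seed)
            rates = res.dose_rates(marginalize=config.marginalize_rates)

    if config.engine == "cfo":
        if rates is None:
            odds = cfo_engine.odds_from_counts(y_k, n_k, current, phi)
        else:
            odds = cfo_engine.compute_odds(rates, current, phi)
        n_L = int(n_k[current - 1]) if current > 0 else 0
        n_R = int(n_k[current + 1]) if current < config.n_doses - 1 else 0
        gammas = cfo_engine.calibrate_gammas(n_L, int(n_k[current]), n_R, phi)
        move = cfo_engine.cfo_decide(odds, gammas)
        trace.update(
            O_L=odds.O_L, O_C=odds.O_C, O_R=odds.O_R,
            gamma_L=gammas.gamma_L, gamma_R=gammas.gamma_R, move=move,
        )
        nxt = current + (move == ESCALATE) - (move == DE_ESCALATE)
    elif config.engine == "boin":
        bounds = boin_boundaries(phi)
        if rates is None:
            est = y_k[current] / n_k[current] if n_k[current] > 0 else 0.0
        else:
            est = float(rates[:, current].mean())
        move = boin_decide(float(est), bounds)
        trace.update(rate_estimate=float(est), move=move)
        nxt = current + (move == ESCALATE) - (move == DE_ESCALATE)
    else:  # crm
        skeleton = np.asarray(priors.c, dtype=float)
        crm = CrmRandomEffectsModel(
            data, skeleton, random_effects=config.scheme in ("pride", "pride_fa")
        )
        res = crm.fit(n_samples=config.n_posterior, seed=fit_seed)
        target = res.select_dose(phi)
        trace.update(crm_selection=target + 1, move="model")
        nxt = int(np.clip(target, current - 1, current + 1))

    return int(np.clip(nxt, 0, highest_allowed)), trace


def run_trial(
    scenario: Scenario,
    config: DesignConfig,
    priors: HierPriors | None = None,
    seed: int = 0,
    keep_ledger: bool = False,
) -> TrialResult:
    """Simulate one complete trial; deterministic for a fixed seed.

    ``keep_ledger=True`` attaches the per-cycle patient ledger (a DataFrame)
    to the result for inspection/export.
    """
    if scenario.n_doses != config.n_doses:
        raise ValueError("scenario and config disagree on the number of doses")
    priors = priors or HierPriors.default(config.n_doses)
    K = config.n_doses
    probs = np.asarray(scenario.probs, dtype=float)

    rng = np.random.default_rng(seed)
    max_pat = config.max_effective * config.cohort_size + 8
    U = rng.random((max_pat, config.max_cycles))
    W_true = (
        rng.standard_normal(max_pat) * np.sqrt(config.sigma2_true)
        if config.correlated_outcomes
        else None
    )
    fit_seeds = rng.integers(0, 2**31 - 1, size=4 * config.max_effective)

    pool: list[PatientRecord] = []

    def enroll_next() -> PatientRecord:
        j = len(pool)
        p = PatientRecord(id=j, arrival_week=j * config.interarrival_weeks)
        pool.append(p)
        return p

    def materialize_arrivals(upto_week: float) -> None:
        # accrual is continuous: everyone whose arrival time has passed is enrolled
        while len(pool) * config.interarrival_weeks <= upto_week:
            enroll_next()

    highest_allowed = K - 1
    current = config.start_dose - 1
    effective = 0
    week = 0.0
    terminated = False
    trace_all: list[dict] = []
    n_fits = 0

    while True:
        # ---- form and treat the next cohort --------------------------------
        materialize_arrivals(week)
        assignments = form_cohort(
            current, pool, week, config.cohort_size, config.scheme,
            highest_allowed=highest_allowed, min_washout_weeks=config.min_washout_weeks,
        )
        while len(assignments) < config.cohort_size:
            assignments.append((enroll_next(), current, 1))
        start = max([week] + [p.arrival_week for p, _, _ in assignments])
        end = start + config.assessment_weeks
        for p, dose, z in assignments:
            cyc = len(p.history)
            w_i = None if W_true is None else float(W_true[p.id])
            outcome = _outcome_from_uniform(probs[dose], w_i, float(U[p.id, cyc]))
            if any(c.dose == dose for c in p.history):
                raise RuntimeError("patient assigned twice to the same dose")
            p.history.append(Cycle(dose=dose, start_week=start, end_week=end, outcome=outcome, z=z))
        effective += len(assignments)
        week = end

        # ---- decision epoch -------------------------------------------------
        data = _trial_data_from_pool(pool, K)
        y_k, n_k = data.y_k, data.n_k

        # dose elimination (upward-closed) and early termination
        for k in range(highest_allowed + 1):
            if n_k[k] >= 3 and cfo_engine.check_safety(
                int(y_k[k]), int(n_k[k]), config.phi, config.elimination_cutoff
            ) == "terminate":
                highest_allowed = k - 1
                break
        if highest_allowed < 0:
            terminated = True
            break

        if effective >= config.max_effective:
            break
        if config.per_dose_cap is not None and np.any(n_k >= config.per_dose_cap):
            break

        current = min(current, highest_allowed)
        nxt, trace = _decide_next_dose(
            config, priors, data, current, highest_allowed, int(fit_seeds[n_fits])
        )
        n_fits += 1
        trace["week"] = week
        trace["next_dose"] = nxt + 1
        trace_all.append(trace)
        current = nxt

    # ---- final selection ----------------------------------------------------
    data = _trial_data_from_pool(pool, K)
    eliminated = frozenset(range(highest_allowed + 1, K))
    selected = (
        None
        if terminated
        else cfo_engine.select_mtd(data.y_k, data.n_k, config.phi, eliminated)
    )
    treated_patients = [p for p in pool if p.treated]
    if keep_ledger:
        from .scheduler import pool_to_frame

        ledger = pool_to_frame(treated_patients)
    else:
        ledger = None
    return TrialResult(
        selected_dose=selected,
        effective_per_dose=data.n_k.astype(int),
        dlt_per_dose=data.y_k.astype(int),
        patient_max_dose=tuple(p.max_dose for p in treated_patients),
        distinct_patients=len(treated_patients),
        effective_patients=int(effective),
        duration_weeks=float(week),
        dlt_count=int(data.y_k.sum()),
        terminated_early=terminated,
        decision_trace=trace_all,
        ledger=ledger,
    )


# ----------------------------------------------------------------------
def run_operating_characteristics(
    scenarios: list[Scenario],
    config: DesignConfig,
    priors: HierPriors | None = None,
    n_reps: int = 100,
    base_seed: int = 0,
    baseline_config: DesignConfig | None = None,
) -> pd.DataFrame:
    """Replicate trials per scenario and summarise their operating characteristics.

    Replication ``r`` of every scenario uses seed ``base_seed + r`` so paired
    designs see matched outcome streams.  ``baseline_config`` (typically the
    standard no-retreat CFO) is run on the same seeds to support the
    sample-size-reduction metric.
    """
    from .metrics import aggregate

    rows = []
    for scenario in scenarios:
        results = [run_trial(scenario, config, priors, seed=base_seed + r) for r in range(n_reps)]
        baseline = None
        if baseline_config is not None:
            baseline = [
                run_trial(scenario, baseline_config, priors, seed=base_seed + r)
                for r in range(n_reps)
            ]
        oc = aggregate(results, scenario, baseline_results=baseline)
        row = oc.to_dict()
        row["scenario"] = scenario.label or str(scenario.probs)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("scenario")
    return df


def standard_cfo_config(config: DesignConfig) -> DesignConfig:
    """The matched no-retreat CFO baseline for a given design configuration."""
    return replace(config, scheme="cfo_standard", engine="cfo")
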