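# Methods

## Model

The toxicity model is a Bayesian hierarchical logistic regression on the
patient x dose grid. Patient *i* at dose *k* experiences a DLT with
probability `p_ik = expit(beta_k + alpha_{Z_ik} W_i)`. Observations exist
only where the treatment indicator is set; a patient contributes at most
three cells (one per treatment cycle, each at a distinct dose). The
conditional likelihood is the product of Bernoulli masses over treated
cells, so untreated cells contribute nothing and per-dose aggregates
`(y_k, n_k)` may sum to more cycles than there are patients.

Priors and their defaults:

| parameter | prior | default | role |
| --- | --- | --- | --- |
| `beta_k` | `N(logit c_k, sigma_beta^2)` | `c` equally spaced 0.1–0.5, `sigma_beta^2 = 10` | monotone-in-mean dose trend, weakly informative |
| `W_i` | `N(0, sigma^2)` | — | intra-patient correlation across cycles |
| `sigma^2` | `Inv-Gamma(eta, eta)` | `eta = 1` | conjugate variance; `eta = 1` is the conventional non-informative choice |
| `sigma` (alternative) | `Half-Cauchy(0, tau)` | `tau = 1` | heavier-tailed scale prior |
| `alpha_2` | `N(1, sigma_alpha^2)` | `sigma_alpha^2 = 1` | down-retreat rescaling (flexible allocation only); `alpha_1 = 1` fixed |

The monotonicity of the dose–toxicity curve is imposed through the ordered
prior means only; posterior draws of `expit(beta_k)` are not constrained, and
the final MTD selection applies isotonic regression to restore monotonicity
where the data violate it.

## Sampler

Metropolis–Hastings within Gibbs. Each `beta_k` and each `W_i` gets a
scalar Gaussian random-walk update (their full conditionals are
conditionally independent across `k` given `W`, and across `i` given
`beta`); `sigma^2` is drawn exactly from its conjugate
`Inv-Gamma(eta + n/2, eta + sum W_i^2/2)` conditional, or, under the
half-Cauchy prior, by a random-walk step on `log sigma` (positivity by
construction, Jacobian included); `alpha_2` gets a scalar random-walk step
over the down-retreated cells only. Initialisation is prior-centred
(`beta = mu`, `W = 0`, `sigma^2 = 1`, `alpha_2 = 1`). Proposal scales start
at 0.5 and adapt every 50 burn-in iterations toward a 30–45% acceptance
rate, then freeze, so the retained draws target the exact posterior.
Defaults are 2000 retained draws after an equal burn-in. The whole chain is
compiled with numba and is deterministic given the integer seed. Crude
effective-sample-size diagnostics are exposed on the results object but not
enforced; at the trial sizes involved (`K <= 7`, `n <= ~30`) plain Gibbs
mixes adequately, which the prior-recovery and quadrature tests check
directly.

Decision quantities use the reference-patient rate `p_k = expit(beta_k)`
(the median patient, `W = 0`) — the conventional population summary of a
logistic random-effects model. A population-averaged mode (Monte-Carlo
integration over `W ~ N(0, sigma^2)` per draw) is available via
`marginalize_rates` but is not the default: averaging inflates rates toward
0.5 at extreme doses, which distorts the odds comparisons at the top of the
dose ladder.

## CFO engine

Per-dose over-toxicity odds `O_k = Pr(p_k > phi)/Pr(p_k <= phi)` are
estimated from the posterior rate draws; tail fractions of exactly 0 or 1
are clipped to `[1/(S+1), S/(S+1)]` (a pseudo-count floor that avoids
division by zero). De-escalation fires when `O_C * O_L > gamma_L`,
escalation when `1/(O_C * O_R) > gamma_R`; both or neither means stay, and a
missing neighbour defaults its condition to "no". The standard (no-retreat)
CFO baseline computes the same odds in closed form from beta-binomial
posteriors with `Beta(phi, 1-phi)` priors.

Thresholds are calibrated per sample-size configuration by exhaustive
enumeration: for one pairwise comparison, every outcome pair `(y_lo, y_hi)`
is enumerated with binomial probabilities under two simple scenarios —
"move appropriate" `(p_lo, p_hi) = (phi, phi + delta)` and "move
inappropriate" `(phi - delta, phi)`, with `delta = 0.1` — and the cutoff on
the odds-product statistic minimising the summed error probabilities is
taken (`gamma_R` is the reciprocal cutoff, since escalation tests the
reciprocal statistic). A side with zero observations contributes its prior
odds as a constant, so the calibration still applies at the escalation
frontier; only a fully dataless comparison falls back to `gamma = 1`.
Thresholds are deterministic and cached.

Safety: a dose is eliminated (with all higher doses) once it has at least 3
observations and `Pr(p > phi | y, n) > 0.95` under the `Beta(phi, 1-phi)`
beta-binomial posterior; elimination of the lowest dose terminates the trial
with no MTD. The beta-binomial form is used here (not the hierarchical
posterior) because the rule is a deliberately simple, model-free guardrail on
the raw counts.

MTD selection: weighted PAVA (scikit-learn isotonic regression) of the raw
pooled rates `y_k/n_k` over tested doses; the non-eliminated tested dose with
isotonic estimate closest to `phi` wins. Ties: an exact hit at `phi` takes
the lowest such dose; an all-above-target tie takes the lowest dose
(safety); an all-below tie takes the highest (efficacy); a straddling tie
takes the under-target side.

## BOIN and CRM plug-ins

BOIN uses the closed-form optimal interval boundaries with the conventional
alternatives `(0.6 phi, 1.4 phi)`; the retreatment variant replaces the raw
rate `y_k/n_k` with the hierarchical posterior mean (posterior median is
exposed as an option). Escalation is boundary-inclusive
(`estimate <= lambda_e`), de-escalation strict (`> lambda_d`).

The CRM variant fits `logit p_ik = beta_0 + beta_1 d_k + W_i` with effective
doses `d_k = logit(skeleton_k)` (the standard backsolve at prior means
`beta_0 = 0, beta_1 = 1`), priors `beta_0 ~ N(0, 4)`,
`log beta_1 ~ N(0, 1)` (monotonicity via `beta_1 > 0` by construction), and
the same `W`/`sigma^2` structure. The next dose is the one whose posterior
mean rate is closest to the target, restricted to one level of movement per
decision.

## Scheduler and simulator

Patients arrive every 2 weeks on a fixed accrual stream and are enrolled on
arrival. A cohort (default 3) starts treatment simultaneously once all
members are available; its DLT assessment closes 3 weeks later, at which
point the model is refitted on all completed cycles, elimination/stopping
rules fire, the engine picks the next dose, and the next cohort is formed:
enrolled-but-untreated patients first, then eligible retreatment candidates
ordered by longest elapsed time since last treatment end (ties to the
smaller id — earlier enrollment), then new enrollment (the cohort waits for
arrivals if necessary). Retreatment eligibility: DLT-free, fewer than 3
completed cycles, no pending assessment. Scheme-specific dose rules: PRIDE
and the AIDE baseline allow retreatment only strictly above the patient's
previous maximum; PRIDE-FA allows any dose not previously received (a dose
below the patient's maximum is a down-retreat, assignment type Z = 2); IPDE
auto-escalates each retreated patient one level above their own maximum
regardless of the trial's movement. The AIDE/IPDE baselines are simplified
re-implementations of the cited strategies: they share the machinery but
clamp `W = 0` (no correlation modelling), which is the distinction the
comparison is about. A minimum-washout gate is configurable and defaults to
0 weeks: the scheduling rule in force is a pure preference ordering that
maximises washout, matching the worked trial timeline in which a patient can
be retreated at the week their assessment closes.

Trials stop when assigned effective patients (treatment cycles) reach the
cap (default 24), when any dose accrues the per-dose cap (default 12,
disablable), or on lowest-dose elimination. Duration is the week the final
assessment window closes. One uniform deviate per (patient, cycle) is
pre-drawn from the trial seed and consumed in assignment order, so designs
differing only in allocation can be compared on a common outcome stream
(matched seeds give paired comparisons for the sample-size-reduction
metric). Outcomes are independent Bernoulli draws from the scenario's
marginal probabilities by default; a correlated mode draws a true patient
effect and tilts the probabilities on the logit scale, for studying
robustness when intra-patient correlation is real.

## Scenarios

The two embedded benchmark sets (six five-dose scenarios at target 0.33,
eight seven-dose scenarios at target 0.20) are stored verbatim, with the
true MTD marked where a dose sits exactly at the target (one scenario per
set has none). The random generator pins the MTD (uniform position) at the
target and grows neighbours outward with truncated-exponential increments
(Exp(1) truncated at 3, rescaled so the post-truncation mean equals the
requested APDT — the average probability difference around the target),
clipped to (0.001, 0.999). APDT is calibrated on the two immediate
neighbours of the MTD, averaged where both exist; Monte-Carlo tests verify
the calibration. Clipping can flatten the extreme ends of a scenario at the
probability floor/ceiling, so exact APDT calibration holds when the target
is not too close to 0 or 1 relative to the requested difference.

## Metrics

Selection percentages are computed over replications (reps selecting no dose
are reported separately and excluded from over/under-dose selection).
Allocation percentages use highest-dose-matter counting — each distinct
patient counts once, at the highest dose received — pooled over
replications; the per-dose tables also report raw effective (cycle) counts,
since both views are informative and they differ exactly where retreatment
is active. Sample-size reduction is
`100 (n_base - n_scheme)/n_base` on mean distinct patients against the
matched-seed standard-CFO baseline — distinct patients, because recruiting
fewer humans is the quantity retreatment is designed to reduce. Monte-Carlo
standard errors accompany the percentages.

## Problem sizes and what the checks show

The acceptance script runs 200 replications per fixed-scenario target (100
paired per scenario for the reduction metric) with 2000 retained posterior
draws per interim decision — the package's reduced-replication rendition of
a 5000-replication study; binomial standard errors at 200 reps are about
3.5 percentage points. The synthetic outcome streams emulate only what the
scenarios state (marginal monotone toxicity probabilities, fixed accrual,
binary DLT within a fixed window): passing tests demonstrate correctness of
the machinery and reproduction of operating characteristics under those
idealised conditions, not performance under real-world accrual variation,
late-onset or graded toxicity, or patient dropout, none of which are
modelled.

## Known limitations

* The AIDE/IPDE baselines follow the comparison descriptions, not the full
  source algorithms.
* The CFO thresholds come from this package's own enumeration criterion;
  published threshold tables for the CFO family are not reproduced, and
  operating characteristics are sensitive to these within a few percentage
  points.
* Isotonic selection operates on pooled raw counts; with very sparse dose
  exploration the tie-break conventions matter.
* Weekly time granularity; no dropout; accrual is deterministic.
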