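"""Patient pool management: retreatment eligibility and cohort formation.

A patient may be treated for up to three cycles, each at a distinct dose
level, and only while DLT-free.  When a new cohort is formed at the dose the
design chose, slots are filled in priority order: (1) enrolled patients not
yet treated, (2) eligible retreatment candidates with the longest elapsed time
since their last treatment (maximising washout), (3) newly enrolled patients.

The schemes differ in where a retreated patient may go:

* PRIDE / AIDE — only strictly above every dose the patient has received;
* PRIDE-FA    — any dose the patient has not received (down-retreats get
  assignment type Z=2);
* IPDE        — the patient's own next-higher dose, regardless of the dose
  the trial itself moves to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["Cycle", "PatientRecord", "eligible_for_retreat", "allowed_doses", "form_cohort"]

MAX_CYCLES = 3

UP_SCHEMES = ("pride", "aide")


@dataclass
class Cycle:
    """One treatment cycle: dose (0-based), timing, outcome, assignment type."""

    dose: int
    start_week: float
    end_week: float
    outcome: int | None = None  # None while the assessment is pending
    z: int = 1


@dataclass
class PatientRecord:
    """One enrolled subject and their treatment history."""

    id: int
    arrival_week: float
    history: list[Cycle] = field(default_factory=list)

    @property
    def doses(self) -> set[int]:
        return {c.dose for c in self.history}

    @property
    def max_dose(self) -> int:
        return max((c.dose for c in self.history), default=-1)

    @property
    def has_dlt(self) -> bool:
        return any(c.outcome == 1 for c in self.history)

    @property
    def pending(self) -> bool:
        return any(c.outcome is None for c in self.history)

    @property
    def completed_cycles(self) -> int:
        return sum(1 for c in self.history if c.outcome is not None)

    @property
    def treated(self) -> bool:
        return bool(self.history)

    @property
    def last_treatment_end(self) -> float:
        return max(c.end_week for c in self.history)

    @property
    def status(self) -> str:
        if not self.history:
            return "untreated"
        if self.pending:
            return "in_assessment"
        if self.has_dlt or self.completed_cycles >= MAX_CYCLES:
            return "retired"
        return "eligible_retreat"


def eligible_for_retreat(p: PatientRecord, scheme: str = "pride") -> bool:
    """DLT-free, fewer than three completed cycles, no pending assessment."""
    return p.treated and p.status == "eligible_retreat"


def allowed_doses(p: PatientRecord, next_dose: int, scheme: str) -> set[int]:
    """Doses this patient may receive when the trial moves to ``next_dose``.

    Returns a (possibly empty) set of 0-based dose indices.  Under IPDE the
    answer ignores ``next_dose`` entirely: the patient auto-escalates one
    level above their own maximum.
    """
    if scheme in UP_SCHEMES:
        return {next_dose} if next_dose > p.max_dose else set()
    if scheme == "pride_fa":
        return {next_dose} if next_dose not in p.doses else set()
    if scheme == "ipde":
        return {p.max_dose + 1}
    if scheme == "cfo_standard":
        return set()  # no retreatment at all
    raise ValueError(f"unknown scheme {scheme!r}")


def form_cohort(
    next_dose: int,
    pool: list[PatientRecord],
    week: float,
    cohort_size: int,
    scheme: str,
    highest_allowed: int | None = None,
    min_washout_weeks: float = 0.0,
) -> list[tuple[PatientRecord, int, int]]:
    """Fill cohort slots from the existing pool; shortfall is left to enrollment.

    Returns up to ``cohort_size`` assignments ``(patient, dose, z)``:

    1. enrolled-but-untreated patients (by arrival, then id) at ``next_dose``;
    2. eligible retreatment candidates whose scheme-allowed dose is usable,
       ordered by longest elapsed time since last treatment end (ties by
       smaller id), subject to the optional minimum washout;
    3. remaining slots are NOT filled here — the simulator enrolls new
       patients for them.

    ``highest_allowed`` caps assignable doses (highest non-eliminated level).
    """
    assignments: list[tuple[PatientRecord, int, int]] = []
    cap = highest_allowed if highest_allowed is not None else next_dose

    untreated = sorted(
        (p for p in pool if not p.treated and p.arrival_week <= week),
        key=lambda p: (p.arrival_week, p.id),
    )
    for p in untreated:
        if len(assignments) >= cohort_size:
            return assignments
        assignments.append((p, next_dose, 1))

    retreat = sorted(
        (p for p in pool if eligible_for_retreat(p, scheme)),
        key=lambda p: (-(week - p.last_treatment_end), p.id),
    )
    for p in retreat:
        if len(assignments) >= cohort_size:
            break
        if week - p.last_treatment_end < min_washout_weeks:
            continue
        allowed = {d for d in allowed_doses(p, next_dose, scheme) if 0 <= d <= cap}
        if not allowed:
            continue
        dose = min(allowed)
        z = 2 if (scheme == "pride_fa" and dose < p.max_dose) else 1
        assignments.append((p, dose, z))
    return assignments


def pool_to_frame(pool: list[PatientRecord]) -> pd.DataFrame:
    """Patient ledger: one row per treatment cycle."""
    rows = []
    for p in pool:
        for j, c in enumerate(p.history, start=1):
            rows.append(
                dict(
                    patient_id=p.id,
                    arrival_week=p.arrival_week,
                    cycle=j,
                    dose_level=c.dose + 1,
                    start_week=c.start_week,
                    end_week=c.end_week,
                    outcome=c.outcome,
                    assign_type=c.z,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "arrival_week",
            "cycle",
            "dose_level",
            "start_week",
            "end_week",
            "outcome",
            "assign_type",
        ],
    )
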