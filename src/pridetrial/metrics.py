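"""Operating characteristics of simulated trials.

Accuracy (MTD selection / allocation), safety (overdose selection /
allocation), and efficiency (sample-size reduction vs a matched baseline,
trial duration).  Patient allocation follows the highest-dose-matter
principle: a patient treated at several levels is counted once, at the
highest level received — so a patient who passed through the MTD on the way
to an overdose counts toward overdose allocation only.  The per-dose
parenthetical averages reported alongside selection percentages are raw
effective (per-cycle) counts, which is why both countings are emitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scenarios import Scenario
from .simulate import TrialResult

__all__ = ["OperatingCharacteristics", "patient_counting", "aggregate"]


def patient_counting(result: TrialResult) -> np.ndarray:
    """Distinct-patient counts per dose under the highest-dose-matter rule."""
    return result.highest_dose_counts


def _pct_se(p_pct: float, n: int) -> float:
    p = p_pct / 100.0
    return 100.0 * float(np.sqrt(p * (1 - p) / n)) if n > 0 else np.nan


@dataclass
class OperatingCharacteristics:
    """Summary metrics over a set of replicated trials (percentages in [0,100])."""

    n_reps: int
    mtd_selection_pct: float
    overdose_selection_pct: float
    underdose_selection_pct: float
    none_selected_pct: float
    selection_per_dose_pct: np.ndarray
    mtd_allocation_pct: float
    overdose_allocation_pct: float
    mean_patients_per_dose: np.ndarray  # raw effective (per-cycle) counts
    mean_distinct_patients: float
    mean_effective_patients: float
    mean_duration_weeks: float
    sample_size_reduction_pct: float | None
    mtd_selection_se: float
    overdose_selection_se: float
    duration_se: float

    def to_dict(self) -> dict:
        d = {
            "n_reps": self.n_reps,
            "mtd_selection_pct": self.mtd_selection_pct,
            "overdose_selection_pct": self.overdose_selection_pct,
            "underdose_selection_pct": self.underdose_selection_pct,
            "none_selected_pct": self.none_selected_pct,
            "mtd_allocation_pct": self.mtd_allocation_pct,
            "overdose_allocation_pct": self.overdose_allocation_pct,
            "mean_distinct_patients": self.mean_distinct_patients,
            "mean_effective_patients": self.mean_effective_patients,
            "mean_duration_weeks": self.mean_duration_weeks,
            "sample_size_reduction_pct": self.sample_size_reduction_pct,
            "mtd_selection_se": self.mtd_selection_se,
        }
        for k, v in enumerate(self.selection_per_dose_pct):
            d[f"select_dose_{k+1}_pct"] = v
        for k, v in enumerate(self.mean_patients_per_dose):
            d[f"patients_dose_{k+1}"] = v
        return d


def aggregate(
    results: list[TrialResult],
    scenario: Scenario,
    baseline_results: list[TrialResult] | None = None,
) -> OperatingCharacteristics:
    """Pool replicated trial results into operating characteristics.

    ``baseline_results`` (matched-seed standard-design runs) enable the
    sample-size-reduction metric 100*(n_base - n_scheme)/n_base on mean
    distinct patients; without them the metric is reported as None.
    Replications selecting no dose count toward ``none_selected_pct`` and are
    excluded from over/underdose selection.
    """
    R = len(results)
    if R == 0:
        raise ValueError("no results to aggregate")
    K = len(results[0].effective_per_dose)
    mtd = scenario.mtd_index

    sel = np.array([-1 if r.selected_dose is None else r.selected_dose for r in results])
    sel_per_dose = np.array([100.0 * np.mean(sel == k) for k in range(K)])
    none_pct = 100.0 * float(np.mean(sel < 0))
    if mtd is not None:
        mtd_sel = 100.0 * float(np.mean(sel == mtd))
        over_sel = 100.0 * float(np.mean(sel > mtd))
        under_sel = 100.0 * float(np.mean((sel >= 0) & (sel < mtd)))
    else:
        mtd_sel = np.nan
        over_sel = 100.0 * float(np.mean(sel >= 0))  # any selection is an overdose
        under_sel = 0.0

    # allocation: highest-dose-matter distinct counts pooled over reps
    alloc = np.sum([patient_counting(r) for r in results], axis=0).astype(float)
    total_distinct = alloc.sum()
    if mtd is not None and total_distinct > 0:
        mtd_alloc = 100.0 * alloc[mtd] / total_distinct
        over_alloc = 100.0 * alloc[mtd + 1 :].sum() / total_distinct
    elif total_distinct > 0:
        mtd_alloc = np.nan
        over_alloc = 100.0
    else:
        mtd_alloc = over_alloc = np.nan

    mean_per_dose = np.mean([r.effective_per_dose for r in results], axis=0)
    mean_distinct = float(np.mean([r.distinct_patients for r in results]))
    mean_effective = float(np.mean([r.effective_patients for r in results]))
    durations = np.array([r.duration_weeks for r in results])

    reduction = None
    if baseline_results is not None:
        base = float(np.mean([r.distinct_patients for r in baseline_results]))
        if base > 0:
            reduction = 100.0 * (base - mean_distinct) / base

    return OperatingCharacteristics(
        n_reps=R,
        mtd_selection_pct=mtd_sel,
        overdose_selection_pct=over_sel,
        underdose_selection_pct=under_sel,
        none_selected_pct=none_pct,
        selection_per_dose_pct=sel_per_dose,
        mtd_allocation_pct=mtd_alloc,
        overdose_allocation_pct=over_alloc,
        mean_patients_per_dose=mean_per_dose,
        mean_distinct_patients=mean_distinct,
        mean_effective_patients=mean_effective,
        mean_duration_weeks=float(durations.mean()),
        sample_size_reduction_pct=reduction,
        mtd_selection_se=_pct_se(mtd_sel, R) if mtd is not None else np.nan,
        overdose_selection_se=_pct_se(over_sel, R),
        duration_se=float(durations.std(ddof=1) / np.sqrt(R)) if R > 1 else np.nan,
    )
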