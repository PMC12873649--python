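"""Trial data container for intra-patient dose-escalation designs.

A phase I trial under patient retreatment produces a sparse patient x dose
matrix of binary dose-limiting-toxicity (DLT) outcomes: patient ``i`` may be
treated at up to three distinct dose levels, contributing one observation per
level.  :class:`TrialData` stores the outcome matrix ``y``, the treatment
indicator matrix (which cells were observed), and the assignment-type matrix
``Z`` distinguishing new/up-retreated assignments (Z=1) from down-retreated
assignments (Z=2, flexible-allocation scheme only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrialData"]

MAX_CYCLES = 3


@dataclass
class TrialData:
    """Patient x dose observation matrix of DLT outcomes.

    Parameters
    ----------
    y : ndarray of shape (n_patients, n_doses)
        Binary DLT outcomes; only cells with ``treated == True`` are
        meaningful.
    treated : ndarray of bool, shape (n_patients, n_doses)
        Observation indicator ``I_ik`` — True where patient ``i`` was treated
        at dose ``k``.
    assign_type : ndarray of int, shape (n_patients, n_doses), optional
        ``Z_ik`` in {1, 2}: 1 for newly enrolled / up-retreated, 2 for
        down-retreated.  0 marks untreated cells.  Defaults to 1 wherever
        treated.
    """

    y: np.ndarray
    treated: np.ndarray
    assign_type: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        self.treated = np.asarray(self.treated, dtype=bool)
        if self.y.shape != self.treated.shape:
            raise ValueError(
                f"y shape {self.y.shape} != treated shape {self.treated.shape}"
            )
        if self.y.ndim != 2:
            raise ValueError("y must be 2-D (patients x doses)")
        if self.assign_type is None:
            self.assign_type = np.where(self.treated, 1, 0).astype(np.int8)
        else:
            self.assign_type = np.asarray(self.assign_type, dtype=np.int8)
            if self.assign_type.shape != self.y.shape:
                raise ValueError("assign_type shape mismatch")
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_patients(self) -> int:
        return self.y.shape[0]

    @property
    def n_doses(self) -> int:
        return self.y.shape[1]

    @property
    def y_k(self) -> np.ndarray:
        """Per-dose DLT counts (treated cells only)."""
        return (self.y * self.treated).sum(axis=0)

    @property
    def n_k(self) -> np.ndarray:
        """Per-dose treatment counts; their sum may exceed ``n_patients``."""
        return self.treated.sum(axis=0)

    def validate(self) -> None:
        if np.any(self.treated.sum(axis=1) > MAX_CYCLES):
            raise ValueError(f"a patient was treated at more than {MAX_CYCLES} doses")
        if np.any((self.assign_type != 0) != self.treated):
            raise ValueError("assign_type must be in {1,2} exactly on treated cells")
        bad = self.treated & ~np.isin(self.y, (0, 1))
        if np.any(bad):
            raise ValueError("outcomes must be binary on treated cells")

    # ------------------------------------------------------------------
    @classmethod
    def empty(cls, n_doses: int) -> "TrialData":
        z = np.zeros((0, n_doses), dtype=np.int8)
        return cls(y=z, treated=z.astype(bool))

    def to_long(self) -> pd.DataFrame:
        """Long-format table: one row per treated (patient, dose) cell."""
        rows = []
        for i in range(self.n_patients):
            cycle = 0
            for k in range(self.n_doses):
                if self.treated[i, k]:
                    cycle += 1
                    rows.append(
                        dict(
                            patient_id=i + 1,
                            dose_level=k + 1,
                            outcome=int(self.y[i, k]),
                            assign_type=int(self.assign_type[i, k]),
                            cycle_index=cycle,
                        )
                    )
        return pd.DataFrame(
            rows,
            columns=["patient_id", "dose_level", "outcome", "assign_type", "cycle_index"],
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame, n_doses: int | None = None) -> "TrialData":
        """Build from a long-format table (1-based patient_id / dose_level)."""
        if len(df) == 0:
            return cls.empty(n_doses or 0)
        n = int(df["patient_id"].max())
        K = n_doses or int(df["dose_level"].max())
        y = np.zeros((n, K), dtype=np.int8)
        treated = np.zeros((n, K), dtype=bool)
        z = np.zeros((n, K), dtype=np.int8)
        for _, row in df.iterrows():
            i, k = int(row["patient_id"]) - 1, int(row["dose_level"]) - 1
            if treated[i, k]:
                raise ValueError(f"duplicate observation for patient {i+1} dose {k+1}")
            treated[i, k] = True
            y[i, k] = int(row["outcome"])
            z[i, k] = int(row.get("assign_type", 1))
        return cls(y=y, treated=treated, assign_type=z)

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_doses: int | None = None) -> "TrialData":
        return cls.from_long(pd.read_csv(path), n_doses=n_doses)
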