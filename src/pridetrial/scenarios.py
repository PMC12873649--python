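"""Dose-toxicity scenarios: fixed benchmark sets and a random generator.

Set A holds six five-dose scenarios with target DLT rate 0.33; Set B holds
eight seven-dose scenarios with target 0.20.  The true MTD of each scenario is
the dose whose probability equals the target exactly (one scenario per set has
no such dose: every dose is over- or under-dosed).

Random scenarios follow a Paoletti-style construction indexed by the average
probability difference around the target (APDT): the MTD position is uniform
over doses, the MTD probability is pinned at the target, and neighbour
probabilities grow outward by truncated-exponential increments whose mean
equals the APDT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Scenario", "fixed_scenarios", "random_scenario"]


@dataclass(frozen=True)
class Scenario:
    """True per-dose toxicity probabilities with the trial's target rate."""

    probs: tuple
    phi: float
    mtd_index: int | None  # 0-based; None when no dose sits at the target
    label: str = ""

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if np.any(np.diff(p) < 0):
            raise ValueError("toxicity probabilities must be non-decreasing")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0,1]")
        if self.mtd_index is not None and not 0 <= self.mtd_index < len(self.probs):
            raise ValueError("mtd_index out of range")

    @property
    def n_doses(self) -> int:
        return len(self.probs)


# target 0.33, five doses; MTD (0-based) is the dose with p == 0.33
_SET_A = [
    ((0.33, 0.45, 0.58, 0.70, 0.80), 0),
    ((0.18, 0.33, 0.52, 0.60, 0.70), 1),
    ((0.12, 0.22, 0.33, 0.40, 0.50), 2),
    ((0.01, 0.02, 0.03, 0.33, 0.50), 3),
    ((0.00, 0.00, 0.05, 0.10, 0.33), 4),
    ((0.45, 0.55, 0.65, 0.75, 0.85), None),  # every dose over-toxic
]

# target 0.20, seven doses
_SET_B = [
    ((0.05, 0.20, 0.46, 0.50, 0.60, 0.70, 0.80), 1),
    ((0.02, 0.05, 0.20, 0.28, 0.34, 0.40, 0.44), 2),
    ((0.01, 0.05, 0.10, 0.20, 0.32, 0.50, 0.70), 3),
    ((0.01, 0.04, 0.07, 0.10, 0.50, 0.70, 0.90), None),  # no dose at the target
    ((0.01, 0.05, 0.10, 0.14, 0.20, 0.26, 0.34), 4),
    ((0.01, 0.02, 0.03, 0.05, 0.20, 0.40, 0.50), 4),
    ((0.01, 0.04, 0.07, 0.10, 0.15, 0.20, 0.25), 5),
    ((0.01, 0.02, 0.03, 0.04, 0.05, 0.20, 0.45), 5),
]


def fixed_scenarios(set_id: str) -> list[Scenario]:
    """The fixed benchmark scenario tables ('A': 5 doses, phi=0.33; 'B': 7, 0.20)."""
    set_id = set_id.upper()
    if set_id == "A":
        rows, phi = _SET_A, 0.33
    elif set_id == "B":
        rows, phi = _SET_B, 0.20
    else:
        raise ValueError(f"unknown scenario set {set_id!r}")
    return [
        Scenario(probs=p, phi=phi, mtd_index=m, label=f"{set_id}{j+1}")
        for j, (p, m) in enumerate(rows)
    ]


def _truncated_exp_increments(rng: np.random.Generator, size: int, mean: float) -> np.ndarray:
    """Exp(1) truncated at 3, rescaled so the post-truncation mean equals `mean`."""
    t = 3.0
    u = rng.random(size)
    e = -np.log1p(-u * (1.0 - np.exp(-t)))  # inverse-CDF of Exp(1) on [0, t]
    m_t = 1.0 - t * np.exp(-t) / (1.0 - np.exp(-t))  # mean of the truncated draw
    return e * (mean / m_t)


def random_scenario(
    K: int, phi: float, apdt: float, rng: np.random.Generator
) -> Scenario:
    """Draw a monotone scenario with the MTD pinned at the target rate.

    The MTD position is uniform over the K doses; probabilities grow outward
    from p_MTD = phi by independent truncated-exponential increments with mean
    ``apdt`` (so the expected one-step probability gap around the target is
    the APDT), clipped to (0.001, 0.999).
    """
    if not 0 < apdt < 0.5:
        raise ValueError("apdt must be in (0, 0.5)")
    if K < 2:
        raise ValueError("need at least two doses")
    if not 0 < phi < 1:
        raise ValueError("phi must be in (0,1)")
    m = int(rng.integers(K))
    p = np.empty(K)
    p[m] = phi
    if m < K - 1:
        up = _truncated_exp_increments(rng, K - 1 - m, apdt)
        p[m + 1 :] = phi + np.cumsum(up)
    if m > 0:
        down = _truncated_exp_increments(rng, m, apdt)
        p[:m] = (phi - np.cumsum(down))[::-1]
    p = np.clip(p, 0.001, 0.999)
    p = np.maximum.accumulate(p)  # clipping can only create flats, keep monotone
    return Scenario(probs=tuple(p), phi=phi, mtd_index=m, label=f"random-{K}-{apdt}")
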