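"""Lifetime six-state annual-cycle Markov cohort engine.

Day-90 survivors enter in "No CKD" or "CKD 1-4" and transition annually
between No CKD, CKD 1-4, ESRD, dialysis, post-transplant and death until
an age cap.  Reversion to milder kidney states is structurally impossible;
the only two-way traffic is dialysis <-> post-transplant (graft failure
returns to dialysis, after which a further transplant is possible).

Mortality combines state-specific relative risks with age- and sex-mixed
general-population annual death probabilities on the survival scale:
q_state = 1 - (1 - qx)^RR.  Rewards use a trapezoidal half-cycle
correction (mean of cycle-start and cycle-end occupancy); utilities are
age/sex adjusted multiplicatively against population norms; costs and
QALYs accruing beyond the first model year are discounted at 3.5%/yr.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "STATES",
    "ALLOWED_TRANSITIONS",
    "TransitionSpec",
    "Lifetable",
    "UtilityNorms",
    "StateValues",
    "MarkovResult",
    "build_matrix",
    "adjust_utility",
    "run_cohort",
]

STATES = ("no_ckd", "ckd", "esrd", "dialysis", "transplant", "death")
N_ALIVE = 5
DEATH = 5

# structural support: row -> permitted destination columns among alive states
ALLOWED_TRANSITIONS = {
    0: (0, 1),        # no_ckd -> no_ckd, ckd
    1: (1, 2),        # ckd -> ckd, esrd (no reversion)
    2: (2, 3),        # esrd -> esrd, dialysis
    3: (3, 4),        # dialysis -> dialysis, transplant
    4: (4, 3),        # transplant -> transplant, dialysis (graft failure)
}


@dataclass(frozen=True)
class TransitionSpec:
    """Annual base transitions among alive states plus mortality RRs.

    ``base`` is 5x5 and row-stochastic over the alive states (mortality is
    layered on top from the lifetable); structural zeros are enforced.
    ``mortality_rr`` is the per-state relative risk versus the general
    population.
    """

    base: np.ndarray
    mortality_rr: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        b = np.asarray(self.base, dtype=float)
        if b.shape != (N_ALIVE, N_ALIVE):
            raise ValueError("base must be 5x5 over the alive states")
        if np.any(b < 0):
            raise ValueError("base transition probabilities must be >= 0")
        if np.any(np.abs(b.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("base transition rows must sum to 1")
        for i in range(N_ALIVE):
            forbidden = [j for j in range(N_ALIVE) if j not in ALLOWED_TRANSITIONS[i]]
            if np.any(b[i, forbidden] > 0):
                raise ValueError(
                    f"structural zero violated in row {STATES[i]!r}: "
                    f"mass on {[STATES[j] for j in forbidden if b[i, j] > 0]}"
                )
        if any(rr < 0 for rr in self.mortality_rr):
            raise ValueError("mortality relative risks must be >= 0")
        object.__setattr__(self, "base", b)


@dataclass(frozen=True)
class Lifetable:
    """General-population annual death probabilities by age and sex."""

    ages: np.ndarray
    qx_male: np.ndarray
    qx_female: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.ages, dtype=float)
        qm = np.asarray(self.qx_male, dtype=float)
        qf = np.asarray(self.qx_female, dtype=float)
        if not (len(a) == len(qm) == len(qf)):
            raise ValueError("lifetable columns must have equal length")
        if np.any(np.diff(a) != 1.0):
            raise ValueError("lifetable ages must be contiguous single years")
        for q in (qm, qf):
            if np.any(q < 0) or np.any(q > 1):
                raise ValueError("lifetable probabilities must lie in [0, 1]")
        object.__setattr__(self, "ages", a)
        object.__setattr__(self, "qx_male", qm)
        object.__setattr__(self, "qx_female", qf)

    def qx(self, age: float, female_fraction: float) -> float:
        """Sex-mixed annual death probability at ``age``."""
        if age < self.ages[0] or age > self.ages[-1]:
            raise ValueError(f"age {age} outside lifetable range")
        i = int(np.searchsorted(self.ages, age, side="right")) - 1
        return float(
            female_fraction * self.qx_female[i] + (1.0 - female_fraction) * self.qx_male[i]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "qx_male": self.qx_male, "qx_female": self.qx_female}
        )


@dataclass(frozen=True)
class UtilityNorms:
    """Population utility norms by age and sex (for age/sex adjustment)."""

    ages: np.ndarray
    norm_male: np.ndarray
    norm_female: np.ndarray

    def value(self, age: float, female_fraction: float) -> float:
        m = float(np.interp(age, self.ages, self.norm_male))
        f = float(np.interp(age, self.ages, self.norm_female))
        return female_fraction * f + (1.0 - female_fraction) * m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "norm_male": self.norm_male, "norm_female": self.norm_female}
        )


@dataclass(frozen=True)
class StateValues:
    """Annual cost and base utility per alive state."""

    costs: tuple[float, float, float, float, float]
    utilities: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.costs):
            raise ValueError("state costs must be >= 0")
        if any(not 0.0 <= u <= 1.0 for u in self.utilities):
            raise ValueError("state utilities must lie in [0, 1]")


@dataclass(frozen=True)
class MarkovResult:
    discounted_cost: float
    discounted_qaly: float
    trace: pd.DataFrame  # occupancy per state per cycle (cycle 0 = start)


def build_matrix(
    age: float,
    female_fraction: float,
    spec: TransitionSpec,
    lifetable: Lifetable,
) -> np.ndarray:
    """One-cycle 6x6 row-stochastic matrix at a given age.

    Per alive state: death probability 1 - (1 - qx)^RR, with the base
    transition row renormalised over survivors.
    """
    qx = lifetable.qx(age, female_fraction)
    P = np.zeros((6, 6))
    for i in range(N_ALIVE):
        die = 1.0 - (1.0 - qx) ** spec.mortality_rr[i]
        P[i, :N_ALIVE] = spec.base[i] * (1.0 - die)
        P[i, DEATH] = die
    P[DEATH, DEATH] = 1.0
    if np.any(P < 0):
        raise ValueError("negative transition probability after mortality combination")
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
        raise ValueError("transition matrix rows do not sum to 1")
    return P


def adjust_utility(
    base: float,
    age: float,
    female_fraction: float,
    norms: UtilityNorms,
    reference_age: float,
) -> float:
    """Multiplicative age/sex utility adjustment against population norms.

    base * norm(age) / norm(reference_age), capped at 1, so quality of
    life declines naturally with age as the norms do.
    """
    ref = norms.value(reference_age, female_fraction)
    if ref == 0:
        raise ValueError("reference-age population norm is zero")
    return min(base * norms.value(age, female_fraction) / ref, 1.0)


def run_cohort(
    start_split,
    spec: TransitionSpec,
    lifetable: Lifetable,
    values: StateValues,
    norms: UtilityNorms,
    start_age: float,
    female_fraction: float,
    discount: float = 0.035,
    age_cap: float = 100.0,
) -> MarkovResult:
    """Run the cohort from ``start_age`` to ``age_cap`` in annual cycles.

    ``start_split`` is either a length-2 occupancy over (no_ckd, ckd) or a
    full length-6 vector.  Rewards use the trapezoidal half-cycle
    correction; cycle 1 is undiscounted, cycle t discounted by
    (1 + discount)^-(t-1).
    """
    v = np.zeros(6)
    s = np.asarray(start_split, dtype=float)
    if s.shape == (2,):
        v[0], v[1] = s
    elif s.shape == (6,):
        v = s.copy()
    else:
        raise ValueError("start_split must have length 2 or 6")
    if abs(v.sum() - 1.0) > 1e-9 or np.any(v < 0):
        raise ValueError("start occupancy must be a probability vector")

    base_utils = np.asarray(values.utilities, dtype=float)
    cost_vec = np.asarray(values.costs, dtype=float)
    n_cycles = int(round(age_cap - start_age))
    if n_cycles < 1:
        raise ValueError("age cap must allow at least one cycle")

    total_cost = 0.0
    total_qaly = 0.0
    trace = [v.copy()]
    for t in range(1, n_cycles + 1):
        age = start_age + t - 1
        P = build_matrix(age, female_fraction, spec, lifetable)
        v_next = v @ P
        occ = 0.5 * (v + v_next)  # half-cycle correction
        utils = np.array(
            [
                adjust_utility(u, age, female_fraction, norms, start_age)
                for u in base_utils
            ]
        )
        disc = (1.0 + discount) ** (-(t - 1))
        total_cost += disc * float(occ[:N_ALIVE] @ cost_vec)
        total_qaly += disc * float(occ[:N_ALIVE] @ utils)
        v = v_next
        if abs(v.sum() - 1.0) > 1e-10:
            raise RuntimeError(f"occupancy sum drifted to {v.sum()} at cycle {t}")
        trace.append(v.copy())

    trace_df = pd.DataFrame(trace, columns=STATES)
    trace_df.index.name = "cycle"
    return MarkovResult(
        discounted_cost=total_cost, discounted_qaly=total_qaly, trace=trace_df
    )
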