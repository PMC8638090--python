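"""90-day diagnostic decision tree for AKI biomarker testing.

One tested cohort splits into the four classification branches (TP, FN,
FP, TN).  All test positives receive a preventative KDIGO care bundle,
but only true positives realise treatment benefits: AKI aversion (tests
that can detect kidney stress before damage), a downward shift of the
KDIGO severity distribution, and attenuated improvements in ICU need,
length of stay, 90-day mortality and CKD risk.  False negatives follow
standard care (AKI is eventually picked up by creatinine monitoring);
false positives incur bundle costs and, in scenario analysis, an excess
mortality risk from unnecessary nephrotoxic-treatment withdrawal.

The tree returns 90-day expected cost and QALYs plus the day-90 survivor
distribution over {No CKD, CKD 1-4} that seeds the lifetime Markov model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accuracy import classification_probs

__all__ = [
    "KDIGO_STAGES",
    "StageDistribution",
    "BundleEffect",
    "AttenuationFractions",
    "AcuteOutcomeTable",
    "StrategySpec",
    "UnitCosts",
    "AcuteUtilities",
    "AcuteInputs",
    "AcuteResult",
    "attenuate",
    "apply_bundle",
    "day90_ckd_share",
    "evaluate_arm",
]

logger = logging.getLogger(__name__)
_seen_warnings: set[str] = set()


def _warn_once(msg: str, *args) -> None:
    """Log a warning once per unique message (PSA loops repeat inputs)."""
    text = msg % args if args else msg
    if text not in _seen_warnings:
        _seen_warnings.add(text)
        logger.warning(text)

KDIGO_STAGES = (0, 1, 2, 3)  # 0 = no AKI; peak in-hospital KDIGO stage
DAYS = 90.0
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class StageDistribution:
    """Probabilities over KDIGO stages 1..3, conditional on AKI."""

    probs: tuple[float, float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("stage distribution must be non-negative and sum to 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)


def identity_shift() -> np.ndarray:
    return np.eye(3)


@dataclass(frozen=True)
class BundleEffect:
    """Care-bundle effect for treated true positives.

    ``arr`` is the absolute risk reduction in AKI incidence among treated
    test positives.  ``severity_shift`` is a lower-triangular 3x3 operator
    on the conditional stage distribution; entry [i, j] is the probability
    that a would-be stage i+1 case presents as stage j+1 (j <= i), so no
    mass ever moves to a more severe stage.  ``bundle_cost`` is the total
    cost of the bundle course (``bundle_days`` days).
    """

    arr: float
    severity_shift: np.ndarray = field(default_factory=identity_shift)
    bundle_cost: float = 0.0
    bundle_days: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.arr <= 1.0:
            raise ValueError("arr must lie in [0, 1]")
        s = np.asarray(self.severity_shift, dtype=float)
        if s.shape != (3, 3) or np.any(s < 0):
            raise ValueError("severity_shift must be a non-negative 3x3 matrix")
        if np.any(np.abs(s.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("severity_shift rows must sum to 1")
        if np.any(np.triu(s, 1) > 0):
            raise ValueError("severity_shift may not move mass to a more severe stage")
        object.__setattr__(self, "severity_shift", s)


@dataclass(frozen=True)
class AttenuationFractions:
    """Fraction of the observed with-AKI/without-AKI outcome gap realised
    when AKI is averted or mitigated.

    Base case: full effect on CKD risk, half on ICU need and length of
    stay, none on 90-day mortality.
    """

    f_ckd: float = 1.0
    f_icu: float = 0.5
    f_los: float = 0.5
    f_mort: float = 0.0

    def __post_init__(self) -> None:
        for name in ("f_ckd", "f_icu", "f_los", "f_mort"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class AcuteOutcomeTable:
    """Short-term outcomes by peak KDIGO stage (index 0..3).

    ``icu_los`` is conditional on ICU admission; ``p_ckd90`` is the CKD
    probability among day-90 survivors (stage 0 equals the background
    prevalence).
    """

    p_icu: tuple[float, float, float, float]
    p_rrt: tuple[float, float, float, float]
    ward_los: tuple[float, float, float, float]
    icu_los: tuple[float, float, float, float]
    p_death90: tuple[float, float, float, float]
    p_ckd90: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for name in ("p_icu", "p_rrt", "p_death90", "p_ckd90"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        for name in ("ward_los", "icu_los"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v < 0):
                raise ValueError(f"{name} entries must be >= 0")
        for name in ("p_icu", "p_rrt", "ward_los", "p_death90", "p_ckd90"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(np.diff(v) < -1e-12):
                _warn_once("%s is not non-decreasing in KDIGO stage", name)

    def stage(self, i: int) -> dict[str, float]:
        return {
            "p_icu": self.p_icu[i],
            "p_rrt": self.p_rrt[i],
            "ward_los": self.ward_los[i],
            "icu_los": self.icu_los[i],
            "p_death90": self.p_death90[i],
            "p_ckd90": self.p_ckd90[i],
        }


@dataclass(frozen=True)
class StrategySpec:
    """One comparator arm: standard care, or a biomarker test + bundle."""

    strategy_id: str
    accuracy_param: str | None = None  # name of the logit-bivariate accuracy parameter
    can_avert_aki: bool = False
    test_unit_cost: float = 0.0
    tests_per_patient: int = 1
    fp_mortality_rr: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.accuracy_param is None:
            if self.test_unit_cost != 0.0:
                raise ValueError("standard care carries no test cost")
            if self.can_avert_aki:
                raise ValueError("standard care has no care bundle to avert AKI with")
        if self.fp_mortality_rr < 0:
            raise ValueError("fp_mortality_rr must be >= 0")

    @property
    def is_standard_care(self) -> bool:
        return self.accuracy_param is None


@dataclass(frozen=True)
class UnitCosts:
    ward_day: float
    icu_day: float
    rrt_episode: float
    excess_aki_day: float = 0.0  # scenario: daily excess cost while an AKI case is in hospital

    def __post_init__(self) -> None:
        for name in ("ward_day", "icu_day", "rrt_episode", "excess_aki_day"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class AcuteUtilities:
    in_hospital: float
    post_discharge: float

    def __post_init__(self) -> None:
        for name in ("in_hospital", "post_discharge"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class AcuteInputs:
    """Resolved (per-draw) numeric inputs for one tree evaluation."""

    prevalence: float
    stage_dist: StageDistribution
    outcomes: AcuteOutcomeTable
    bundle: BundleEffect
    attenuation: AttenuationFractions
    costs: UnitCosts
    utilities: AcuteUtilities


@dataclass(frozen=True)
class AcuteResult:
    expected_cost_90d: float
    expected_qaly_90d: float
    survivor_fraction: float
    day90_state_split: dict[str, float]  # {"no_ckd": ., "ckd": .} among survivors
    survivor_strata: dict[str, dict[str, float]]  # by AKI exposure, for scenarios
    icu_fraction_survivors: float
    branch_audit: pd.DataFrame


def attenuate(outcome_with: float, outcome_without: float, f: float) -> float:
    """Interpolate between the with-AKI and without/milder-AKI outcome.

    f = 1 realises the full observed gap, f = 0 none of it.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("attenuation fraction must lie in [0, 1]")
    return outcome_without + (1.0 - f) * (outcome_with - outcome_without)


def apply_bundle(
    prevalence: float,
    stages: StageDistribution,
    effect: BundleEffect,
    can_avert: bool,
) -> tuple[float, StageDistribution]:
    """Cohort-level bundle effect: AKI aversion and severity down-shift.

    Aversion is absolute: a reduction of min(arr, prevalence) in AKI
    incidence; tests that cannot pre-empt damage (can_avert=False) leave
    the prevalence unchanged.  The severity shift applies to the surviving
    conditional stage distribution in all cases.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    if can_avert:
        reduction = effect.arr
        if reduction > prevalence:
            _warn_once("care-bundle ARR exceeds the branch prevalence; aversion capped")
            reduction = prevalence
        adjusted_prev = prevalence - reduction
    else:
        adjusted_prev = prevalence
    shifted = stages.as_array() @ effect.severity_shift
    return adjusted_prev, StageDistribution(tuple(shifted))


def day90_ckd_share(
    background: float,
    stage_weights,
    stage_hrs,
    aki_fraction: float = 1.0,
) -> float:
    """CKD share among day-90 survivors from stage-specific hazard ratios.

    background prevalence plus the stage-weighted incremental CKD risk
    background*(HR_i - 1), scaled by the AKI fraction of the survivor
    cohort; clamped into [0, 1] with a warning.
    """
    w = np.asarray(stage_weights, dtype=float)
    hr = np.asarray(stage_hrs, dtype=float)
    share = background + aki_fraction * float(w @ (background * (hr - 1.0)))
    if share < 0.0 or share > 1.0:
        _warn_once("day-90 CKD share outside [0, 1]; clamped")
        share = min(max(share, 0.0), 1.0)
    return share


# ---------------------------------------------------------------------------
# tree evaluation


def _substate(
    weight: float,
    with_stage: int,
    target_stage: int,
    inputs: AcuteInputs,
    f: AttenuationFractions,
    branch: str,
    death_rr: float = 1.0,
    bundled: bool = False,
) -> dict:
    """One leaf of the tree: a cohort slice whose realised outcomes
    interpolate between its would-be stage and its (same or milder)
    target stage."""
    src = inputs.outcomes.stage(with_stage)
    dst = inputs.outcomes.stage(target_stage)
    p_icu = attenuate(src["p_icu"], dst["p_icu"], f.f_icu)
    p_rrt = attenuate(src["p_rrt"], dst["p_rrt"], f.f_icu)
    ward = attenuate(src["ward_los"], dst["ward_los"], f.f_los)
    icu = attenuate(src["icu_los"], dst["icu_los"], f.f_los)
    p_death = attenuate(src["p_death90"], dst["p_death90"], f.f_mort)
    p_ckd = attenuate(src["p_ckd90"], dst["p_ckd90"], f.f_ckd)
    p_death = min(p_death * death_rr, 1.0)

    hosp_days = min(ward + p_icu * icu, DAYS)
    cost = (
        ward * inputs.costs.ward_day
        + p_icu * icu * inputs.costs.icu_day
        + p_rrt * inputs.costs.rrt_episode
    )
    # realised AKI status follows the target stage (averted cases are stage 0)
    realised_aki = target_stage > 0
    if realised_aki:
        cost += hosp_days * inputs.costs.excess_aki_day
    if bundled:
        cost += inputs.bundle.bundle_cost

    u = inputs.utilities
    qaly_alive = (hosp_days * u.in_hospital + (DAYS - hosp_days) * u.post_discharge) / DAYS_PER_YEAR
    qaly = (1.0 - p_death) * qaly_alive + p_death * 0.5 * qaly_alive

    return {
        "branch": branch,
        "with_stage": with_stage,
        "target_stage": target_stage,
        "weight": weight,
        "cost": cost,
        "qaly": qaly,
        "p_death90": p_death,
        "p_icu": p_icu,
        "p_ckd90": p_ckd,
        "aki": realised_aki,
    }


def _standard_substates(inputs: AcuteInputs, prevalence: float | None = None) -> list[dict]:
    p = inputs.prevalence if prevalence is None else prevalence
    f_none = AttenuationFractions(0.0, 0.0, 0.0, 0.0)  # identity interpolation
    subs = [_substate(1.0 - p, 0, 0, inputs, f_none, "no_aki")]
    stage_w = inputs.stage_dist.as_array()
    for i in (1, 2, 3):
        subs.append(_substate(p * stage_w[i - 1], i, i, inputs, f_none, "aki"))
    return subs


def evaluate_arm(
    strategy: StrategySpec,
    inputs: AcuteInputs,
    sensitivity: float | None = None,
    specificity: float | None = None,
) -> AcuteResult:
    """Expected 90-day cost/QALY and day-90 handoff for one strategy arm.

    For test arms, ``sensitivity`` / ``specificity`` are the per-draw
    accuracy values (shared across the whole tree within a PSA draw).
    """
    p = inputs.prevalence
    stage_w = inputs.stage_dist.as_array()
    f = inputs.attenuation
    subs: list[dict] = []
    test_cost = 0.0

    if strategy.is_standard_care:
        subs = _standard_substates(inputs)
    else:
        if sensitivity is None or specificity is None:
            raise ValueError(f"{strategy.strategy_id}: accuracy draw required for a test arm")
        se, sp = float(sensitivity), float(specificity)
        p_tp, p_fn, p_fp, p_tn = classification_probs(p, se, sp)
        test_cost = strategy.tests_per_patient * strategy.test_unit_cost

        # TN: disease-free, correctly negative -> standard no-AKI pathway
        subs.append(_substate(p_tn, 0, 0, inputs, f, "TN"))
        # FP: disease-free but bundled; optional excess mortality scenario
        subs.append(
            _substate(
                p_fp, 0, 0, inputs, f, "FP",
                death_rr=strategy.fp_mortality_rr, bundled=True,
            )
        )
        # FN: missed AKI follows standard care, stage for stage
        for i in (1, 2, 3):
            subs.append(_substate(p_fn * stage_w[i - 1], i, i, inputs, f, "FN"))
        # TP: bundled with early-treatment benefit.  The absolute risk
        # reduction is applied to the TP-branch prevalence (the AKI risk
        # among test positives), matching the bundle trial's test-positive
        # population, so the averted fraction is min(arr, ppv) / ppv.
        if p_tp > 0.0:
            ppv = p_tp / (p_tp + p_fp)
            adj_prev, shifted = apply_bundle(
                ppv, inputs.stage_dist, inputs.bundle, strategy.can_avert_aki
            )
            averted_frac = (ppv - adj_prev) / ppv
            shift = inputs.bundle.severity_shift
            for i in (1, 2, 3):
                w_stage = p_tp * stage_w[i - 1]
                if averted_frac > 0.0:
                    subs.append(
                        _substate(
                            w_stage * averted_frac, i, 0, inputs, f, "TP_averted",
                            bundled=True,
                        )
                    )
                for j in (1, 2, 3):
                    w = w_stage * (1.0 - averted_frac) * shift[i - 1, j - 1]
                    if w > 0.0 or i == j:
                        subs.append(
                            _substate(w, i, j, inputs, f, "TP", bundled=True)
                        )

    audit = pd.DataFrame(subs)
    weights = audit["weight"].to_numpy()
    total_w = weights.sum()
    if abs(total_w - 1.0) > 1e-9:
        raise RuntimeError(f"branch weights sum to {total_w}, not 1")

    cost = float(weights @ audit["cost"].to_numpy()) + test_cost
    qaly = float(weights @ audit["qaly"].to_numpy())

    surv_w = weights * (1.0 - audit["p_death90"].to_numpy())
    survivor_fraction = float(surv_w.sum())
    if survivor_fraction <= 0.0:
        raise RuntimeError("no survivors at day 90; check mortality inputs")
    ckd_share = float(surv_w @ audit["p_ckd90"].to_numpy()) / survivor_fraction
    icu_fraction = float(surv_w @ audit["p_icu"].to_numpy()) / survivor_fraction

    strata: dict[str, dict[str, float]] = {}
    aki_mask = audit["aki"].to_numpy(dtype=bool)
    for label, mask in (("aki", aki_mask), ("no_aki", ~aki_mask)):
        w = surv_w[mask]
        if w.sum() > 0:
            strata[label] = {
                "fraction": float(w.sum()) / survivor_fraction,
                "ckd_share": float(w @ audit["p_ckd90"].to_numpy()[mask]) / float(w.sum()),
            }
        else:
            strata[label] = {"fraction": 0.0, "ckd_share": ckd_share}

    return AcuteResult(
        expected_cost_90d=cost,
        expected_qaly_90d=qaly,
        survivor_fraction=survivor_fraction,
        day90_state_split={"no_ckd": 1.0 - ckd_share, "ckd": ckd_share},
        survivor_strata=strata,
        icu_fraction_survivors=icu_fraction,
        branch_audit=audit,
    )
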