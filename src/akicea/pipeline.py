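"""End-to-end orchestration: parameter draws -> tree -> Markov -> CEA/VOI.

A :class:`ModelConfig` bundles the parameter set, the comparator arms and
the demographic tables.  For each PSA draw the 90-day tree produces the
acute cost/QALY and day-90 handoff per arm, and the Markov engine is run
once per start state (lifetime outcomes are linear in the start split, so
two unit runs per draw value every arm).  Point-estimate runs reuse the
same path with every parameter at its point value.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .acute import (
    AcuteInputs,
    AcuteOutcomeTable,
    AcuteResult,
    AcuteUtilities,
    AttenuationFractions,
    BundleEffect,
    StageDistribution,
    StrategySpec,
    UnitCosts,
    evaluate_arm,
)
from .cea import StrategyOutcome, ceac, frontier, nmb
from .markov import Lifetable, StateValues, TransitionSpec, UtilityNorms, run_cohort
from .params import ParameterSet, ParameterSpec, CohortProfile, sample_matrix
from .synthetic import make_base_fixture, make_lifetable, make_strategies, make_utility_norms
from .voi import evpi, evppi_ranking, population_evpi

__all__ = [
    "ModelConfig",
    "PsaResults",
    "resolve_acute_inputs",
    "resolve_markov",
    "run_point",
    "run_psa",
    "basecase_table",
    "run_voi",
    "default_config",
    "config_to_yaml",
    "config_from_yaml",
]

MARKOV_STATE_ORDER = ("no_ckd", "ckd", "esrd", "dialysis", "transplant")


@dataclass
class ModelConfig:
    params: ParameterSet
    strategies: list[StrategySpec]
    lifetable: Lifetable
    norms: UtilityNorms
    age_cap: float = 100.0

    def content_hash(self) -> str:
        return hashlib.sha256(config_to_yaml(self).encode("utf-8")).hexdigest()[:16]


def default_config(seed: int = 0) -> ModelConfig:
    params = make_base_fixture(seed)
    return ModelConfig(
        params=params,
        strategies=make_strategies(params),
        lifetable=make_lifetable(),
        norms=make_utility_norms(),
    )


# ---------------------------------------------------------------------------
# resolution of sampled values into module inputs


def _severity_shift(downshift: float) -> np.ndarray:
    """Move a fraction of each KDIGO stage one stage milder (stage 1 stays)."""
    d = float(downshift)
    if not 0.0 <= d <= 1.0:
        raise ValueError("severity_downshift must lie in [0, 1]")
    return np.array([
        [1.0, 0.0, 0.0],
        [d, 1.0 - d, 0.0],
        [0.0, d, 1.0 - d],
    ])


def resolve_acute_inputs(values: Mapping[str, float]) -> AcuteInputs:
    """Build decision-tree inputs from one draw's parameter values."""
    try:
        background = values["ckd_background_prev"]
        stage_fracs = np.array([values[f"stage{i}_frac"] for i in (1, 2, 3)])
        stage_fracs = stage_fracs / stage_fracs.sum()
        hrs = [values[f"ckd_hr_stage{i}"] for i in (1, 2, 3)]
        p_ckd90 = [background] + [min(background * hr, 1.0) for hr in hrs]
        outcomes = AcuteOutcomeTable(
            p_icu=tuple(min(values[f"p_icu_stage{i}"], 1.0) for i in range(4)),
            p_rrt=tuple(min(values[f"p_rrt_stage{i}"], 1.0) for i in range(4)),
            ward_los=tuple(values[f"ward_los_stage{i}"] for i in range(4)),
            icu_los=tuple(values[f"icu_los_stage{i}"] for i in range(4)),
            p_death90=tuple(min(values[f"p_death90_stage{i}"], 1.0) for i in range(4)),
            p_ckd90=tuple(p_ckd90),
        )
        return AcuteInputs(
            prevalence=values["aki_prevalence"],
            stage_dist=StageDistribution(tuple(stage_fracs)),
            outcomes=outcomes,
            bundle=BundleEffect(
                arr=min(values["arr_bundle"], 1.0),
                severity_shift=_severity_shift(values["severity_downshift"]),
                bundle_cost=values["bundle_cost"],
            ),
            attenuation=AttenuationFractions(
                f_ckd=values["f_ckd"], f_icu=values["f_icu"],
                f_los=values["f_los"], f_mort=values["f_mort"],
            ),
            costs=UnitCosts(
                ward_day=values["cost_ward_day"],
                icu_day=values["cost_icu_day"],
                rrt_episode=values["cost_rrt_episode"],
                excess_aki_day=values["excess_aki_day_cost"],
            ),
            utilities=AcuteUtilities(
                in_hospital=min(values["u_in_hospital"], 1.0),
                post_discharge=min(values["u_post_discharge"], 1.0),
            ),
        )
    except KeyError as exc:
        raise KeyError(f"missing model parameter {exc.args[0]!r}") from None


def resolve_markov(values: Mapping[str, float]) -> tuple[TransitionSpec, StateValues]:
    """Markov transition spec and state values from one draw."""
    try:
        b = np.zeros((5, 5))
        b[0, 1] = min(values["tp_nockd_ckd"], 1.0)
        b[1, 2] = min(values["tp_ckd_esrd"], 1.0)
        b[2, 3] = min(values["tp_esrd_dialysis"], 1.0)
        b[3, 4] = min(values["tp_dialysis_transplant"], 1.0)
        b[4, 3] = min(values["tp_transplant_dialysis"], 1.0)
        for i in range(5):
            b[i, i] = 1.0 - b[i].sum()
        spec = TransitionSpec(
            base=b,
            mortality_rr=tuple(values[f"mort_rr_{s}"] for s in MARKOV_STATE_ORDER),
        )
        sv = StateValues(
            costs=tuple(values[f"cost_state_{s}"] for s in MARKOV_STATE_ORDER),
            utilities=tuple(min(values[f"u_state_{s}"], 1.0) for s in MARKOV_STATE_ORDER),
        )
        return spec, sv
    except KeyError as exc:
        raise KeyError(f"missing model parameter {exc.args[0]!r}") from None


def _markov_unit_runs(
    config: ModelConfig,
    values: Mapping[str, float],
    ckd_excess_multiplier: float = 1.0,
) -> dict[str, tuple[float, float]]:
    """Discounted lifetime (cost, QALY) per pure start state.

    Lifetime outcomes are linear in the day-90 start split, so these two
    unit runs value any survivor mix.  ``ckd_excess_multiplier`` scales
    the No CKD -> CKD transition (lifetime-excess-CKD-risk scenario).
    """
    spec, sv = resolve_markov(values)
    if ckd_excess_multiplier != 1.0:
        b = spec.base.copy()
        b[0, 1] = min(b[0, 1] * ckd_excess_multiplier, 1.0)
        b[0, 0] = 1.0 - b[0, 1]
        spec = TransitionSpec(base=b, mortality_rr=spec.mortality_rr)
    cohort = config.params.cohort
    out: dict[str, tuple[float, float]] = {}
    for label, split in (("no_ckd", (1.0, 0.0)), ("ckd", (0.0, 1.0))):
        res = run_cohort(
            split, spec, config.lifetable, sv, config.norms,
            start_age=cohort.start_age, female_fraction=cohort.female_fraction,
            discount=cohort.discount_rate, age_cap=config.age_cap,
        )
        out[label] = (res.discounted_cost, res.discounted_qaly)
    return out


def _lifetime_for_arm(
    acute: AcuteResult,
    units: dict[str, tuple[float, float]],
    units_aki: dict[str, tuple[float, float]] | None = None,
    units_icu: dict[str, tuple[float, float]] | None = None,
) -> tuple[float, float]:
    """Expected discounted lifetime (cost, QALY) per patient at day 0.

    Mixes the Markov unit runs over the arm's day-90 survivor split.  If
    ``units_aki`` is given (excess lifetime CKD risk scenario), AKI-exposed
    survivors use it; if ``units_icu`` is given, the ICU-exposed survivor
    fraction uses it (ICU-dependent long-term outcomes scenario).
    """

    def mix(u: dict[str, tuple[float, float]], split: Mapping[str, float]) -> np.ndarray:
        return split["no_ckd"] * np.asarray(u["no_ckd"]) + split["ckd"] * np.asarray(u["ckd"])

    if units_aki is not None:
        parts = np.zeros(2)
        for label, u in (("aki", units_aki), ("no_aki", units)):
            st = acute.survivor_strata[label]
            split = {"no_ckd": 1.0 - st["ckd_share"], "ckd": st["ckd_share"]}
            parts += st["fraction"] * mix(u, split)
    elif units_icu is not None:
        f_icu = acute.icu_fraction_survivors
        parts = (1.0 - f_icu) * mix(units, acute.day90_state_split) + f_icu * mix(
            units_icu, acute.day90_state_split
        )
    else:
        parts = mix(units, acute.day90_state_split)
    cost, qaly = acute.survivor_fraction * parts
    return float(cost), float(qaly)


def _scenario_knobs(params: ParameterSet) -> dict:
    flags = params.scenario_flags
    return {
        "ckd_excess_multiplier": float(flags.get("ckd_excess_multiplier", 1.0)),
        "icu_longterm": bool(flags.get("icu_longterm", False)),
    }


def _evaluate_draw(
    config: ModelConfig, values: Mapping[str, float]
) -> dict[str, tuple[float, float]]:
    """Total (cost, QALY) per strategy for one set of parameter values."""
    knobs = _scenario_knobs(config.params)
    inputs = resolve_acute_inputs(values)
    units = _markov_unit_runs(config, values)
    units_aki = (
        _markov_unit_runs(config, values, knobs["ckd_excess_multiplier"])
        if knobs["ckd_excess_multiplier"] != 1.0
        else None
    )
    units_icu = None
    if knobs["icu_longterm"]:
        vals_icu = dict(values)
        cmult = values["scenario_icu_cost_multiplier"]
        mmult = values["scenario_icu_mort_multiplier"]
        for s in MARKOV_STATE_ORDER:
            vals_icu[f"cost_state_{s}"] = values[f"cost_state_{s}"] * cmult
            vals_icu[f"mort_rr_{s}"] = values[f"mort_rr_{s}"] * mmult
        units_icu = _markov_unit_runs(config, vals_icu)

    out: dict[str, tuple[float, float]] = {}
    for strat in config.strategies:
        if strat.is_standard_care:
            acute = evaluate_arm(strat, inputs)
        else:
            se = values[f"{strat.accuracy_param}_sens"]
            sp = values[f"{strat.accuracy_param}_spec"]
            acute = evaluate_arm(strat, inputs, se, sp)
        lt_cost, lt_qaly = _lifetime_for_arm(acute, units, units_aki, units_icu)
        out[strat.strategy_id] = (
            acute.expected_cost_90d + lt_cost,
            acute.expected_qaly_90d + lt_qaly,
        )
    return out


# ---------------------------------------------------------------------------
# public runs


@dataclass
class PsaResults:
    """Per-draw, per-strategy costs/QALYs plus the sampled parameter values."""

    costs: pd.DataFrame      # draws x strategies
    qalys: pd.DataFrame      # draws x strategies
    param_draws: pd.DataFrame
    seed: int

    def outcomes(self) -> list[StrategyOutcome]:
        return [
            StrategyOutcome(sid, self.costs[sid].to_numpy(), self.qalys[sid].to_numpy())
            for sid in self.costs.columns
        ]

    def nmb_matrix(self, threshold: float, strategies: list[str] | None = None) -> np.ndarray:
        ids = strategies or list(self.costs.columns)
        return np.column_stack(
            [nmb(self.costs[s].to_numpy(), self.qalys[s].to_numpy(), threshold) for s in ids]
        )


def run_point(config: ModelConfig) -> pd.DataFrame:
    """Deterministic run with every parameter at its point estimate."""
    values = config.params.point_values()
    totals = _evaluate_draw(config, values)
    rows = [
        {"strategy": sid, "cost": c, "qaly": q} for sid, (c, q) in totals.items()
    ]
    return pd.DataFrame(rows)


def run_psa(config: ModelConfig, n_draws: int = 1000, seed: int = 42) -> PsaResults:
    """Monte Carlo PSA: sample, evaluate every strategy per draw."""
    draws = sample_matrix(config.params, n_draws, seed)
    ids = [s.strategy_id for s in config.strategies]
    costs = np.empty((n_draws, len(ids)))
    qalys = np.empty((n_draws, len(ids)))
    records = draws.to_dict("records")
    for i, values in enumerate(records):
        totals = _evaluate_draw(config, values)
        for j, sid in enumerate(ids):
            costs[i, j], qalys[i, j] = totals[sid]
    return PsaResults(
        costs=pd.DataFrame(costs, columns=ids),
        qalys=pd.DataFrame(qalys, columns=ids),
        param_draws=draws,
        seed=seed,
    )


def basecase_table(
    results: PsaResults,
    threshold: float | None = None,
    reference: str = "standard_care",
) -> pd.DataFrame:
    """Publication-shaped base-case table.

    Columns: mean cost, incremental cost, mean QALY, incremental QALY,
    incremental ICER along the frontier, ICER vs the reference strategy,
    and probabilities of cost-effectiveness at the threshold (multi-
    strategy and pairwise vs reference).
    """
    outcomes = results.outcomes()
    entries = {e.strategy_id: e for e in frontier(outcomes, reference=reference)}
    lam = 20_000.0 if threshold is None else threshold
    probs = ceac(outcomes, thresholds=[lam], reference=reference).iloc[0]

    ref_cost = entries[reference].mean_cost
    ref_qaly = entries[reference].mean_qaly
    rows = []
    for o in outcomes:
        e = entries[o.strategy_id]
        dominated = e.status != "on_frontier"
        rows.append(
            {
                "strategy": o.strategy_id,
                "cost": e.mean_cost,
                "incremental_cost": (
                    "Dominated" if dominated else e.mean_cost - ref_cost
                ),
                "qaly": e.mean_qaly,
                "incremental_qaly": (
                    "Dominated" if dominated else e.mean_qaly - ref_qaly
                ),
                "icer_incremental": (
                    "Dominated" if dominated else e.icer_incremental
                ),
                "icer_vs_reference": e.icer_vs_reference,
                "status": e.status,
                "p_ce": probs[o.strategy_id],
                "p_ce_vs_reference": probs.get(f"{o.strategy_id}_vs_{reference}", np.nan),
            }
        )
    return pd.DataFrame(rows).sort_values("cost", kind="mergesort").reset_index(drop=True)


def run_voi(
    results: PsaResults,
    config: ModelConfig,
    strategies: tuple[str, str] = ("nephrocheck", "standard_care"),
    threshold: float | None = None,
    per_parameter: bool = True,
):
    """EVPI and (grouped) EVPPI for a two-strategy comparison.

    Follows the published analysis in valuing information for the most
    promising test versus standard care at the stated threshold, scaled
    to the annual population over the decision horizon (undiscounted).
    """
    from .voi import VoiResult

    cohort = config.params.cohort
    lam = cohort.wtp_threshold if threshold is None else threshold
    m = results.nmb_matrix(lam, list(strategies))
    pp = evpi(m)
    pop = population_evpi(pp, cohort.annual_population, cohort.decision_horizon)

    sampled = [
        s for s in config.params.parameters.values()
        if s.family not in ("fixed",)
    ]
    subsets: dict[str, list[str]] = {}
    if per_parameter:
        for s in sampled:
            subsets[s.name] = s.column_names()
    for group in ("baseline_probability", "cost", "utility", "relative_effect"):
        names = [c for s in sampled if s.group == group for c in s.column_names()]
        if names:
            subsets[f"group:{group}"] = names
    ranking = evppi_ranking(
        m, results.param_draws, subsets,
        annual_population=cohort.annual_population,
        horizon_years=cohort.decision_horizon,
    )
    return VoiResult(
        threshold=lam, evpi_per_patient=pp, population_evpi=pop, evppi=ranking
    )


# ---------------------------------------------------------------------------
# YAML configuration round trip


def config_to_yaml(config: ModelConfig) -> str:
    """Serialise a full model configuration (fixture) to YAML."""
    d = {
        "cohort": {
            "start_age": config.params.cohort.start_age,
            "female_fraction": config.params.cohort.female_fraction,
            "annual_population": config.params.cohort.annual_population,
            "decision_horizon": config.params.cohort.decision_horizon,
            "discount_rate": config.params.cohort.discount_rate,
            "wtp_threshold": config.params.cohort.wtp_threshold,
        },
        "scenario_flags": dict(config.params.scenario_flags),
        "age_cap": config.age_cap,
        "parameters": [
            {
                "name": s.name,
                "group": s.group,
                "family": s.family,
                "hyperparameters": {k: float(v) for k, v in s.hyperparameters.items()},
                "point_estimate": None if np.isnan(s.point_estimate) else float(s.point_estimate),
                "placeholder": s.placeholder,
            }
            for s in config.params.parameters.values()
        ],
        "strategies": [
            {
                "strategy_id": s.strategy_id,
                "accuracy_param": s.accuracy_param,
                "can_avert_aki": s.can_avert_aki,
                "test_unit_cost": s.test_unit_cost,
                "tests_per_patient": s.tests_per_patient,
                "fp_mortality_rr": s.fp_mortality_rr,
                "label": s.label,
            }
            for s in config.strategies
        ],
        "lifetable": {
            k: [float(x) for x in v]
            for k, v in config.lifetable.to_frame().to_dict("list").items()
        },
        "utility_norms": {
            k: [float(x) for x in v]
            for k, v in config.norms.to_frame().to_dict("list").items()
        },
    }
    return yaml.safe_dump(d, sort_keys=False)


def config_from_yaml(text: str) -> ModelConfig:
    """Rebuild a :class:`ModelConfig` from its YAML serialisation."""
    d = yaml.safe_load(text)
    params = ParameterSet(
        parameters={
            p["name"]: ParameterSpec(
                name=p["name"], group=p["group"], family=p["family"],
                hyperparameters=p["hyperparameters"],
                point_estimate=(
                    float("nan") if p["point_estimate"] is None else p["point_estimate"]
                ),
                placeholder=p.get("placeholder", False),
            )
            for p in d["parameters"]
        },
        cohort=CohortProfile(**d["cohort"]),
        scenario_flags=d.get("scenario_flags", {}),
    )
    strategies = [StrategySpec(**s) for s in d["strategies"]]
    lt = d["lifetable"]
    norms = d["utility_norms"]
    return ModelConfig(
        params=params,
        strategies=strategies,
        lifetable=Lifetable(
            ages=np.asarray(lt["age"]),
            qx_male=np.asarray(lt["qx_male"]),
            qx_female=np.asarray(lt["qx_female"]),
        ),
        norms=UtilityNorms(
            ages=np.asarray(norms["age"]),
            norm_male=np.asarray(norms["norm_male"]),
            norm_female=np.asarray(norms["norm_female"]),
        ),
        age_cap=d.get("age_cap", 100.0),
    )
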