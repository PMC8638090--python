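"""Registry of the twelve structural scenario analyses.

Each scenario returns a modified copy of the model configuration.  Only
the false-positive mortality relative risk (1.5, scenario 12) and the
doubled test count (scenario 11) are published magnitudes; the remaining
levers (higher prevalence, excess daily AKI cost, ICU-dependent long-term
multipliers, lifetime excess CKD risk) are config-exposed placeholders
read from the parameter set.  Slots 8 and 9 are user-definable overrides.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace
from typing import Callable

from .params import ParameterSpec
from .pipeline import ModelConfig

__all__ = ["Scenario", "SCENARIOS", "apply_scenario"]


@dataclass(frozen=True)
class Scenario:
    scenario_id: int
    name: str
    description: str
    apply: Callable[[ModelConfig], ModelConfig]


def _set_fixed(config: ModelConfig, name: str, value: float) -> None:
    old = config.params.parameters[name]
    config.params.parameters[name] = ParameterSpec(
        name=name, group=old.group, family="fixed", hyperparameters={},
        point_estimate=float(value), placeholder=old.placeholder,
    )


def _set_attenuation(config: ModelConfig, f: float) -> ModelConfig:
    c = copy.deepcopy(config)
    for name in ("f_ckd", "f_icu", "f_los", "f_mort"):
        _set_fixed(c, name, f)
    return c


def _full_effects(config: ModelConfig) -> ModelConfig:
    return _set_attenuation(config, 1.0)


def _no_effects(config: ModelConfig) -> ModelConfig:
    return _set_attenuation(config, 0.0)


def _ngal_can_avert(config: ModelConfig) -> ModelConfig:
    c = copy.deepcopy(config)
    c.params.scenario_flags["ngal_can_avert"] = True
    c.strategies = [
        replace(s, can_avert_aki=True) if not s.is_standard_care else s
        for s in c.strategies
    ]
    return c


def _excess_aki_cost(config: ModelConfig) -> ModelConfig:
    c = copy.deepcopy(config)
    level = c.params.parameters["scenario_excess_aki_day_cost"].point_estimate
    _set_fixed(c, "excess_aki_day_cost", level)
    return c


def _no_rrt_costs(config: ModelConfig) -> ModelConfig:
    c = copy.deepcopy(config)
    _set_fixed(c, "cost_rrt_episode", 0.0)
    return c


def _icu_longterm(config: ModelConfig) -> ModelConfig:
    c = copy.deepcopy(config)
    c.params.scenario_flags["icu_longterm"] = True
    return c


def _lifetime_ckd_risk(config: ModelConfig) -> ModelConfig:
    c = copy.deepcopy(config)
    mult = c.params.parameters["scenario_ckd_excess_multiplier"].point_estimate
    c.params.scenario_flags["ckd_excess_multiplier"] = float(mult)
    return c


def _user_slot(config: ModelConfig) -> ModelConfig:
    """Apply user-supplied fixed-parameter overrides from scenario_flags."""
    c = copy.deepcopy(config)
    for name, value in c.params.scenario_flags.get("user_overrides", {}).items():
        _set_fixed(c, name, float(value))
    return c


def _higher_prevalence(config: ModelConfig) -> ModelConfig:
    c = copy.deepcopy(config)
    level = c.params.parameters["scenario_high_prevalence"].point_estimate
    _set_fixed(c, "aki_prevalence", level)
    return c


def _two_tests(config: ModelConfig) -> ModelConfig:
    c = copy.deepcopy(config)
    c.params.scenario_flags["tests_per_patient"] = 2
    c.strategies = [
        replace(s, tests_per_patient=2) if not s.is_standard_care else s
        for s in c.strategies
    ]
    return c


def _fp_mortality(config: ModelConfig) -> ModelConfig:
    c = copy.deepcopy(config)
    _set_fixed(c, "fp_mortality_rr", 1.5)
    c.strategies = [
        replace(s, fp_mortality_rr=1.5) if not s.is_standard_care else s
        for s in c.strategies
    ]
    return c


SCENARIOS: dict[int, Scenario] = {
    1: Scenario(1, "full_effects",
                "Full observed AKI-outcome effects realised by prevention/mitigation",
                _full_effects),
    2: Scenario(2, "no_effects",
                "None of the observed AKI-outcome effects realised", _no_effects),
    3: Scenario(3, "ngal_can_avert", "NGAL tests can also avert AKI", _ngal_can_avert),
    4: Scenario(4, "excess_aki_day_cost",
                "Daily excess in-hospital cost for AKI patients", _excess_aki_cost),
    5: Scenario(5, "no_rrt_costs", "RRT costs removed", _no_rrt_costs),
    6: Scenario(6, "icu_longterm",
                "Long-term costs and mortality depend on ICU exposure", _icu_longterm),
    7: Scenario(7, "lifetime_ckd_risk",
                "Lifetime excess CKD risk for AKI survivors", _lifetime_ckd_risk),
    8: Scenario(8, "user_slot_8", "User-definable overrides", _user_slot),
    9: Scenario(9, "user_slot_9", "User-definable overrides", _user_slot),
    10: Scenario(10, "higher_prevalence", "Higher AKI prevalence", _higher_prevalence),
    11: Scenario(11, "two_tests", "Each test conducted twice per patient", _two_tests),
    12: Scenario(12, "fp_mortality",
                 "Mortality relative risk 1.5 applied to all FP test results",
                 _fp_mortality),
}


def apply_scenario(config: ModelConfig, scenario_id: int) -> ModelConfig:
    try:
        scenario = SCENARIOS[int(scenario_id)]
    except (KeyError, ValueError):
        raise KeyError(f"unknown scenario id {scenario_id!r}") from None
    return scenario.apply(config)
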