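"""Parameter universe, uncertainty distributions and reproducible PSA sampling.

Every uncertain model input is a :class:`ParameterSpec` with one of the
standard health-economics families: beta for probabilities and utilities,
gamma for costs, lognormal for relative effects (hazard/risk ratios),
a bivariate logit-normal for joint (sensitivity, specificity), and
``fixed`` for structural constants.  A :class:`ParameterSet` bundles the
specs with the cohort profile (age, sex mix, discount rate, willingness to
pay, target population) and scenario flags.

Sampling uses one global seed expanded into independent per-parameter
substreams (keyed on a stable hash of the parameter name), so adding or
removing a parameter never perturbs the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
from scipy import optimize, stats

from .accuracy import AccuracySummary, sample_accuracy

__all__ = [
    "FAMILIES",
    "GROUPS",
    "ParameterSpec",
    "CohortProfile",
    "ParameterSet",
    "PsaDraw",
    "beta_from_mean_ci",
    "gamma_from_mean_se",
    "lognormal_from_mean_ci",
    "sample_matrix",
    "sample_draws",
]

FAMILIES = ("beta", "gamma", "lognormal", "logit_bivariate_normal", "fixed")
GROUPS = (
    "baseline_probability",
    "relative_effect",
    "cost",
    "utility",
    "accuracy",
    "structural",
)


class ParameterError(ValueError):
    """Invalid parameter specification or unresolvable parameter name."""


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain (or fixed) model input.

    ``placeholder`` flags values that stand in for unpublished source data;
    tests asserting published numbers must never touch a placeholder.
    """

    name: str
    group: str
    family: str
    hyperparameters: dict
    point_estimate: float
    placeholder: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ParameterError(f"{self.name}: unknown group {self.group!r}")
        if self.family not in FAMILIES:
            raise ParameterError(f"{self.name}: unknown family {self.family!r}")
        h = self.hyperparameters
        if self.family == "beta":
            if h["shape1"] <= 0 or h["shape2"] <= 0:
                raise ParameterError(f"{self.name}: beta shapes must be > 0")
            if not 0.0 <= self.point_estimate <= 1.0:
                raise ParameterError(f"{self.name}: beta point estimate outside [0, 1]")
        elif self.family == "gamma":
            if h["shape"] <= 0 or h["scale"] <= 0:
                raise ParameterError(f"{self.name}: gamma shape/scale must be > 0")
            if self.point_estimate < 0:
                raise ParameterError(f"{self.name}: gamma point estimate must be >= 0")
        elif self.family == "lognormal":
            if h["sigma"] < 0:
                raise ParameterError(f"{self.name}: lognormal sigma must be >= 0")
            if self.point_estimate <= 0:
                raise ParameterError(f"{self.name}: lognormal point estimate must be > 0")
        elif self.family == "logit_bivariate_normal":
            # delegates validation to AccuracySummary
            self.accuracy_summary()

    def accuracy_summary(self) -> AccuracySummary:
        if self.family != "logit_bivariate_normal":
            raise ParameterError(f"{self.name} is not an accuracy parameter")
        h = self.hyperparameters
        return AccuracySummary(
            test_id=self.name,
            mu_se=h["mu_se"],
            sd_se=h["sd_se"],
            mu_sp=h["mu_sp"],
            sd_sp=h["sd_sp"],
            rho=h["rho"],
        )

    @property
    def analytic_mean(self) -> float:
        """Mean of the sampling distribution (point estimate for fixed)."""
        h = self.hyperparameters
        if self.family == "beta":
            return h["shape1"] / (h["shape1"] + h["shape2"])
        if self.family == "gamma":
            return h["shape"] * h["scale"]
        if self.family == "lognormal":
            return float(np.exp(h["mu"] + h["sigma"] ** 2 / 2.0))
        return self.point_estimate

    def column_names(self) -> list[str]:
        """Draw-matrix columns this parameter produces."""
        if self.family == "logit_bivariate_normal":
            return [f"{self.name}_sens", f"{self.name}_spec"]
        return [self.name]


@dataclass(frozen=True)
class CohortProfile:
    """Modelled cohort and decision context."""

    start_age: float = 63.0
    female_fraction: float = 0.543
    annual_population: int = 564_738
    decision_horizon: float = 10.0
    discount_rate: float = 0.035
    wtp_threshold: float = 20_000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ParameterError("female_fraction must lie in [0, 1]")
        if self.discount_rate < 0:
            raise ParameterError("discount_rate must be >= 0")
        if self.wtp_threshold < 0:
            raise ParameterError("wtp_threshold must be >= 0")


@dataclass
class ParameterSet:
    parameters: dict[str, ParameterSpec]
    cohort: CohortProfile = field(default_factory=CohortProfile)
    scenario_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, spec in self.parameters.items():
            if name != spec.name:
                raise ParameterError(f"key {name!r} != spec name {spec.name!r}")

    def __getitem__(self, name: str) -> ParameterSpec:
        try:
            return self.parameters[name]
        except KeyError:
            raise ParameterError(f"unknown parameter {name!r}") from None

    def point_values(self) -> dict[str, float]:
        """Point-estimate value per draw-matrix column (deterministic run)."""
        values: dict[str, float] = {}
        for spec in self.parameters.values():
            if spec.family == "logit_bivariate_normal":
                s = spec.accuracy_summary()
                values[f"{spec.name}_sens"] = s.mean_sensitivity
                values[f"{spec.name}_spec"] = s.mean_specificity
            else:
                values[spec.name] = spec.point_estimate
        return values


@dataclass(frozen=True)
class PsaDraw:
    index: int
    values: Mapping[str, float]
    seed_record: int


def beta_from_mean_ci(
    mean: float,
    lo: float,
    hi: float,
    level: float = 0.95,
    tol: float = 0.005,
) -> tuple[float, float]:
    """Beta shapes reproducing a published mean and central interval.

    First tries the exact-mean family beta(mean*k, (1-mean)*k), choosing
    the concentration k that minimises the squared endpoint error; when
    that family cannot reproduce both endpoints to within ``tol`` (common
    for published point estimates paired with normal-approximation CIs,
    which a skewed beta cannot carry at its mean), both shapes are freed
    and the interval takes precedence — for PSA it is the propagated
    uncertainty that must match the evidence.  Raises if no positive
    shapes reproduce the interval to within ``tol``.
    """
    if not 0.0 < lo <= mean <= hi < 1.0:
        raise ParameterError(f"require 0 < lo <= mean <= hi < 1, got {(mean, lo, hi)}")
    if lo == hi:
        raise ParameterError("degenerate interval; use a fixed parameter instead")
    a = (1.0 - level) / 2.0
    target = np.array([lo, hi])

    def endpoints(shape1: float, shape2: float) -> np.ndarray:
        return stats.beta.ppf([a, 1.0 - a], shape1, shape2)

    res = optimize.minimize_scalar(
        lambda lk: float(
            np.sum((endpoints(mean * np.exp(lk), (1.0 - mean) * np.exp(lk)) - target) ** 2)
        ),
        bounds=(np.log(1e-2), np.log(1e7)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    k = float(np.exp(res.x))
    shapes = (mean * k, (1.0 - mean) * k)
    if np.max(np.abs(endpoints(*shapes) - target)) <= tol:
        return shapes

    free = optimize.minimize(
        lambda p: float(np.sum((endpoints(*np.exp(p)) - target) ** 2)),
        x0=np.log(shapes),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-16},
    )
    shape1, shape2 = np.exp(free.x)
    err = np.max(np.abs(endpoints(shape1, shape2) - target))
    if err > tol:
        raise ParameterError(
            f"no beta distribution reproduces the interval ({lo}, {hi}) "
            f"to within {tol} (best error {err:.4g})"
        )
    return float(shape1), float(shape2)


def gamma_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Moment-matched gamma (shape, scale); se = 0 signals a fixed value.

    shape = mean^2 / se^2, scale = se^2 / mean.  Callers should treat
    ``se == 0`` as family ``fixed`` (this function raises for it).
    """
    if mean <= 0:
        raise ParameterError("gamma mean must be > 0")
    if se < 0:
        raise ParameterError("gamma se must be >= 0")
    if se == 0:
        raise ParameterError("se = 0 degenerates to a fixed value; use family 'fixed'")
    return mean**2 / se**2, se**2 / mean


def lognormal_from_mean_ci(mean: float, lo: float, hi: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) matching a geometric-mean style 95% CI.

    mu = log(mean) on the median scale; sigma from the CI width
    log(hi/lo) / (2 * 1.96).  Used for relative effects published as
    point (95% CI) triples.
    """
    if not 0.0 < lo <= mean <= hi:
        raise ParameterError("require 0 < lo <= mean <= hi")
    z = stats.norm.ppf(0.975)
    sigma = float(np.log(hi / lo) / (2.0 * z)) if hi > lo else 0.0
    return float(np.log(mean)), sigma


def _substream(seed: int, name: str) -> np.random.Generator:
    # stable per-name key so adding a parameter never shifts other streams
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _sample_one(spec: ParameterSpec, n: int, seed: int) -> dict[str, np.ndarray]:
    rng = _substream(seed, spec.name)
    h = spec.hyperparameters
    if spec.family == "beta":
        return {spec.name: rng.beta(h["shape1"], h["shape2"], n)}
    if spec.family == "gamma":
        return {spec.name: rng.gamma(h["shape"], h["scale"], n)}
    if spec.family == "lognormal":
        return {spec.name: rng.lognormal(h["mu"], h["sigma"], n)}
    if spec.family == "fixed":
        return {spec.name: np.full(n, float(spec.point_estimate))}
    if spec.family == "logit_bivariate_normal":
        draws = sample_accuracy(spec.accuracy_summary(), n, rng)
        return {f"{spec.name}_sens": draws[:, 0], f"{spec.name}_spec": draws[:, 1]}
    raise ParameterError(f"{spec.name}: unknown family {spec.family!r}")


def sample_matrix(params: ParameterSet, n: int, seed: int):
    """Sample ``n`` PSA draws as a pandas DataFrame (one column per value).

    Deterministic: identical (params, n, seed) give bit-identical output.
    """
    import pandas as pd

    if n < 1:
        raise ParameterError("n must be >= 1")
    columns: dict[str, np.ndarray] = {}
    for spec in params.parameters.values():
        columns.update(_sample_one(spec, n, seed))
    return pd.DataFrame(columns)


def sample_draws(params: ParameterSet, n: int, seed: int) -> Iterator[PsaDraw]:
    """Sampled draws as :class:`PsaDraw` records (thin view over the matrix)."""
    matrix = sample_matrix(params, n, seed)
    records = matrix.to_dict("records")
    return [PsaDraw(index=i, values=rec, seed_record=seed) for i, rec in enumerate(records)]
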