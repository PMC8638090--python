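"""Bivariate logit-normal model of pooled diagnostic test accuracy.

Pooled sensitivity and specificity from a diagnostic-accuracy meta-analysis
are summarised on the logit (log-odds) scale as a bivariate normal with a
between-measure correlation.  This module reconstructs natural-scale means
and confidence intervals from the logit summaries, draws correlated
(sensitivity, specificity) pairs for probabilistic sensitivity analysis,
and converts a prevalence plus an accuracy draw into the four
classification probabilities (TP, FN, FP, TN) that drive the decision tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit as _logit
from scipy.stats import norm

__all__ = [
    "AccuracySummary",
    "AccuracyDraw",
    "inv_logit",
    "logit",
    "logit_ci",
    "sample_accuracy",
    "classification_probs",
]


@dataclass(frozen=True)
class AccuracySummary:
    """Pooled accuracy of one test on the logit scale.

    ``mu_se``/``mu_sp`` are logit-scale mean sensitivity/specificity,
    ``sd_se``/``sd_sp`` their logit-scale standard errors and ``rho`` the
    correlation of the bivariate normal used for joint sampling.
    """

    test_id: str
    mu_se: float
    sd_se: float
    mu_sp: float
    sd_sp: float
    rho: float

    def __post_init__(self) -> None:
        if self.sd_se < 0 or self.sd_sp < 0:
            raise ValueError("logit-scale standard errors must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"correlation must lie in [-1, 1], got {self.rho}")

    @property
    def mean_sensitivity(self) -> float:
        return float(inv_logit(self.mu_se))

    @property
    def mean_specificity(self) -> float:
        return float(inv_logit(self.mu_sp))


@dataclass(frozen=True)
class AccuracyDraw:
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if not (0.0 < self.sensitivity < 1.0 and 0.0 < self.specificity < 1.0):
            raise ValueError("sensitivity and specificity must lie in (0, 1)")


def inv_logit(x):
    """Inverse logit 1/(1+exp(-x)), overflow-safe for large |x|."""
    return expit(x)


def logit(p):
    """Log-odds of a proportion in (0, 1)."""
    return _logit(p)


def logit_ci(mu: float, sd: float, level: float = 0.95) -> tuple[float, float]:
    """Natural-scale confidence interval from a logit-scale mean and SE.

    Uses the exact standard-normal quantile (1.959964... at 95%), which is
    required to round-trip published 2-dp intervals.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    z = norm.ppf(0.5 + level / 2.0)
    return float(inv_logit(mu - z * sd)), float(inv_logit(mu + z * sd))


def sample_accuracy(
    summary: AccuracySummary,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` correlated (sensitivity, specificity) pairs.

    Sampling is bivariate normal on the logit scale followed by the inverse
    logit.  Perfectly correlated summaries (|rho| = 1) are handled by an
    explicit rank-1 construction (z_sp = rho * z_se) rather than a generic
    covariance factorisation, which can reject the singular matrix.

    Returns an (n, 2) array with columns (sensitivity, specificity).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    if abs(summary.rho) == 1.0:
        z2 = summary.rho * z1
    else:
        z_extra = rng.standard_normal(n)
        z2 = summary.rho * z1 + np.sqrt(1.0 - summary.rho**2) * z_extra
    se = inv_logit(summary.mu_se + summary.sd_se * z1)
    sp = inv_logit(summary.mu_sp + summary.sd_sp * z2)
    return np.column_stack([se, sp])


def classification_probs(
    prevalence: float, sensitivity: float, specificity: float
) -> tuple[float, float, float, float]:
    """Joint probabilities (pTP, pFN, pFP, pTN) for one tested patient.

    With disease prevalence p, a test is true positive with probability
    p*Se, false negative p*(1-Se), false positive (1-p)*(1-Sp) and true
    negative (1-p)*Sp; the four always sum to one.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    p_tp = prevalence * sensitivity
    p_fn = prevalence * (1.0 - sensitivity)
    p_fp = (1.0 - prevalence) * (1.0 - specificity)
    p_tn = (1.0 - prevalence) * specificity
    return p_tp, p_fn, p_fp, p_tn
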