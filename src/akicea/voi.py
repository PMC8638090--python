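"""Expected value of perfect (partial) information from PSA output.

EVPI is the gap between decision value under perfect and current
information: mean over draws of the per-draw maximum NMB, minus the best
strategy's mean NMB.  EVPPI for a parameter subset uses the single-loop
regression estimator popularised by the SAVI tool: each strategy's NMB is
regressed on the subset with an additive cubic B-spline basis, and the
EVPI formula is applied to the fitted conditional expectations.  Per-
patient values scale to the population served over the decision horizon
(undiscounted by default, optionally as a discounted annuity).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "VoiResult",
    "evpi",
    "population_evpi",
    "evppi",
    "evppi_ranking",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VoiResult:
    threshold: float
    evpi_per_patient: float
    population_evpi: float
    evppi: pd.DataFrame  # columns: subset, evppi_per_patient, population_evppi


def evpi(nmb_matrix) -> float:
    """Per-patient EVPI from a draws-by-strategies NMB matrix; always >= 0."""
    m = np.asarray(nmb_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("nmb matrix must be draws x strategies")
    if not np.all(np.isfinite(m)):
        raise ValueError("nmb matrix must be finite")
    if m.shape[1] < 2:
        logger.warning("single strategy: EVPI is 0 by construction")
        return 0.0
    # mean-of-max >= max-of-mean holds exactly; clip the floating-point
    # cancellation error when one strategy wins every draw
    return max(float(m.max(axis=1).mean() - m.mean(axis=0).max()), 0.0)


def population_evpi(
    evpi_pp: float,
    annual_population: float,
    horizon_years: float,
    discount: float | None = None,
) -> float:
    """Scale per-patient EVPI to the population served over the horizon.

    Undiscounted (discount=None) the factor is simply ``horizon_years``;
    otherwise an annuity-due factor sum_{t=0..h-1} (1+d)^-t is used.
    """
    if evpi_pp < 0 or annual_population < 0 or horizon_years < 0:
        raise ValueError("inputs must be non-negative")
    if discount is None or discount == 0:
        factor = horizon_years
    else:
        t = np.arange(int(horizon_years))
        factor = float(np.sum((1.0 + discount) ** (-t)))
    return evpi_pp * annual_population * factor


def _spline_basis(x: np.ndarray, df: int) -> np.ndarray | None:
    """Cubic B-spline design matrix with ~df columns; None for constant x."""
    if np.ptp(x) == 0:
        return None
    k = 3
    n_interior = max(df - k - 1, 0)
    qs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    interior = np.unique(np.quantile(x, qs)) if n_interior else np.array([])
    lo, hi = float(x.min()), float(x.max())
    pad = 1e-9 * (hi - lo)
    t = np.r_[[lo - pad] * (k + 1), interior, [hi + pad] * (k + 1)]
    basis = BSpline.design_matrix(x, t, k, extrapolate=True).toarray()
    # B-splines are a partition of unity; drop one column per block so the
    # additive design stays identifiable next to the global intercept
    return basis[:, 1:]


def _fit_conditional_nmb(
    nmb: np.ndarray, X: pd.DataFrame, subset: list[str], df: int
) -> np.ndarray:
    """Fitted E[NMB_s | subset] per strategy via additive-spline OLS."""
    blocks = [np.ones((len(X), 1))]
    for name in subset:
        basis = _spline_basis(X[name].to_numpy(dtype=float), df)
        if basis is not None:
            blocks.append(basis)
    design = np.hstack(blocks)
    coef, _, rank, _ = np.linalg.lstsq(design, nmb, rcond=None)
    if rank < design.shape[1]:
        if df > 5:
            warnings.warn(
                f"rank-deficient EVPPI design ({rank}/{design.shape[1]}); "
                f"reducing basis dimension to {df // 2}",
                stacklevel=2,
            )
            return _fit_conditional_nmb(nmb, X, subset, df // 2)
        warnings.warn("rank-deficient EVPPI design at minimal basis; using lstsq fit",
                      stacklevel=2)
    return design @ coef


def evppi(
    nmb_matrix,
    param_draws: pd.DataFrame,
    subset: list[str] | str,
    df_per_param: int | None = None,
) -> float:
    """Per-patient EVPPI of a parameter subset (regression estimator).

    ``param_draws`` holds the sampled parameter values aligned row-for-row
    with the NMB matrix.  Clipped at zero (the estimand is non-negative;
    small negative estimates are Monte-Carlo noise).
    """
    if isinstance(subset, str):
        subset = [subset]
    if not subset:
        raise ValueError("subset must be non-empty")
    missing = [s for s in subset if s not in param_draws.columns]
    if missing:
        raise ValueError(f"unknown parameters {missing}")
    m = np.asarray(nmb_matrix, dtype=float)
    n = m.shape[0]
    if len(param_draws) != n:
        raise ValueError("parameter draws not aligned with NMB matrix")
    if n < 500:
        logger.warning("EVPPI with %d draws; >= 500 recommended", n)
    if df_per_param is None:
        # ~n/20 basis functions shared across the subset, so large groups
        # do not overfit the regression on desk-scale draw counts
        df_per_param = int(np.clip(n // (20 * len(subset)), 4, 30))

    # fitting centred incremental NMBs improves conditioning; the EVPPI
    # formula is invariant to subtracting any function common to all arms
    centre = m.mean(axis=1, keepdims=True)
    fitted = _fit_conditional_nmb(m - centre, param_draws, subset, df_per_param)
    value = float(fitted.max(axis=1).mean() - fitted.mean(axis=0).max())
    return max(value, 0.0)


def evppi_ranking(
    nmb_matrix,
    param_draws: pd.DataFrame,
    subsets: dict[str, list[str]],
    annual_population: float,
    horizon_years: float,
    discount: float | None = None,
    df_per_param: int | None = None,
) -> pd.DataFrame:
    """EVPPI per named parameter/group, ranked, with population scaling."""
    rows = []
    for label, names in subsets.items():
        pp = evppi(nmb_matrix, param_draws, names, df_per_param)
        rows.append(
            {
                "subset": label,
                "evppi_per_patient": pp,
                "population_evppi": population_evpi(
                    pp, annual_population, horizon_years, discount
                ),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        "evppi_per_patient", ascending=False, kind="mergesort"
    )
    return out.reset_index(drop=True)
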