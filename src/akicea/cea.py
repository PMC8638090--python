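"""Cost-effectiveness aggregation: NMB, the ICER dominance frontier, CEACs.

The frontier follows the textbook incremental analysis: strategies are
sorted by mean cost, strictly dominated strategies (weakly more costly
and weakly less effective, at least one strict) are excluded, then
extendedly dominated strategies are removed until the incremental ICER
sequence is strictly increasing.  CEACs report, per willingness-to-pay
threshold, the fraction of PSA draws in which each strategy has the
highest net monetary benefit (ties broken by lower cost, then by
registration order, so curves are reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StrategyOutcome",
    "FrontierEntry",
    "nmb",
    "frontier",
    "ceac",
    "default_threshold_grid",
]


@dataclass
class StrategyOutcome:
    """Per-draw costs and QALYs for one strategy."""

    strategy_id: str
    costs: np.ndarray
    qalys: np.ndarray

    def __post_init__(self) -> None:
        self.costs = np.atleast_1d(np.asarray(self.costs, dtype=float))
        self.qalys = np.atleast_1d(np.asarray(self.qalys, dtype=float))
        if self.costs.shape != self.qalys.shape:
            raise ValueError("costs and qalys must have equal length")

    @classmethod
    def from_means(cls, strategy_id: str, cost: float, qaly: float) -> "StrategyOutcome":
        return cls(strategy_id, np.array([cost]), np.array([qaly]))

    @property
    def mean_cost(self) -> float:
        return float(self.costs.mean())

    @property
    def mean_qaly(self) -> float:
        return float(self.qalys.mean())


@dataclass(frozen=True)
class FrontierEntry:
    strategy_id: str
    status: str  # on_frontier | dominated | extendedly_dominated
    mean_cost: float
    mean_qaly: float
    icer_incremental: float | None
    icer_vs_reference: float | None


def nmb(cost, qaly, threshold: float):
    """Net monetary benefit threshold*QALY - cost."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return threshold * np.asarray(qaly, dtype=float) - np.asarray(cost, dtype=float)


def _icer(a: tuple[float, float], b: tuple[float, float]) -> float | None:
    """ICER of b versus a on (cost, qaly) means; None if QALYs equal."""
    dc, dq = b[0] - a[0], b[1] - a[1]
    if dq == 0:
        return None
    return dc / dq


def frontier(
    outcomes: list[StrategyOutcome],
    reference: str | None = None,
) -> list[FrontierEntry]:
    """Dominance classification and ICERs along the efficiency frontier.

    Returns one entry per input strategy (input order preserved).
    ``reference`` names the strategy against which per-strategy pairwise
    ICERs are reported (defaults to the cheapest strategy).
    """
    if not outcomes:
        raise ValueError("at least one strategy required")
    ids = [o.strategy_id for o in outcomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strategy ids")
    means = {o.strategy_id: (o.mean_cost, o.mean_qaly) for o in outcomes}

    # deterministic ordering: by cost, then descending QALY, then input order
    order = sorted(ids, key=lambda s: (means[s][0], -means[s][1], ids.index(s)))
    status = {s: "on_frontier" for s in ids}

    # strict dominance: weakly cheaper and weakly more effective, one strict
    for s in ids:
        cs, qs = means[s]
        for t in ids:
            if t == s:
                continue
            ct, qt = means[t]
            if ct <= cs and qt >= qs and (ct < cs or qt > qs):
                status[s] = "dominated"
                break

    # extended dominance: enforce strictly increasing incremental ICERs
    candidates = [s for s in order if status[s] == "on_frontier"]
    changed = True
    while changed and len(candidates) > 2:
        changed = False
        for k in range(1, len(candidates) - 1):
            lo, mid, hi = candidates[k - 1], candidates[k], candidates[k + 1]
            icer_in = _icer(means[lo], means[mid])
            icer_out = _icer(means[mid], means[hi])
            if icer_in is not None and icer_out is not None and icer_in >= icer_out:
                status[mid] = "extendedly_dominated"
                candidates.pop(k)
                changed = True
                break

    if reference is None:
        reference = order[0]
    if reference not in means:
        raise ValueError(f"unknown reference strategy {reference!r}")

    frontier_ids = [s for s in order if status[s] == "on_frontier"]
    icer_inc: dict[str, float | None] = {}
    for k, s in enumerate(frontier_ids):
        icer_inc[s] = None if k == 0 else _icer(means[frontier_ids[k - 1]], means[s])

    entries = []
    for s in ids:
        entries.append(
            FrontierEntry(
                strategy_id=s,
                status=status[s],
                mean_cost=means[s][0],
                mean_qaly=means[s][1],
                icer_incremental=icer_inc.get(s),
                icer_vs_reference=None if s == reference else _icer(means[reference], means[s]),
            )
        )
    return entries


def default_threshold_grid(top: float = 50_000.0, step: float = 500.0) -> np.ndarray:
    """£0..top in ``step`` increments; always includes £20,000."""
    grid = np.arange(0.0, top + step / 2, step)
    if 20_000.0 not in grid:
        grid = np.sort(np.append(grid, 20_000.0))
    return grid


def ceac(
    outcomes: list[StrategyOutcome],
    thresholds=None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    Multi-strategy probabilities are per-draw argmax-NMB frequencies
    (columns sum to 1 at every threshold).  If ``reference`` is given, an
    extra ``<id>_vs_<reference>`` column per non-reference strategy holds
    the pairwise probability that its NMB strictly exceeds the
    reference's.
    """
    if not outcomes:
        raise ValueError("at least one strategy required")
    n = len(outcomes[0].costs)
    if n == 0 or any(len(o.costs) != n for o in outcomes):
        raise ValueError("strategies must share a non-empty draw count")
    if thresholds is None:
        thresholds = default_threshold_grid()
    thresholds = np.asarray(thresholds, dtype=float)

    costs = np.column_stack([o.costs for o in outcomes])  # draws x strategies
    qalys = np.column_stack([o.qalys for o in outcomes])
    ids = [o.strategy_id for o in outcomes]
    ref_idx = ids.index(reference) if reference is not None else None

    rows = []
    for lam in thresholds:
        benefit = lam * qalys - costs
        # tie-break: max NMB, then lowest cost, then registration order
        best = benefit.max(axis=1, keepdims=True)
        tied = np.isclose(benefit, best, rtol=0.0, atol=1e-9)
        masked_cost = np.where(tied, costs, np.inf)
        winner = masked_cost.argmin(axis=1)  # argmin takes first index on ties
        row = {"threshold": lam}
        for j, sid in enumerate(ids):
            row[sid] = float(np.mean(winner == j))
        if ref_idx is not None:
            for j, sid in enumerate(ids):
                if j != ref_idx:
                    row[f"{sid}_vs_{ids[ref_idx]}"] = float(
                        np.mean(benefit[:, j] > benefit[:, ref_idx])
                    )
        rows.append(row)
    return pd.DataFrame(rows)
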