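"""NMB, dominance frontier and CEAC, checked against independent oracles."""

import numpy as np
import pytest

from akicea.cea import StrategyOutcome, ceac, default_threshold_grid, frontier, nmb
from akicea.synthetic import REFERENCE_BASECASE_MEANS


def oracle_frontier_ids(means: dict[str, tuple[float, float]]) -> set[str]:
    """Independent frontier oracle: a strategy is on the cost-effectiveness
    frontier iff it attains the strict maximum of lambda*QALY - cost for
    some willingness-to-pay lambda >= 0 (support-function / lower convex
    hull characterisation, structurally unlike sort-and-eliminate)."""
    ids = list(means)
    slopes = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            dq = means[b][1] - means[a][1]
            dc = means[b][0] - means[a][0]
            if dq != 0 and dc / dq > 0:
                slopes.append(dc / dq)
    slopes = sorted(set(slopes))
    lams = [0.0] + [
        0.5 * (x + y) for x, y in zip(slopes, slopes[1:])
    ] + ([slopes[-1] + 1.0] if slopes else [1.0])
    winners = set()
    for lam in lams:
        benefits = {s: lam * means[s][1] - means[s][0] for s in ids}
        best = max(benefits.values())
        tied = [s for s in ids if benefits[s] == best]
        if len(tied) == 1:
            winners.add(tied[0])
    return winners


class TestNmb:
    def test_break_even(self):
        assert nmb(20_000.0, 1.0, 20_000.0) == pytest.approx(0.0)

    def test_reference_arm_arithmetic(self):
        assert nmb(22_978.0, 6.07277, 20_000.0) == pytest.approx(98_477.4)

    def test_zero(self):
        assert nmb(0.0, 0.0, 35_000.0) == 0.0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            nmb(1.0, 1.0, -1.0)


class TestFrontier:
    def test_published_basecase_dominance_structure(self):
        """The published five-strategy means classify exactly the three
        NGAL strategies as dominated, leaving standard care and
        NephroCheck on the frontier."""
        outcomes = [
            StrategyOutcome.from_means(s, c, q)
            for s, (c, q) in REFERENCE_BASECASE_MEANS.items()
        ]
        entries = {e.strategy_id: e for e in frontier(outcomes, reference="standard_care")}
        assert entries["standard_care"].status == "on_frontier"
        assert entries["nephrocheck"].status == "on_frontier"
        for s in ("ngal_urine_bioporto", "ngal_plasma_bioporto", "ngal_urine_architect"):
            assert entries[s].status == "dominated"
        # incremental ICER from the printed (display-rounded) means
        assert entries["nephrocheck"].icer_incremental == pytest.approx(
            38.0 / 0.00036, rel=1e-6
        )

    def test_single_strategy(self):
        [entry] = frontier([StrategyOutcome.from_means("only", 100.0, 1.0)])
        assert entry.status == "on_frontier"
        assert entry.icer_incremental is None

    def test_extended_dominance(self):
        # B lies above the A-C hull segment: ICER(A->B) > ICER(B->C)
        outcomes = [
            StrategyOutcome.from_means("A", 0.0, 0.0),
            StrategyOutcome.from_means("B", 100.0, 1.0),
            StrategyOutcome.from_means("C", 150.0, 3.0),
        ]
        entries = {e.strategy_id: e for e in frontier(outcomes)}
        assert entries["B"].status == "extendedly_dominated"
        assert entries["A"].status == entries["C"].status == "on_frontier"
        assert entries["C"].icer_incremental == pytest.approx(50.0)

    def test_frontier_icers_strictly_increase(self):
        rng = np.random.default_rng(1)
        outcomes = [
            StrategyOutcome.from_means(f"s{i}", rng.uniform(0, 1e4), rng.uniform(0, 5))
            for i in range(20)
        ]
        entries = frontier(outcomes)
        icers = [
            e.icer_incremental for e in sorted(entries, key=lambda e: e.mean_cost)
            if e.status == "on_frontier" and e.icer_incremental is not None
        ]
        assert all(a < b for a, b in zip(icers, icers[1:]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_support_function_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        means = {
            f"s{i}": (float(rng.uniform(0, 1e4)), float(rng.uniform(0, 5)))
            for i in range(n)
        }
        outcomes = [StrategyOutcome.from_means(s, c, q) for s, (c, q) in means.items()]
        got = {e.strategy_id for e in frontier(outcomes) if e.status == "on_frontier"}
        assert got == oracle_frontier_ids(means)

    def test_removing_dominated_strategy_preserves_classification(self):
        rng = np.random.default_rng(3)
        outcomes = [
            StrategyOutcome.from_means(f"s{i}", rng.uniform(0, 1e4), rng.uniform(0, 5))
            for i in range(12)
        ]
        full = {e.strategy_id: e.status for e in frontier(outcomes)}
        dominated = [s for s, st in full.items() if st == "dominated"]
        reduced = [o for o in outcomes if o.strategy_id != dominated[0]]
        partial = {e.strategy_id: e.status for e in frontier(reduced)}
        for s, st in partial.items():
            assert st == full[s]


class TestCeac:
    def _toy_outcomes(self, n=1000, seed=5):
        rng = np.random.default_rng(seed)
        return [
            StrategyOutcome("a", rng.normal(1000, 200, n), rng.normal(1.0, 0.2, n)),
            StrategyOutcome("b", rng.normal(1200, 200, n), rng.normal(1.1, 0.2, n)),
            StrategyOutcome("c", rng.normal(900, 300, n), rng.normal(0.9, 0.3, n)),
        ]

    def test_probabilities_sum_to_one(self):
        curves = ceac(self._toy_outcomes(), thresholds=[0, 10_000, 20_000, 50_000])
        totals = curves[["a", "b", "c"]].sum(axis=1)
        np.testing.assert_allclose(totals, 1.0, atol=1e-12)

    def test_matches_argmax_counting_oracle(self):
        outcomes = self._toy_outcomes()
        lam = 20_000.0
        curves = ceac(outcomes, thresholds=[lam])
        # oracle: per-draw argmax count over the NMB matrix
        m = np.column_stack([lam * o.qalys - o.costs for o in outcomes])
        counts = np.bincount(m.argmax(axis=1), minlength=3) / len(m)
        for j, sid in enumerate(["a", "b", "c"]):
            assert curves[sid].iloc[0] == pytest.approx(counts[j])

    def test_dominant_strategy_has_probability_one(self):
        a = StrategyOutcome("a", np.full(100, 100.0), np.full(100, 2.0))
        b = StrategyOutcome("b", np.full(100, 200.0), np.full(100, 1.0))
        curves = ceac([a, b], thresholds=[0, 20_000])
        assert (curves["a"] == 1.0).all()

    def test_identical_strategies_tie_break_deterministic(self):
        x_c, x_q = np.full(50, 100.0), np.full(50, 1.0)
        curves = ceac(
            [StrategyOutcome("first", x_c, x_q), StrategyOutcome("second", x_c, x_q)],
            thresholds=[20_000],
        )
        assert curves["first"].iloc[0] == 1.0
        assert curves["second"].iloc[0] == 0.0

    def test_pairwise_variant_against_reference(self):
        outcomes = self._toy_outcomes()
        lam = 20_000.0
        curves = ceac(outcomes, thresholds=[lam], reference="a")
        nmb_m = np.column_stack([lam * o.qalys - o.costs for o in outcomes])
        expected = float(np.mean(nmb_m[:, 1] > nmb_m[:, 0]))
        assert curves["b_vs_a"].iloc[0] == pytest.approx(expected)

    def test_threshold_grid_includes_wtp(self):
        grid = default_threshold_grid()
        assert 20_000.0 in grid
        assert grid[0] == 0.0
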