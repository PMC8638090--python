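"""Markov cohort engine: matrix construction, half-cycle correction,
discounting, and an independently coded trace oracle."""

import numpy as np
import pytest

from akicea.markov import (
    Lifetable,
    StateValues,
    TransitionSpec,
    UtilityNorms,
    adjust_utility,
    build_matrix,
    run_cohort,
)

AGES = np.arange(0, 102, dtype=float)


def flat_lifetable(qx: float) -> Lifetable:
    q = np.full(len(AGES), qx)
    return Lifetable(ages=AGES, qx_male=q, qx_female=q)


def flat_norms(value: float = 1.0) -> UtilityNorms:
    v = np.full(len(AGES), value)
    return UtilityNorms(ages=AGES, norm_male=v, norm_female=v)


def identity_spec(rr=(1.0, 1.0, 1.0, 1.0, 1.0)) -> TransitionSpec:
    return TransitionSpec(base=np.eye(5), mortality_rr=rr)


def toy_spec() -> TransitionSpec:
    base = np.eye(5)
    base[0, 0], base[0, 1] = 0.97, 0.03
    base[1, 1], base[1, 2] = 0.95, 0.05
    base[2, 2], base[2, 3] = 0.7, 0.3
    base[3, 3], base[3, 4] = 0.92, 0.08
    base[4, 4], base[4, 3] = 0.96, 0.04
    return TransitionSpec(base=base, mortality_rr=(1.0, 1.4, 2.5, 6.0, 1.8))


VALUES = StateValues(
    costs=(150.0, 900.0, 4000.0, 28_000.0, 8000.0),
    utilities=(0.82, 0.74, 0.62, 0.60, 0.71),
)


class TestBuildMatrix:
    def test_reduces_to_lifetable_when_rr_one(self):
        lt = flat_lifetable(0.05)
        P = build_matrix(70, 0.5, identity_spec(), lt)
        np.testing.assert_allclose(P[:5, 5], 0.05)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_mortality_returns_base(self):
        spec = toy_spec()
        P = build_matrix(70, 0.5, spec, flat_lifetable(0.0))
        np.testing.assert_allclose(P[:5, :5], spec.base)
        np.testing.assert_allclose(P[:5, 5], 0.0)

    def test_relative_risk_on_survival_scale(self):
        # RR = 2 at qx = 0.1: death probability 1 - 0.9^2 = 0.19
        spec = identity_spec(rr=(2.0, 1.0, 1.0, 1.0, 1.0))
        P = build_matrix(70, 0.5, spec, flat_lifetable(0.1))
        assert P[0, 5] == pytest.approx(0.19)
        assert P[0, 0] == pytest.approx(0.81)

    def test_sex_mix_interpolates_lifetable(self):
        lt = Lifetable(
            ages=AGES,
            qx_male=np.full(len(AGES), 0.2),
            qx_female=np.full(len(AGES), 0.1),
        )
        assert lt.qx(70, 0.543) == pytest.approx(0.543 * 0.1 + 0.457 * 0.2)

    def test_structural_zero_violation_rejected(self):
        base = np.eye(5)
        base[1, 0], base[1, 1] = 0.1, 0.9  # CKD -> No CKD reversion
        with pytest.raises(ValueError, match="structural"):
            TransitionSpec(base=base, mortality_rr=(1.0,) * 5)


class TestAdjustUtility:
    def test_identity_at_reference_age(self):
        norms = flat_norms(0.9)
        assert adjust_utility(0.8, 63, 0.5, norms, 63) == pytest.approx(0.8)

    def test_proportional_to_norm_ratio(self):
        v = np.full(len(AGES), 0.9)
        v[AGES >= 80] = 0.45
        norms = UtilityNorms(ages=AGES, norm_male=v, norm_female=v)
        assert adjust_utility(0.8, 85, 0.5, norms, 63) == pytest.approx(0.4)

    def test_arithmetic(self):
        v = np.where(AGES >= 80, 0.72, 0.8)
        norms = UtilityNorms(ages=AGES, norm_male=v, norm_female=v)
        assert adjust_utility(0.8, 85, 0.5, norms, 63) == pytest.approx(0.72)


class TestRunCohort:
    def test_immediate_absorption_credits_half_cycle(self):
        """qx = 1: everyone dies in cycle 1; the trapezoidal correction
        credits exactly half the first-cycle utility, then nothing."""
        res = run_cohort(
            (1.0, 0.0), identity_spec(), flat_lifetable(1.0), VALUES,
            flat_norms(), start_age=63, female_fraction=0.5, discount=0.0,
        )
        assert res.discounted_qaly == pytest.approx(0.5 * 0.82)
        assert res.trace.iloc[1]["death"] == pytest.approx(1.0)

    def test_constant_occupancy_undiscounted(self):
        """Identity transitions, no mortality, flat norms: QALY = u * T."""
        res = run_cohort(
            (1.0, 0.0), identity_spec(), flat_lifetable(0.0), VALUES,
            flat_norms(), start_age=63, female_fraction=0.5, discount=0.0,
            age_cap=83,
        )
        assert res.discounted_qaly == pytest.approx(0.82 * 20)
        assert res.discounted_cost == pytest.approx(150.0 * 20)

    def test_constant_occupancy_geometric_series(self):
        """Discounted constant occupancy matches the closed-form geometric
        series u * sum_{t=1..T} (1+d)^-(t-1)."""
        d, T = 0.035, 20
        res = run_cohort(
            (1.0, 0.0), identity_spec(), flat_lifetable(0.0), VALUES,
            flat_norms(), start_age=63, female_fraction=0.5, discount=d,
            age_cap=63 + T,
        )
        annuity = sum((1 + d) ** -(t - 1) for t in range(1, T + 1))
        assert res.discounted_qaly == pytest.approx(0.82 * annuity, rel=1e-12)

    def test_matches_independent_trace_oracle(self):
        """Engine totals agree to 1e-10 with a plain dict-based
        reimplementation of the cohort trace on the toy chain."""
        spec, lt = toy_spec(), flat_lifetable(0.02)
        ages = AGES
        norm_curve = np.clip(0.95 - 0.003 * np.maximum(ages - 25, 0), 0.3, 1.0)
        norms = UtilityNorms(ages=ages, norm_male=norm_curve, norm_female=norm_curve)
        start_age, d, cap, ff = 63, 0.035, 100, 0.543
        res = run_cohort(
            (0.8, 0.2), spec, lt, VALUES, norms,
            start_age=start_age, female_fraction=ff, discount=d, age_cap=cap,
        )

        # oracle: explicit per-state bookkeeping, no shared code path
        occ = {"no_ckd": 0.8, "ckd": 0.2, "esrd": 0.0, "dialysis": 0.0,
               "transplant": 0.0, "death": 0.0}
        names = list(occ)
        rrs = dict(zip(names[:5], spec.mortality_rr))
        cost_o = qaly_o = 0.0
        for t in range(1, cap - start_age + 1):
            age = start_age + t - 1
            qx = 0.02
            nxt = {s: 0.0 for s in names}
            nxt["death"] = occ["death"]
            for i, s in enumerate(names[:5]):
                die = 1 - (1 - qx) ** rrs[s]
                for j, s2 in enumerate(names[:5]):
                    nxt[s2] += occ[s] * spec.base[i, j] * (1 - die)
                nxt["death"] += occ[s] * die
            ratio = float(
                np.interp(age, ages, norm_curve) / np.interp(start_age, ages, norm_curve)
            )
            disc = (1 + d) ** -(t - 1)
            for i, s in enumerate(names[:5]):
                mid = 0.5 * (occ[s] + nxt[s])
                cost_o += disc * mid * VALUES.costs[i]
                qaly_o += disc * mid * min(VALUES.utilities[i] * ratio, 1.0)
            occ = nxt
        assert res.discounted_cost == pytest.approx(cost_o, abs=1e-10)
        assert res.discounted_qaly == pytest.approx(qaly_o, abs=1e-10)

    def test_occupancy_conserved_and_death_monotone(self):
        res = run_cohort(
            (0.7, 0.3), toy_spec(), flat_lifetable(0.03), VALUES, flat_norms(),
            start_age=63, female_fraction=0.5,
        )
        sums = res.trace.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-10)
        assert (res.trace["death"].diff().dropna() >= -1e-12).all()

    def test_no_reversion_to_milder_states(self):
        """Mass starting in CKD never reaches No CKD."""
        res = run_cohort(
            (0.0, 1.0), toy_spec(), flat_lifetable(0.02), VALUES, flat_norms(),
            start_age=63, female_fraction=0.5,
        )
        assert (res.trace["no_ckd"] == 0.0).all()

    def test_discounting_reduces_totals(self):
        kwargs = dict(
            start_split=(0.8, 0.2), spec=toy_spec(), lifetable=flat_lifetable(0.02),
            values=VALUES, norms=flat_norms(), start_age=63, female_fraction=0.5,
        )
        undisc = run_cohort(**kwargs, discount=0.0)
        disc = run_cohort(**kwargs, discount=0.035)
        assert disc.discounted_cost <= undisc.discounted_cost
        assert disc.discounted_qaly <= undisc.discounted_qaly

    def test_invalid_start_split_rejected(self):
        with pytest.raises(ValueError):
            run_cohort(
                (0.5, 0.2), identity_spec(), flat_lifetable(0.0), VALUES,
                flat_norms(), start_age=63, female_fraction=0.5,
            )
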