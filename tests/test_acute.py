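"""90-day decision tree: bundle effects, attenuation, branch arithmetic."""

import numpy as np
import pytest

from akicea.acute import (
    AcuteInputs,
    AcuteOutcomeTable,
    AcuteUtilities,
    AttenuationFractions,
    BundleEffect,
    StageDistribution,
    StrategySpec,
    UnitCosts,
    apply_bundle,
    attenuate,
    day90_ckd_share,
    evaluate_arm,
)

QALY_CAP = 90.0 / 365.25


def make_inputs(**overrides) -> AcuteInputs:
    defaults = dict(
        prevalence=0.2,
        stage_dist=StageDistribution((0.5, 0.3, 0.2)),
        outcomes=AcuteOutcomeTable(
            p_icu=(0.02, 0.06, 0.12, 0.35),
            p_rrt=(0.0, 0.004, 0.02, 0.15),
            ward_los=(6.0, 9.0, 12.0, 16.0),
            icu_los=(3.0, 4.0, 6.0, 9.0),
            p_death90=(0.04, 0.12, 0.20, 0.33),
            p_ckd90=(0.1105, 0.21, 0.28, 0.42),
        ),
        bundle=BundleEffect(arr=0.166, bundle_cost=106.36),
        attenuation=AttenuationFractions(),
        costs=UnitCosts(ward_day=346.0, icu_day=1306.0, rrt_episode=3000.0),
        utilities=AcuteUtilities(in_hospital=0.6, post_discharge=0.73),
    )
    defaults.update(overrides)
    return AcuteInputs(**defaults)


class TestAttenuate:
    @pytest.mark.parametrize(
        "f,expected", [(0.0, 0.3), (1.0, 0.1), (0.5, 0.2)],
        ids=["none", "full", "half"],
    )
    def test_interpolation(self, f, expected):
        assert attenuate(0.3, 0.1, f) == pytest.approx(expected)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            attenuate(0.3, 0.1, 1.5)


class TestApplyBundle:
    def test_null_effect_is_identity(self):
        stages = StageDistribution((0.5, 0.3, 0.2))
        prev, out = apply_bundle(0.4, stages, BundleEffect(arr=0.0), can_avert=True)
        assert prev == 0.4
        np.testing.assert_allclose(out.as_array(), stages.as_array())

    def test_published_arr_reduces_prevalence_absolutely(self):
        prev, _ = apply_bundle(
            0.5, StageDistribution((0.5, 0.3, 0.2)), BundleEffect(arr=0.166), True
        )
        assert prev == pytest.approx(0.334)

    def test_cannot_avert_leaves_prevalence(self):
        prev, _ = apply_bundle(
            0.5, StageDistribution((0.5, 0.3, 0.2)), BundleEffect(arr=0.166), False
        )
        assert prev == 0.5

    def test_full_downshift_operator(self):
        # stage 3 -> 2, stage 2 -> 1, stage 1 stays
        shift = np.array([[1.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]])
        _, out = apply_bundle(
            0.5,
            StageDistribution((0.5, 0.3, 0.2)),
            BundleEffect(arr=0.0, severity_shift=shift),
            can_avert=False,
        )
        np.testing.assert_allclose(out.as_array(), [0.8, 0.2, 0.0])

    def test_arr_above_prevalence_is_capped(self):
        prev, _ = apply_bundle(
            0.1, StageDistribution((1.0, 0.0, 0.0)), BundleEffect(arr=0.5), True
        )
        assert prev == 0.0

    def test_upshift_operator_rejected(self):
        shift = np.array([[0.5, 0.5, 0], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(ValueError):
            BundleEffect(arr=0.1, severity_shift=shift)


class TestEvaluateArm:
    def _standard(self, inputs):
        return evaluate_arm(StrategySpec("standard_care"), inputs)

    def test_branch_weights_sum_to_one(self):
        inputs = make_inputs()
        arm = StrategySpec("t", accuracy_param="acc_t", can_avert_aki=True,
                           test_unit_cost=60.0)
        res = evaluate_arm(arm, inputs, 0.75, 0.61)
        assert res.branch_audit["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_useless_test_equals_standard_care_plus_test_cost(self):
        """Se = 0, Sp = 1: the test changes nothing but adds its own cost."""
        inputs = make_inputs()
        std = self._standard(inputs)
        arm = StrategySpec("t", accuracy_param="acc_t", test_unit_cost=42.0)
        res = evaluate_arm(arm, inputs, 0.0, 1.0)
        assert res.expected_qaly_90d == pytest.approx(std.expected_qaly_90d, abs=1e-12)
        assert res.expected_cost_90d - std.expected_cost_90d == pytest.approx(42.0)
        assert res.survivor_fraction == pytest.approx(std.survivor_fraction, abs=1e-12)

    def test_perfect_test_perfect_prevention(self):
        """Se = Sp = 1, full aversion, full effect fractions: every AKI
        patient realises the no-AKI outcomes."""
        inputs = make_inputs(
            bundle=BundleEffect(arr=1.0, bundle_cost=0.0),
            attenuation=AttenuationFractions(1.0, 1.0, 1.0, 1.0),
        )
        no_aki = make_inputs(prevalence=0.0)
        arm = StrategySpec("t", accuracy_param="acc_t", can_avert_aki=True)
        res = evaluate_arm(arm, inputs, 1.0, 1.0)
        ref = self._standard(no_aki)
        assert res.expected_qaly_90d == pytest.approx(ref.expected_qaly_90d, abs=1e-12)
        assert res.survivor_fraction == pytest.approx(ref.survivor_fraction, abs=1e-12)

    def test_zero_prevalence_branch_arithmetic(self):
        """p = 0, Sp = 0.5: cost = standard + test + half the bundle."""
        inputs = make_inputs(prevalence=0.0)
        std = self._standard(inputs)
        arm = StrategySpec("t", accuracy_param="acc_t", test_unit_cost=30.0)
        res = evaluate_arm(arm, inputs, 0.75, 0.5)
        expected = std.expected_cost_90d + 30.0 + 0.5 * inputs.bundle.bundle_cost
        assert res.expected_cost_90d == pytest.approx(expected)

    def test_qaly_bounded_by_interval(self):
        for prev in (0.0, 0.2, 0.9):
            res = self._standard(make_inputs(prevalence=prev))
            assert 0.0 <= res.expected_qaly_90d <= QALY_CAP

    def test_cost_nondecreasing_in_prevalence(self):
        costs = [
            self._standard(make_inputs(prevalence=p)).expected_cost_90d
            for p in np.linspace(0.0, 0.9, 10)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(costs, costs[1:]))

    def test_fp_mortality_rr_scales_fp_branch_only(self):
        inputs = make_inputs()
        arm = StrategySpec("t", accuracy_param="acc_t", fp_mortality_rr=1.5)
        res = evaluate_arm(arm, inputs, 0.75, 0.61)
        audit = res.branch_audit
        fp = audit[audit["branch"] == "FP"]
        base_death = inputs.outcomes.p_death90[0]
        assert fp["p_death90"].iloc[0] == pytest.approx(1.5 * base_death)
        tn = audit[audit["branch"] == "TN"]
        assert tn["p_death90"].iloc[0] == pytest.approx(base_death)


class TestDay90Handoff:
    def test_no_aki_cohort_keeps_background_prevalence(self):
        assert day90_ckd_share(0.1105, [0, 0, 0], [2, 3, 5], aki_fraction=0.0) == (
            pytest.approx(0.1105)
        )

    def test_hand_computed_hazard_weighted_share(self):
        # background 0.1, stage mix (0.5, 0.3, 0.2), HRs (2, 3, 5):
        # 0.1 + 0.5*0.1*1 + 0.3*0.1*2 + 0.2*0.1*4 = 0.29
        share = day90_ckd_share(0.1, [0.5, 0.3, 0.2], [2.0, 3.0, 5.0])
        assert share == pytest.approx(0.29)

    def test_share_clamped_into_unit_interval(self):
        assert day90_ckd_share(0.5, [1.0, 0, 0], [10.0, 1, 1]) == 1.0

    def test_no_ckd_effect_equalises_arms(self):
        """f_ckd = 0 with f_mort = 0: the test arm's day-90 CKD share
        equals standard care's (no realised CKD benefit)."""
        inputs = make_inputs(
            attenuation=AttenuationFractions(f_ckd=0.0, f_icu=0.5, f_los=0.5, f_mort=0.0)
        )
        std = evaluate_arm(StrategySpec("standard_care"), inputs)
        arm = StrategySpec("t", accuracy_param="acc_t", can_avert_aki=True)
        res = evaluate_arm(arm, inputs, 0.75, 0.61)
        assert res.day90_state_split["ckd"] == pytest.approx(
            std.day90_state_split["ckd"], abs=1e-12
        )
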