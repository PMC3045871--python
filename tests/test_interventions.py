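"""Medication and health-promotion intervention models."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sbpsim import (
    ConfigurationError,
    IntegrationGrid,
    MedicationPolicy,
    PromotionPolicy,
    RiskModel,
    SBPDistribution,
    SuccessRateTable,
    aggregate_success_rate,
    consultation_probability_density,
    consultation_rate,
    cumulative_ir,
    post_medication_ir,
    post_promotion_ir,
    post_promotion_ir_closed_form,
    promoted_individual_ir,
    sbp_lowering_effect,
    treated_individual_ir,
)

OPTIMISTIC = MedicationPolicy(alarm=140, access=0.03, target=140,
                              adherence=0.7, initiation=150)
IDEAL = MedicationPolicy(alarm=130, access=0.05, target=130,
                         adherence=0.8, initiation=140)


class TestConsultationRate:
    def test_worked_example(self):
        # hypertensive at 160 mm Hg under a=140, b=0.03 consults with p=0.45
        assert consultation_rate(160.0, OPTIMISTIC) == pytest.approx(0.4512, abs=5e-5)

    def test_zero_at_alarm_and_clamped_below(self):
        assert consultation_rate(140.0, OPTIMISTIC) == 0.0
        assert consultation_rate(100.0, OPTIMISTIC) == 0.0

    def test_direct_formula_above_alarm(self):
        policy = MedicationPolicy(alarm=130, access=0.05, target=130,
                                  adherence=0.8, initiation=140)
        assert consultation_rate(180.0, policy) == pytest.approx(
            1.0 - math.exp(-2.5), rel=1e-12
        )

    @given(st.floats(min_value=0.0, max_value=300.0))
    def test_bounded_in_unit_interval(self, x):
        assert 0.0 <= consultation_rate(x, OPTIMISTIC) <= 1.0

    def test_complement_is_nonconsulting_rate(self):
        # above the alarm SBP, 1 - s(x) = exp(-(x-a) b)
        x = np.linspace(140.0, 250.0, 23)
        assert np.allclose(
            1.0 - consultation_rate(x, OPTIMISTIC),
            np.exp(-(x - 140.0) * 0.03),
        )


class TestConsultationDensity:
    def test_zero_below_alarm(self, dist):
        assert consultation_probability_density(120.0, dist, OPTIMISTIC) == 0.0

    def test_product_of_verified_factors(self, dist):
        value = consultation_probability_density(160.0, dist, OPTIMISTIC)
        assert value == pytest.approx(0.006477 * 0.4512, rel=1e-3)

    def test_integral_bounded_by_one(self, dist, grid):
        x = grid.points()
        total = np.trapezoid(
            consultation_probability_density(x, dist, OPTIMISTIC), x
        )
        assert total <= 1.0


class TestLoweringEffect:
    def test_worked_example_seven_mmhg(self):
        assert sbp_lowering_effect(160.0, OPTIMISTIC) == pytest.approx(7.0)

    def test_zero_at_target_and_below(self):
        assert sbp_lowering_effect(140.0, OPTIMISTIC) == 0.0
        assert sbp_lowering_effect(120.0, OPTIMISTIC) == 0.0

    def test_ideal_patient(self):
        assert sbp_lowering_effect(180.0, IDEAL) == pytest.approx(20.0)

    @given(st.floats(min_value=140.0, max_value=300.0))
    def test_treated_sbp_never_below_target(self, x):
        assert sbp_lowering_effect(x, OPTIMISTIC) <= x - OPTIMISTIC.target


class TestIndividualRates:
    def test_treated_worked_example(self, risk):
        # 160 mm Hg -> effective 153 mm Hg -> ~0.019 events/year
        assert treated_individual_ir(160.0, risk, OPTIMISTIC) == pytest.approx(
            0.019, abs=5e-4
        )

    def test_zero_adherence_leaves_risk_unchanged(self, risk):
        policy = MedicationPolicy(adherence=0.0)
        assert treated_individual_ir(160.0, risk, policy) == pytest.approx(
            risk.risk_at(160.0), rel=1e-12
        )

    def test_ideal_composition(self, risk):
        policy = MedicationPolicy(alarm=130, access=0.05, target=130,
                                  adherence=0.8, initiation=140)
        assert treated_individual_ir(180.0, risk, policy) == pytest.approx(
            risk.risk_at(160.0), rel=1e-12
        )

    def test_below_initiation_rejected(self, risk):
        with pytest.raises(ValueError, match="e="):
            treated_individual_ir(140.0, risk, OPTIMISTIC)

    def test_promotion_shifted_worked_example(self, risk):
        # 160 mm Hg shifted to 155 mm Hg -> ~0.021 events/year
        policy = PromotionPolicy(alpha=10.0, beta=0.275)
        assert promoted_individual_ir(160.0, risk, policy) == pytest.approx(
            0.021, abs=5e-4
        )


class TestPolicyValidation:
    def test_medication_invariants(self):
        with pytest.raises(ConfigurationError, match="access"):
            MedicationPolicy(access=0.0)
        with pytest.raises(ConfigurationError, match="adherence"):
            MedicationPolicy(adherence=1.5)
        with pytest.raises(ConfigurationError, match="initiation"):
            MedicationPolicy(target=150.0, initiation=140.0)

    def test_promotion_invariants(self):
        with pytest.raises(ConfigurationError, match="alpha"):
            PromotionPolicy(alpha=-1.0)
        with pytest.raises(ConfigurationError, match="beta"):
            PromotionPolicy(beta=1.5)
        with pytest.raises(ConfigurationError, match="contribution"):
            PromotionPolicy(contribution=0.0)


class TestSuccessRateTable:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (SuccessRateTable.realistic(), 0.1375),
            (SuccessRateTable.optimistic(), 0.275),
            (SuccessRateTable.ideal(), 0.50),
            (SuccessRateTable.campaign(0.0, 0.0, 0.0), 0.0),
        ],
    )
    def test_aggregation(self, table, expected):
        assert aggregate_success_rate(table) == pytest.approx(expected, abs=1e-15)

    def test_invalid_shares_rejected(self):
        with pytest.raises(ConfigurationError, match="sum"):
            SuccessRateTable((("a", 0.5, 0.1), ("b", 0.4, 0.1)))
        with pytest.raises(ConfigurationError, match="success rate"):
            SuccessRateTable((("a", 1.0, 1.5),))


class TestPostMedication:
    def test_nobody_consults_restores_baseline(self, dist, risk, grid):
        policy = MedicationPolicy(access=1e-12)
        assert post_medication_ir(dist, risk, policy, grid) == pytest.approx(
            cumulative_ir(dist, risk, grid), rel=1e-9
        )

    def test_optimistic_flagship_reduction(self, dist, risk, grid):
        delta = cumulative_ir(dist, risk, grid) - post_medication_ir(
            dist, risk, OPTIMISTIC, grid
        )
        assert delta == pytest.approx(9.99e-4, rel=0.02)

    def test_ideal_flagship_reduction(self, dist, risk, grid):
        delta = cumulative_ir(dist, risk, grid) - post_medication_ir(
            dist, risk, IDEAL, grid
        )
        assert delta == pytest.approx(2.33e-3, rel=0.02)

    def test_initiation_outside_grid_rejected(self, dist, risk):
        small = IntegrationGrid(lower=10.0, upper=140.0, step=1.0)
        with pytest.raises(ConfigurationError, match="initiation"):
            post_medication_ir(dist, risk, OPTIMISTIC, small)

    def test_matches_fine_simpson_reference(self, dist, risk, grid, fine_grid):
        coarse = post_medication_ir(dist, risk, OPTIMISTIC, grid)
        fine = post_medication_ir(dist, risk, OPTIMISTIC, fine_grid, "simpson")
        assert abs(coarse - fine) / fine < 1e-3

    @given(
        access=st.floats(min_value=5e-3, max_value=0.2),
        adherence=st.floats(min_value=0.0, max_value=1.0),
        initiation=st.floats(min_value=140.0, max_value=180.0),
    )
    def test_dominance(self, access, adherence, initiation):
        # tolerance covers the node inserted at a non-grid-aligned threshold
        dist, risk, grid = SBPDistribution(), RiskModel(), IntegrationGrid()
        policy = MedicationPolicy(alarm=140.0, access=access, target=140.0,
                                  adherence=adherence, initiation=initiation)
        post = post_medication_ir(dist, risk, policy, grid)
        baseline = cumulative_ir(dist, risk, grid)
        assert post <= baseline + 1e-7
        if adherence > 0.05:
            assert post < baseline


class TestPostPromotion:
    def test_null_policies_leave_baseline(self, dist, risk, grid):
        baseline = cumulative_ir(dist, risk, grid)
        for policy in (PromotionPolicy(beta=0.0), PromotionPolicy(alpha=0.0)):
            assert post_promotion_ir(dist, risk, policy, grid) == pytest.approx(
                baseline, rel=1e-12
            )

    def test_optimistic_matches_mixture_closed_form(self, dist, risk, grid):
        policy = PromotionPolicy(alpha=10.0, beta=0.275)
        expected = 0.01 * (1.0 - 0.275 * (1.0 - math.exp(-0.25)))
        assert post_promotion_ir(dist, risk, policy, grid) == pytest.approx(
            expected, rel=1e-3
        )

    def test_closed_form_reference_values(self, dist, risk):
        base = post_promotion_ir_closed_form(dist, risk, PromotionPolicy(alpha=0.0))
        assert base == pytest.approx(0.01, rel=1e-12)
        # full uptake with alpha*contribution = 2k reduces to pure e^-2 rescaling
        full = PromotionPolicy(alpha=80.0, beta=1.0, contribution=0.5)
        assert post_promotion_ir_closed_form(dist, risk, full) == pytest.approx(
            0.01 * math.exp(-2.0), rel=1e-12
        )
        half = PromotionPolicy(alpha=20.0, beta=0.5, contribution=0.5)
        assert post_promotion_ir_closed_form(dist, risk, half) == pytest.approx(
            8.033e-3, rel=1e-3
        )

    @given(
        alpha=st.floats(min_value=0.0, max_value=40.0),
        beta=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_quadrature_matches_closed_form(self, alpha, beta):
        dist, risk, grid = SBPDistribution(), RiskModel(), IntegrationGrid()
        policy = PromotionPolicy(alpha=alpha, beta=beta)
        quad = post_promotion_ir(dist, risk, policy, grid)
        closed = post_promotion_ir_closed_form(dist, risk, policy)
        assert abs(quad - closed) / closed < 1e-3

    def test_reduction_linear_in_beta(self, dist, risk, grid):
        baseline = cumulative_ir(dist, risk, grid)
        deltas = [
            baseline - post_promotion_ir(
                dist, risk, PromotionPolicy(alpha=10.0, beta=b), grid
            )
            for b in (0.1375, 0.275, 0.50)
        ]
        assert deltas[1] / deltas[0] == pytest.approx(2.0, rel=1e-9)
        assert deltas[2] / deltas[0] == pytest.approx(50 / 13.75, rel=1e-9)
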