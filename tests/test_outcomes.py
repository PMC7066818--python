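"""Valuation: discounting, QALYs, costs, friction, ICER and reporting."""

import copy

import numpy as np
import pytest

import healthecon as he
from healthecon.markov_engine import CohortTrace
from healthecon.outcomes import (
    CostBreakdown,
    ValueTables,
    state_annual_cost,
    state_utility,
    _cohort_outcome,
)
from healthecon.parampack import (
    HealthState,
    STATE_INDEX,
    N_STATES,
    FrictionParams,
)


class TestRelapseAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.0, 0.9), (1.0, 0.7), (0.1, 0.88)],
    )
    def test_weighted_mean(self, p, expected):
        assert he.relapse_adjust(0.7, 0.9, p) == pytest.approx(expected)

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            he.relapse_adjust(0.7, 0.9, 1.5)


class TestDiscountFactor:
    def test_zero_rate_is_one(self):
        assert he.discount_factor(0.0, 10) == 1.0

    def test_cost_rate_first_cycle(self):
        assert he.discount_factor(0.03, 1) == pytest.approx(0.970874, abs=1e-6)

    def test_child_lead_time_shrinks_effects(self):
        child = he.discount_factor(0.015, 5, lead=22)
        parent = he.discount_factor(0.015, 5, lead=0)
        assert child / parent == pytest.approx(1.015 ** -22)


def _constant_trace(state, n_cycles=70, entry_age=30):
    occ = np.zeros((n_cycles + 1, N_STATES))
    occ[:, STATE_INDEX[state]] = 1.0
    return CohortTrace(occ, entry_age=entry_age, country="belgium", sex="female")


class TestQALYs:
    def test_perfect_health_undiscounted_is_horizon(self, pack):
        p = copy.deepcopy(pack)
        p.utilities.baseline["u0"] = 1.0
        tr = _constant_trace(HealthState.AT_RISK)
        assert he.qalys_from_trace(tr, p, "female", rate=0.0) == pytest.approx(70.0)

    def test_constant_occupancy_matches_geometric_series(self, pack):
        """Discounted QALYs of a constant trace equal the closed-form
        annuity sum u * sum_t (1+r)^-t."""
        tr = _constant_trace(HealthState.AT_RISK)
        r = pack.discount.effect_rate
        expected = sum(
            state_utility(pack, HealthState.AT_RISK, "female", min(30 + t, 99))
            * (1 + r) ** -t
            for t in range(70)
        )
        got = he.qalys_from_trace(tr, pack, "female")
        assert got == pytest.approx(expected, abs=1e-9)

    def test_decrement_scales_linearly_with_person_years(self, pack):
        tr_at_risk = _constant_trace(HealthState.AT_RISK)
        tr_diabetes = _constant_trace(HealthState.DIABETES)
        diff = he.qalys_from_trace(tr_at_risk, pack, "female", rate=0.0) - (
            he.qalys_from_trace(tr_diabetes, pack, "female", rate=0.0)
        )
        dec = pack.utilities.decrement("diabetes", "first")
        assert diff == pytest.approx(dec * 70, abs=1e-9)

    def test_death_contributes_zero(self, pack):
        assert he.qalys_from_trace(_constant_trace(HealthState.DEATH), pack, "male") == 0.0


class TestStateCosts:
    def test_chd_worked_example(self, pack):
        """One person-year in first-year CHD: direct 2000 * (1 + 0.8)
        indirect multiplier + 17.91% of the direct T2DM cost 1000."""
        p = copy.deepcopy(pack)
        df = p.costs.df
        df.loc[
            (df.country == "belgium") & (df.disease == "chd") & (df.phase == "first"),
            "direct",
        ] = 2000.0
        df.loc[(df.country == "belgium") & (df.disease == "diabetes"), "direct"] = 1000.0
        d, i = state_annual_cost(p, HealthState.CHD1, "belgium", 40)
        assert d + i == pytest.approx(2000 * 1.8 + 0.1791 * 1000)
        assert d == pytest.approx(2000 + 179.1)

    def test_stroke_indirect_equals_direct(self, pack):
        d, i = state_annual_cost(pack, HealthState.STROKE1, "belgium", 40)
        direct_only = pack.costs.direct("belgium", "stroke", "first", 40)
        assert i == pytest.approx(direct_only)

    def test_at_risk_and_death_cost_nothing(self, pack):
        assert state_annual_cost(pack, HealthState.AT_RISK, "belgium", 40) == (0, 0)
        assert state_annual_cost(pack, HealthState.DEATH, "belgium", 40) == (0, 0)
        tr = _constant_trace(HealthState.AT_RISK)
        assert he.costs_from_trace(tr, pack, "belgium").total == 0.0

    def test_followup_cost_is_relapse_adjusted(self, pack):
        d_first, _ = state_annual_cost(pack, HealthState.CHD1, "belgium", 40)
        d_fu, _ = state_annual_cost(pack, HealthState.CHD1PLUS, "belgium", 40)
        p_rel = pack.utilities.relapse["chd"]
        direct_fu = pack.costs.direct("belgium", "chd", "followup", 40)
        add_on = 0.1791 * pack.costs.direct("belgium", "diabetes", "all", 40)
        expected = he.relapse_adjust(d_first, direct_fu + add_on, p_rel)
        assert d_fu == pytest.approx(expected)

    def test_t2dm_age_stratification_switches_at_55(self, pack):
        lo = state_annual_cost(pack, HealthState.DIABETES, "belgium", 54)[0]
        hi = state_annual_cost(pack, HealthState.DIABETES, "belgium", 55)[0]
        assert hi > lo


class TestFrictionCost:
    def test_zero_outside_working_age(self):
        fp = FrictionParams()
        assert he.friction_death_cost(fp, 70) == 0.0
        assert he.friction_death_cost(fp, 29) == 0.0

    def test_elasticity_translates_time_loss_to_production_loss(self):
        """A 10% labour-time reduction yields an 8% production loss under
        the default elasticity of 0.8."""
        fp = FrictionParams(hourly_productivity=1.0, unemployment_rate=0.0)
        full_year_hours = fp.hours_in_period / (160 / 365.25)
        loss_10pct_time = he.friction_death_cost(
            FrictionParams(
                hours_in_period=0.10 * full_year_hours,
                hourly_productivity=1.0,
                unemployment_rate=0.0,
            ),
            40,
        )
        assert loss_10pct_time / (0.10 * full_year_hours) == pytest.approx(0.8)

    def test_worked_example(self):
        fp = FrictionParams(
            hours_in_period=800, hourly_productivity=30, unemployment_rate=0.10
        )
        assert he.friction_death_cost(fp, 40) == pytest.approx(17_280.0)

    def test_deaths_in_trace_incur_friction(self, pack):
        occ = np.zeros((71, N_STATES))
        occ[0, STATE_INDEX[HealthState.AT_RISK]] = 1.0
        occ[1:, STATE_INDEX[HealthState.DEATH]] = 1.0  # everyone dies in cycle 0
        tr = CohortTrace(occ, entry_age=40, country="belgium", sex="male")
        out = he.costs_from_trace(tr, pack, "belgium", rate=0.0)
        assert out.friction == pytest.approx(
            he.friction_death_cost(pack.friction["belgium"], 40)
        )


class TestICER:
    def test_ratio_quadrant(self):
        r = he.icer(2000, 1000, 1.0, 0.5)
        assert r.value == pytest.approx(2000.0)
        assert r.flag == "ratio"

    def test_dominant(self):
        assert he.icer(990, 1000, 1.1, 1.0).flag == "dominant"

    def test_dominated(self):
        assert he.icer(1100, 1000, 0.9, 1.0).flag == "dominated"

    def test_southwest_ratio(self):
        assert he.icer(900, 1000, 0.9, 1.0).flag == "ratio_sw"

    def test_zero_delta_q_undefined(self):
        r = he.icer(1100, 1000, 1.0, 1.0)
        assert r.flag == "undefined"
        assert np.isnan(r.value)


class TestPer1000:
    def test_identity_at_cohort_1000(self):
        rep = he.per_1000_report(10.0, CostBreakdown(direct=5.0), 1000)
        assert rep["qalys"] == 10.0 and rep["cost_direct"] == 5.0

    def test_proportional_scaling(self):
        rep = he.per_1000_report(10.0, CostBreakdown(), 500)
        assert rep["qalys"] == pytest.approx(20.0)

    def test_zero_cohort_rejected(self):
        with pytest.raises(ValueError):
            he.per_1000_report(1.0, CostBreakdown(), 0)


class TestRunComparison:
    def test_null_effect_gives_zero_delta_q(self, pack):
        """With identical arm distributions the only difference is the
        intervention cost; the ICER is undefined."""
        d = pack.prevalence[("belgium", "male")]
        effect = he.ArmEffect(mode="bmi", dist_control=d, dist_intervention=d)
        child = pack.child_prevalence[("belgium", "male")]
        effect_child = he.ArmEffect(mode="bmi", dist_control=child, dist_intervention=child)
        res = he.run_comparison(pack, "belgium", effect_child, effect)
        assert res.summary.delta_qaly == pytest.approx(0.0, abs=1e-12)
        assert res.summary.flag == "undefined" or res.summary.delta_qaly == 0.0

    def test_intervention_gains_qalys(self, pack):
        res = he.run_comparison(pack, "belgium")
        assert res.summary.delta_qaly > 0
        for (component, sex), rep in res.per_component.items():
            assert rep["delta_qaly_per_1000"] > 0

    def test_hrf_component_uses_hrf_costs_only(self, pack):
        res = he.run_comparison(pack, "belgium")
        all_fam = res.per_component[("all_families", "male")]
        hrf = res.per_component[("hrf", "male")]
        n_fam = pack.cohorts.n_families("belgium", "intervention")
        n_hrf = pack.cohorts.n_hrf("belgium", "intervention")
        assert all_fam["intervention"]["cost_intervention"] == pytest.approx(
            1000 * pack.ledger.total("belgium", "school") / n_fam
        )
        assert hrf["intervention"]["cost_intervention"] == pytest.approx(
            1000 * pack.ledger.total("belgium", "hrf") / n_hrf
        )

    def test_doubling_cohort_doubles_absolute_outcomes(self, pack):
        """QALYs and costs are linear in occupancy / cohort size."""
        rep1 = he.per_1000_report(4.2, CostBreakdown(direct=7.0, friction=1.0), 250)
        rep2 = he.per_1000_report(8.4, CostBreakdown(direct=14.0, friction=2.0), 500)
        assert rep1 == pytest.approx(rep2)

    def test_discounting_reduces_totals(self, pack):
        from healthecon.decision_front import arm_distributions
        from healthecon.outcomes import _entry_distributions

        arms = _entry_distributions(pack, "belgium", None, None)
        out_disc = _cohort_outcome(pack, "belgium", arms["control"], "male")
        p0 = copy.deepcopy(pack)
        p0.discount.effect_rate = 0.0
        p0.discount.cost_rate = 0.0
        out_undisc = _cohort_outcome(p0, "belgium", arms["control"], "male")
        assert out_disc.qalys < out_undisc.qalys
        assert out_disc.costs.total < out_undisc.costs.total
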