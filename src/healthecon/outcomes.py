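"""Valuation of cohort traces: discounted QALYs, discounted costs,
ICERs and per-1000 reports, plus the end-to-end arm comparison used by
the sensitivity and budget-impact layers.

Conventions
-----------
* Effects discount at 1.50%/year and costs at 3%/year.  Children carry a
  lead time from the mean intervention age to Markov entry at 30, so the
  factor for cycle t is (1 + r)^-(t + L).
* Follow-up utilities and costs are relapse-adjusted:
  adjusted = (1 - p) * followup + p * first_year.
* Disease-state costs are direct + indirect (per-disease multiplier;
  stroke indirect = direct) plus the T2DM comorbidity add-on (a fixed
  fraction of the direct T2DM cost).
* Friction costs value the production lost when someone aged 30-64 dies:
  hours in the 160-day friction period x hourly productivity x
  (1 - unemployment) x labour-time elasticity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .decision_front import ArmEffect, arm_distributions, parent_entry_schedule
from .markov_engine import CohortTrace, matrices_by_age, run_cohort
from .parampack import (
    COMORBIDITY_FRACTIONS,
    MAX_AGE,
    STATE_DISEASE,
    STATE_INDEX,
    FrictionParams,
    HealthState,
    ParameterPack,
)


def relapse_adjust(value_first_year: float, value_followup: float, p_relapse: float) -> float:
    """Expected follow-up value allowing an annual relapse probability."""
    if not (0 <= p_relapse <= 1):
        raise ValueError("relapse probability outside [0, 1]")
    return (1 - p_relapse) * value_followup + p_relapse * value_first_year


def discount_factor(rate: float, t: float, lead: float = 0.0) -> float:
    """(1 + rate)^-(t + lead); lead covers childhood years before entry."""
    if rate < 0 or t < 0 or lead < 0:
        raise ValueError("rate, cycle and lead must be non-negative")
    return (1 + rate) ** (-(t + lead))


# --------------------------------------------------------------------------
# State-level values
# --------------------------------------------------------------------------


def state_utility(pack: ParameterPack, state: HealthState, sex: str, age: float) -> float:
    """Utility of occupying ``state`` at ``age`` (relapse-adjusted for
    follow-up states); death contributes 0."""
    if state is HealthState.DEATH:
        return 0.0
    u0 = pack.utilities.u0(sex, age)
    if state is HealthState.AT_RISK:
        return u0
    disease, phase = STATE_DISEASE[state]
    dec_first = pack.utilities.decrement(disease, "first")
    if phase == "first":
        dec = dec_first
    else:
        dec = relapse_adjust(
            dec_first,
            pack.utilities.decrement(disease, "followup"),
            pack.utilities.relapse.get(disease, 0.0),
        )
    return max(0.0, u0 - dec)


def state_annual_cost(
    pack: ParameterPack, state: HealthState, country: str, age: float
) -> tuple[float, float]:
    """(direct, indirect) annual cost of one person-year in ``state``.

    Direct = direct disease cost + T2DM comorbidity add-on (fraction of the
    direct T2DM cost); indirect = direct disease cost x the per-disease
    multiplier.  Follow-up states are relapse-adjusted on both parts."""
    if state in (HealthState.AT_RISK, HealthState.DEATH):
        return 0.0, 0.0
    disease, phase = STATE_DISEASE[state]
    costs = pack.costs

    def parts(ph: str) -> tuple[float, float]:
        direct = costs.direct(country, disease, ph, age)
        indirect = direct * costs.indirect_multiplier(disease)
        add_on = 0.0
        if disease in costs.comorbidity_fractions:
            add_on = costs.comorbidity_fractions[disease] * costs.direct(
                country, "diabetes", "all", age
            )
        return direct + add_on, indirect

    if phase == "first" or disease == "diabetes":
        return parts("first")
    p = pack.utilities.relapse.get(disease, 0.0)
    d1, i1 = parts("first")
    d2, i2 = parts("followup")
    return relapse_adjust(d1, d2, p), relapse_adjust(i1, i2, p)


def friction_death_cost(friction: FrictionParams, age: float) -> float:
    """Friction-method productivity loss of one death at ``age`` (EUR).

    Zero outside the working-age window; otherwise the hours worked in
    the friction period, valued at the hourly productivity cost, adjusted
    for unemployment and labour-time elasticity."""
    if not (friction.age_min <= age <= friction.age_max):
        return 0.0
    return (
        friction.hours_in_period
        * friction.hourly_productivity
        * (1 - friction.unemployment_rate)
        * friction.elasticity
    )


# --------------------------------------------------------------------------
# Vectorised per-age value tables
# --------------------------------------------------------------------------


class ValueTables:
    """Per-age state values for one (country, sex), precomputed once.

    ``utility[k, s]``, ``direct[k, s]`` and ``indirect[k, s]`` hold the
    values at age ``ENTRY_AGE + k``; ``friction[k]`` is the per-death
    productivity loss at that age.  State values are piecewise-constant in
    age (decade utility bands, two cost strata), so only a handful of
    table lookups are needed."""

    def __init__(self, pack: ParameterPack, country: str, sex: str):
        from .parampack import ENTRY_AGE

        ages = range(ENTRY_AGE, MAX_AGE + 1)
        n_ages = MAX_AGE - ENTRY_AGE + 1
        n_states = len(HealthState)
        self.entry_age = ENTRY_AGE
        self.utility = np.zeros((n_ages, n_states))
        self.direct = np.zeros((n_ages, n_states))
        self.indirect = np.zeros((n_ages, n_states))
        self.friction = np.zeros(n_ages)
        fr = pack.friction[country]
        ucache: dict = {}
        ccache: dict = {}
        for k, age in enumerate(ages):
            self.friction[k] = friction_death_cost(fr, age)
            for s in HealthState:
                i = STATE_INDEX[s]
                ukey = (s, age // 10)
                if ukey not in ucache:
                    ucache[ukey] = state_utility(pack, s, sex, age)
                self.utility[k, i] = ucache[ukey]
                if s in STATE_DISEASE:
                    # the T2DM add-on switches band at 55 while the host
                    # disease switches at 65, so both bands key the cache
                    ckey = (
                        s,
                        pack.costs.age_lo(STATE_DISEASE[s][0], age),
                        pack.costs.age_lo("diabetes", age),
                    )
                    if ckey not in ccache:
                        ccache[ckey] = state_annual_cost(pack, s, country, age)
                    self.direct[k, i], self.indirect[k, i] = ccache[ckey]

    def age_index(self, entry_age: int, n_cycles: int) -> np.ndarray:
        idx = np.minimum(entry_age + np.arange(n_cycles), MAX_AGE) - self.entry_age
        return idx


# --------------------------------------------------------------------------
# Trace aggregation
# --------------------------------------------------------------------------


def qalys_from_trace(
    traces: CohortTrace | list[CohortTrace],
    pack: ParameterPack,
    sex: str,
    lead: float = 0.0,
    rate: float | None = None,
    tables: ValueTables | None = None,
) -> float:
    """Discounted QALYs per cohort member.

    Sums occupancy x state utility x discount factor over cycles; the
    utility of cycle t is evaluated at the age attained in that cycle."""
    if isinstance(traces, CohortTrace):
        traces = [traces]
    rate = pack.discount.effect_rate if rate is None else rate
    if tables is None:
        tables = ValueTables(pack, traces[0].country, sex)
    total = 0.0
    for tr in traces:
        n = tr.n_cycles
        idx = tables.age_index(tr.entry_age, n)
        df = (1 + rate) ** (-(np.arange(n) + lead))
        per_cycle = np.einsum("ts,ts->t", tr.occupancy[:n], tables.utility[idx])
        total += tr.weight * float(per_cycle @ df)
    return total


@dataclass
class CostBreakdown:
    """Discounted per-member costs split by category (EUR 2016)."""

    direct: float = 0.0
    indirect: float = 0.0
    friction: float = 0.0
    intervention: float = 0.0

    @property
    def total(self) -> float:
        return self.direct + self.indirect + self.friction + self.intervention

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(
            self.direct + other.direct,
            self.indirect + other.indirect,
            self.friction + other.friction,
            self.intervention + other.intervention,
        )

    def scaled(self, k: float) -> "CostBreakdown":
        return CostBreakdown(
            self.direct * k, self.indirect * k, self.friction * k, self.intervention * k
        )


def costs_from_trace(
    traces: CohortTrace | list[CohortTrace],
    pack: ParameterPack,
    country: str,
    lead: float = 0.0,
    rate: float | None = None,
    discounted: bool = True,
    tables: ValueTables | None = None,
) -> CostBreakdown:
    """Discounted disease-state and friction costs per cohort member."""
    if isinstance(traces, CohortTrace):
        traces = [traces]
    rate = pack.discount.cost_rate if rate is None else rate
    if tables is None:
        tables = ValueTables(pack, country, traces[0].sex)
    out = CostBreakdown()
    for tr in traces:
        n = tr.n_cycles
        idx = tables.age_index(tr.entry_age, n)
        df = (1 + rate) ** (-(np.arange(n) + lead)) if discounted else np.ones(n)
        deaths = tr.deaths_in_cycle()
        direct = np.einsum("ts,ts->t", tr.occupancy[:n], tables.direct[idx])
        indirect = np.einsum("ts,ts->t", tr.occupancy[:n], tables.indirect[idx])
        fr = deaths * tables.friction[idx]
        out.direct += tr.weight * float(direct @ df)
        out.indirect += tr.weight * float(indirect @ df)
        out.friction += tr.weight * float(fr @ df)
    return out


def direct_cost_stream(
    traces: CohortTrace | list[CohortTrace],
    pack: ParameterPack,
    country: str,
    tables: ValueTables | None = None,
) -> np.ndarray:
    """Undiscounted direct healthcare cost per cohort member per cycle
    (used as budget-impact cost offsets)."""
    if isinstance(traces, CohortTrace):
        traces = [traces]
    if tables is None:
        tables = ValueTables(pack, country, traces[0].sex)
    n = traces[0].n_cycles
    stream = np.zeros(n)
    for tr in traces:
        idx = tables.age_index(tr.entry_age, n)
        stream += tr.weight * np.einsum(
            "ts,ts->t", tr.occupancy[:n], tables.direct[idx]
        )
    return stream


# --------------------------------------------------------------------------
# ICER
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ICERResult:
    """Incremental comparison of intervention vs control.

    ``flag`` is one of ``"ratio"`` (north-east quadrant), ``"dominant"``
    (more QALYs, lower cost), ``"dominated"`` (fewer QALYs, higher cost),
    ``"ratio_sw"`` (fewer QALYs, lower cost: the ratio is a
    willingness-to-accept) or ``"undefined"`` (no QALY difference)."""

    delta_cost: float
    delta_qaly: float
    value: float
    flag: str


def icer(cost_int: float, cost_ctrl: float, qaly_int: float, qaly_ctrl: float) -> ICERResult:
    """ICER = (COSTintervention - COSTcontrol) / (QALYintervention - QALYcontrol)."""
    dc = cost_int - cost_ctrl
    dq = qaly_int - qaly_ctrl
    if dq == 0:
        return ICERResult(dc, dq, math.nan, "undefined")
    if dq > 0:
        if dc <= 0:
            return ICERResult(dc, dq, dc / dq, "dominant")
        return ICERResult(dc, dq, dc / dq, "ratio")
    if dc >= 0:
        return ICERResult(dc, dq, dc / dq, "dominated")
    return ICERResult(dc, dq, dc / dq, "ratio_sw")


def per_1000_report(qalys: float, costs: CostBreakdown, cohort_size: float) -> dict:
    """Rescale absolute cohort outcomes to 1000 targeted children."""
    if cohort_size <= 0:
        raise ValueError("cohort size must be positive")
    k = 1000.0 / cohort_size
    return {
        "qalys": qalys * k,
        "cost_direct": costs.direct * k,
        "cost_indirect": costs.indirect * k,
        "cost_friction": costs.friction * k,
        "cost_intervention": costs.intervention * k,
        "cost_total": costs.total * k,
    }


# --------------------------------------------------------------------------
# End-to-end arm comparison (the "model runner")
# --------------------------------------------------------------------------


@dataclass
class ArmOutcome:
    qalys: float
    costs: CostBreakdown


@dataclass
class CEResult:
    """Cost-effectiveness result for one country.

    ``per_component`` holds, per component ("all_families", "hrf") and
    child sex, the per-1000-children arm outcomes and the incremental
    comparison.  ``summary`` is the pooled per-family comparison."""

    country: str
    per_component: dict = field(default_factory=dict)
    summary: ICERResult | None = None


def _cohort_outcome(
    pack: ParameterPack,
    country: str,
    arm_dists: dict,
    component_sex: str,
    tables: dict | None = None,
) -> ArmOutcome:
    """Per-family outcome (one child of ``component_sex`` + parents) for one
    arm, given the arm's child/adult entry distributions."""
    disc = pack.discount
    child_lead = disc.child_lead_years
    sched = parent_entry_schedule(pack.cohorts.parent_age_proportions)
    if tables is None:
        tables = {s: ValueTables(pack, country, s) for s in ("male", "female")}

    qalys = 0.0
    costs = CostBreakdown()
    # the child
    traces = run_cohort(
        pack, country, component_sex, arm_dists[("child", component_sex)],
        _matrices=arm_dists.get(("mats_child", component_sex)),
    )
    qalys += qalys_from_trace(
        traces, pack, component_sex, lead=child_lead, tables=tables[component_sex]
    )
    costs = costs + costs_from_trace(
        traces, pack, country, lead=child_lead, tables=tables[component_sex]
    )
    # the parents (one of each sex by default composition)
    per_parent = pack.cohorts.parents_per_family / 2.0
    for sex in ("male", "female"):
        traces = run_cohort(
            pack, country, sex, arm_dists[("adult", sex)], entry_schedule=sched,
            _matrices=arm_dists.get(("mats_adult", sex)),
        )
        qalys += per_parent * qalys_from_trace(
            traces, pack, sex, lead=disc.parent_lead_years, tables=tables[sex]
        )
        costs = costs + costs_from_trace(
            traces, pack, country, lead=disc.parent_lead_years, tables=tables[sex]
        ).scaled(per_parent)
    return ArmOutcome(qalys, costs)


def _entry_distributions(pack, country, effect_child, effect_adult):
    """Per-arm entry weight distributions (and cached matrices) for both
    populations and sexes."""
    arms: dict[str, dict] = {"control": {}, "intervention": {}}
    for sex in ("male", "female"):
        c_child, i_child = arm_distributions(pack, country, sex, "child", effect_child)
        c_adult, i_adult = arm_distributions(pack, country, sex, "adult", effect_adult)
        arms["control"][("child", sex)] = c_child
        arms["intervention"][("child", sex)] = i_child
        arms["control"][("adult", sex)] = c_adult
        arms["intervention"][("adult", sex)] = i_adult
    for arm, dists in arms.items():
        for sex in ("male", "female"):
            dists[("mats_child", sex)] = matrices_by_age(
                pack, country, sex, dists[("child", sex)]
            )
            dists[("mats_adult", sex)] = matrices_by_age(
                pack, country, sex, dists[("adult", sex)]
            )
    return arms


def run_comparison(
    pack: ParameterPack,
    country: str,
    effect_child: ArmEffect | None = None,
    effect_adult: ArmEffect | None = None,
) -> CEResult:
    """Full base-case comparison of intervention vs control for a country.

    The all-families component carries the school-based intervention cost
    spread over every participating family; the HRF component carries the
    high-risk-family session costs over HRF families only.  Outcomes are
    reported per 1000 targeted boys and per 1000 targeted girls."""
    arms = _entry_distributions(pack, country, effect_child, effect_adult)
    tables = {s: ValueTables(pack, country, s) for s in ("male", "female")}

    outcome: dict[tuple[str, str], ArmOutcome] = {}
    for arm in ("control", "intervention"):
        for sex in ("male", "female"):
            outcome[(arm, sex)] = _cohort_outcome(pack, country, arms[arm], sex, tables)

    n_fam = pack.cohorts.n_families(country, "intervention")
    n_hrf = pack.cohorts.n_hrf(country, "intervention")
    cost_per_family = {
        "all_families": pack.ledger.total(country, "school") / n_fam,
        "hrf": pack.ledger.total(country, "hrf") / n_hrf,
    }

    result = CEResult(country=country)
    for component, int_cost in cost_per_family.items():
        for sex in ("male", "female"):
            ctrl = outcome[("control", sex)]
            interv = outcome[("intervention", sex)]
            int_costs = interv.costs + CostBreakdown(intervention=int_cost)
            comp = icer(int_costs.total, ctrl.costs.total, interv.qalys, ctrl.qalys)
            result.per_component[(component, sex)] = {
                "control": per_1000_report(ctrl.qalys, ctrl.costs, 1.0),
                "intervention": per_1000_report(interv.qalys, int_costs, 1.0),
                "delta_cost_per_1000": comp.delta_cost * 1000,
                "delta_qaly_per_1000": comp.delta_qaly * 1000,
                "icer": comp.value,
                "flag": comp.flag,
            }

    # pooled per-family summary over both sexes, all-families component
    split = pack.cohorts.child_sex_split
    dq = dc = 0.0
    for sex, w in (("male", split), ("female", 1 - split)):
        ctrl = outcome[("control", sex)]
        interv = outcome[("intervention", sex)]
        dq += w * (interv.qalys - ctrl.qalys)
        dc += w * (
            interv.costs.total + cost_per_family["all_families"] - ctrl.costs.total
        )
    result.summary = icer(dc, 0.0, dq, 0.0)
    return result


def delta_runner(pack: ParameterPack, country: str = "belgium"):
    """(delta_cost, delta_qaly) per family — the scalar model runner the
    sensitivity layer perturbs."""
    res = run_comparison(pack, country)
    return res.summary.delta_cost, res.summary.delta_qaly
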