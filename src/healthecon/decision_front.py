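"""Decision-analytic front end.

Converts trial-measured intervention effects into the per-arm adult
weight-status distributions that drive the Markov model.  Two effect
modes exist: a direct BMI mode (measured weight-status distributions per
arm) and an EBRB-mediated mode, where relative risk reductions in
energy balance-related behaviours are combined into a relative risk
reduction in overweight and obesity.  When both are supplied the direct
BMI mode takes priority.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parampack import (
    EBRBTable,
    SESAdjustmentTable,
    TrackingMatrix,
    WeightDistribution,
)

PARENT_AGE_GROUP_AGES = {
    "<30": (30,),
    "30-34": (30, 31, 32, 33, 34),
    "35-39": (35, 36, 37, 38, 39),
    "40-44": (40, 41, 42, 43, 44),
    "45-49": (45, 46, 47, 48, 49),
    ">50": (50,),
}


@dataclass(frozen=True)
class ArmEffect:
    """Intervention effect specification for one population (child/adult).

    ``mode="bmi"`` carries measured per-arm weight distributions;
    ``mode="ebrb"`` derives the weight-status effect from behaviour
    exposure changes.  ``mode="auto"`` prefers BMI when distributions are
    present (the direct option gets priority)."""

    mode: str = "auto"
    dist_control: WeightDistribution | None = None
    dist_intervention: WeightDistribution | None = None

    def resolved_mode(self) -> str:
        if self.mode == "auto":
            return "bmi" if self.dist_control is not None else "ebrb"
        return self.mode


def rr_from_or(odds_ratio: float, p0: float) -> float:
    """Convert an odds ratio to a relative risk given baseline risk ``p0``.

    RR = OR / (1 - p0 + p0 * OR).  For OR > 1 the result is at most the
    OR (a conservative estimate); at p0 = 0 it equals the OR.
    """
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if not (0 <= p0 < 1):
        raise ValueError("baseline risk must be in [0, 1)")
    return odds_ratio / (1 - p0 + p0 * odds_ratio)


def ses_adjust(
    dist: WeightDistribution, adj: SESAdjustmentTable, country: str, sex: str
) -> WeightDistribution:
    """Scale overweight/obese prevalence by the low-SES relative risks.

    Countries absent from the adjustment table (their study regions cover
    the whole country) are returned unchanged.  The normal-weight share
    absorbs the complement."""
    if not adj.has_country(country):
        return dist
    rr_ow = adj.get(country, sex, "overweight")
    rr_ob = adj.get(country, sex, "obese")
    if rr_ow is None or rr_ob is None:
        raise KeyError(f"incomplete SES adjustment for ({country}, {sex})")
    p_ow = dist.p_overweight * rr_ow
    p_ob = dist.p_obese * rr_ob
    if p_ow + p_ob > 1 + 1e-12:
        raise ValueError(
            f"SES-adjusted excess-weight mass {p_ow + p_ob:.4f} exceeds 1"
        )
    return WeightDistribution(1.0 - p_ow - p_ob, p_ow, p_ob)


def ebrb_to_weight_rrr(ebrb: EBRBTable, population: str) -> tuple[float, float]:
    """Combine behaviour-level exposure changes into an overweight and an
    obesity relative risk reduction.

    Per included behaviour the change in the attributable fraction is

        delta = (p_ctrl - p_int) * (RR - 1) / (1 + p_ctrl * (RR - 1))

    and behaviours combine multiplicatively on survival of attributable
    fractions (independence assumption): RRR = 1 - prod(1 - delta).
    """
    rows = ebrb.included(population)
    if rows.empty:
        raise ValueError(f"no included behaviours for population {population!r}")
    rrr = {}
    for target, col in (("overweight", "rr_overweight"), ("obese", "rr_obese")):
        surv = 1.0
        for r in rows.itertuples(index=False):
            rr = getattr(r, col)
            if np.isnan(rr):
                raise ValueError(f"behaviour {r.behaviour!r} missing RR on {target}")
            for p in (r.p_control, r.p_intervention):
                if not (0 <= p <= 1):
                    raise ValueError(
                        f"behaviour {r.behaviour!r} prevalence {p} outside [0, 1]"
                    )
            delta = (r.p_control - r.p_intervention) * (rr - 1) / (
                1 + r.p_control * (rr - 1)
            )
            surv *= 1 - delta
        rrr[target] = 1 - surv
    return rrr["overweight"], rrr["obese"]


def apply_weight_rrr(
    dist: WeightDistribution, rrr_overweight: float, rrr_obese: float
) -> WeightDistribution:
    """Shrink overweight/obese shares by their RRRs; freed mass becomes
    normal weight.

    A negative RRR (a harmful effect, possible under sampled parameter
    uncertainty) grows the share instead; the result must still be a
    valid distribution."""
    for r in (rrr_overweight, rrr_obese):
        if r > 1:
            raise ValueError(f"relative risk reduction {r} exceeds 1")
    p_ow = dist.p_overweight * (1 - rrr_overweight)
    p_ob = dist.p_obese * (1 - rrr_obese)
    return WeightDistribution(1.0 - p_ow - p_ob, p_ow, p_ob)


def child_to_adult(dist_child: WeightDistribution, tracking: TrackingMatrix) -> WeightDistribution:
    """Extrapolate a child weight-status distribution to adult age via the
    tracking matrix (row: child status, column: adult status)."""
    adult = dist_child.as_array() @ tracking.matrix
    return WeightDistribution.from_array(adult / adult.sum())


def parent_entry_schedule(age_group_proportions: dict[str, float]) -> dict[int, float]:
    """Spread the six parent age groups over integer model entry ages.

    Parents younger than 30 enter at 30 and older than 50 at 50; each
    five-year group's mass splits evenly over its five ages."""
    unknown = set(age_group_proportions) - set(PARENT_AGE_GROUP_AGES)
    if unknown:
        raise KeyError(f"unknown parent age groups: {sorted(unknown)}")
    if any(p < 0 for p in age_group_proportions.values()):
        raise ValueError("negative age-group proportion")
    total = sum(age_group_proportions.values())
    if abs(total - 1) > 1e-9:
        raise ValueError(f"age-group proportions sum to {total}, not 1")
    schedule: dict[int, float] = {}
    for group, mass in age_group_proportions.items():
        if mass == 0:
            continue
        ages = PARENT_AGE_GROUP_AGES[group]
        for age in ages:
            schedule[age] = schedule.get(age, 0.0) + mass / len(ages)
    return dict(sorted(schedule.items()))


def arm_distributions(
    pack, country: str, sex: str, population: str, effect: ArmEffect | None = None
) -> tuple[WeightDistribution, WeightDistribution]:
    """(control, intervention) weight distributions for one stratum.

    Children: country child prevalence -> arm-specific child distribution
    -> tracking extrapolation to adult status.  Adults (parents): SES-
    adjusted adult prevalence -> arm-specific distribution.  The default
    effect is the EBRB-mediated one held in the pack; a direct-BMI
    :class:`ArmEffect` overrides it.
    """
    if effect is not None and effect.resolved_mode() == "bmi":
        ctrl, interv = effect.dist_control, effect.dist_intervention
        if ctrl is None or interv is None:
            raise ValueError("direct-BMI mode requires both arm distributions")
    else:
        if population == "child":
            ctrl = pack.child_prevalence[(country, sex)]
        else:
            ctrl = ses_adjust(pack.prevalence[(country, sex)], pack.ses, country, sex)
        rrr_ow, rrr_ob = ebrb_to_weight_rrr(pack.ebrb, population)
        interv = apply_weight_rrr(ctrl, rrr_ow, rrr_ob)

    if population == "child":
        ctrl = child_to_adult(ctrl, pack.tracking)
        interv = child_to_adult(interv, pack.tracking)
    return ctrl, interv
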