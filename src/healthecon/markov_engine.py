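"""Eleven-state Markov cohort engine.

Builds per-stratum, per-age transition matrices and runs the 70-cycle
cohort trace starting at age 30.  Transition probabilities out of the
at-risk state are a function of the arm's weight-status distribution:
population incidences are first calibrated to a normal-weight baseline
against the reference (population) distribution, then re-mixed with the
arm's distribution.  A seeded microsimulation of individual trajectories
serves as an independent oracle for the deterministic trace.

Relative risks act multiplicatively on annual probabilities with capping
at 1 (spreadsheet-model idiom); an optional rate-space transform
(``pack.markov.rate_space_rr``) is available for robustness at high
baseline risks.  Within one row, death is claimed first and the
remaining incident transitions are scaled proportionally if they would
exceed the residual mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .parampack import (
    DISEASE_STATES,
    FOLLOWUP_OF,
    MAX_AGE,
    N_STATES,
    STATE_INDEX,
    HealthState,
    ParameterPack,
    WeightDistribution,
)

_TUNNEL_DISEASES = ("stroke", "chd", "crc", "bc")


def calibrate_baseline_incidence(
    i_pop: float, dist: WeightDistribution, rr_overweight: float, rr_obese: float
) -> float:
    """Normal-weight incidence consistent with a population incidence.

    Solves ``i_pop = i_normal * (p_n + p_ow*rr_ow + p_ob*rr_ob)`` so that
    re-mixing with the reference distribution reproduces ``i_pop``."""
    denom = dist.mix(rr_overweight, rr_obese)
    if denom <= 0:
        raise ZeroDivisionError("weight-mixed relative risk is zero")
    return i_pop / denom


def mixed_incidence(
    i_normal: float, dist: WeightDistribution, rr_overweight: float, rr_obese: float
) -> float:
    """Population incidence under ``dist`` given the normal-weight baseline."""
    i = i_normal * dist.mix(rr_overweight, rr_obese)
    if i > 1:
        warnings.warn("weight-mixed incidence exceeded 1; clamped", stacklevel=2)
        i = 1.0
    return i


def diabetic_transition(p_base: float, rr_diabetic: float, rate_space: bool = False) -> float:
    """Transition probability for a diabetic, from the healthy-population
    probability and the diabetic relative risk.

    Default: ``min(1, p_base * rr)``.  Rate space: the RR multiplies the
    instantaneous rate, ``1 - (1 - p_base)**rr``."""
    if not (0 <= p_base <= 1):
        raise ValueError("base probability outside [0, 1]")
    if rate_space:
        return 1.0 - (1.0 - p_base) ** rr_diabetic
    return min(1.0, p_base * rr_diabetic)


def death_probability(
    state: HealthState,
    age: int,
    sex: str,
    pack: ParameterPack,
    country: str,
    weight_dist: WeightDistribution,
) -> float:
    """Annual probability of dying from ``state`` at ``age``.

    At risk: all-cause mortality times the weight-mixed mortality RR.
    Diabetes: all-cause mortality times the diabetic mortality RR.
    Disease tunnel/follow-up states: the state-specific mortality."""
    epi = pack.epidemiology
    if state is HealthState.DEATH:
        return 0.0
    if state is HealthState.AT_RISK:
        m = epi.all_cause_mortality(country, sex, age)
        return min(1.0, m * pack.rr.mixed(sex, "mortality", age, weight_dist))
    if state is HealthState.DIABETES:
        m = epi.all_cause_mortality(country, sex, age)
        return min(1.0, m * pack.rr.diabetic(sex, "mortality", age))
    disease = state.value.replace("1plus", "").replace("1", "").lower()
    phase = "followup" if state in FOLLOWUP_OF.values() else "first"
    return min(1.0, epi.disease_mortality(country, sex, age, disease, phase))


def _allocate_row(row: np.ndarray, stay_idx: int, death: float,
                  transitions: dict[int, float]) -> None:
    """Fill one matrix row: death first, incident transitions scaled
    proportionally into the residual if they overflow, remainder stays."""
    residual = 1.0 - death
    total = sum(transitions.values())
    if total > residual + 1e-12:
        warnings.warn(
            "incident transition mass exceeds residual after death; "
            "scaled proportionally",
            stacklevel=3,
        )
        scale = residual / total if total > 0 else 0.0
        transitions = {k: v * scale for k, v in transitions.items()}
        total = residual
    row[STATE_INDEX[HealthState.DEATH]] = death
    for idx, p in transitions.items():
        row[idx] += p
    row[stay_idx] = residual - total


@dataclass
class TransitionMatrix:
    """Row-stochastic 11x11 annual transition matrix with its annotations."""

    matrix: np.ndarray
    age: int
    country: str
    sex: str
    label: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_STATES, N_STATES):
            raise ValueError("transition matrix must be 11x11")
        if np.abs(m.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("transition matrix rows must sum to 1")
        if (m < -1e-12).any():
            raise ValueError("negative transition probability")
        self.matrix = m


def build_transition_matrix(
    pack: ParameterPack,
    country: str,
    sex: str,
    age: int,
    arm_dist: WeightDistribution,
    ref_dist: WeightDistribution | None = None,
    label: str = "",
) -> TransitionMatrix:
    """Annual transition matrix for one stratum and age.

    ``ref_dist`` is the weight distribution the population incidences
    refer to (default: the country/sex adult prevalence in the pack);
    ``arm_dist`` is the arm-specific distribution that actually drives
    the transitions."""
    if ref_dist is None:
        ref_dist = pack.prevalence[(country, sex)]
    rate_space = pack.markov.rate_space_rr
    epi = pack.epidemiology
    m = np.zeros((N_STATES, N_STATES))

    # arm-mixed incidence per disease (BC closed to men)
    inc: dict[str, float] = {}
    for disease in DISEASE_STATES:
        if disease == "bc" and sex == "male":
            inc[disease] = 0.0
            continue
        i_pop = epi.incidence(country, sex, age, disease)
        rr_ow = pack.rr.at_risk(sex, "overweight", disease, age)
        rr_ob = pack.rr.at_risk(sex, "obese", disease, age)
        i_norm = calibrate_baseline_incidence(i_pop, ref_dist, rr_ow, rr_ob)
        inc[disease] = mixed_incidence(i_norm, arm_dist, rr_ow, rr_ob)

    # at-risk row
    at_risk = STATE_INDEX[HealthState.AT_RISK]
    death = death_probability(HealthState.AT_RISK, age, sex, pack, country, arm_dist)
    transitions = {
        STATE_INDEX[DISEASE_STATES[d][0]]: inc[d] for d in DISEASE_STATES if inc[d] > 0
    }
    _allocate_row(m[at_risk], at_risk, death, transitions)

    # diabetes row: comorbidity transitions at the diabetic RR
    dia = STATE_INDEX[HealthState.DIABETES]
    death = death_probability(HealthState.DIABETES, age, sex, pack, country, arm_dist)
    transitions = {}
    for disease in _TUNNEL_DISEASES:
        if disease == "bc" and sex == "male":
            continue
        p = diabetic_transition(
            inc[disease], pack.rr.diabetic(sex, disease, age), rate_space
        )
        if p > 0:
            transitions[STATE_INDEX[DISEASE_STATES[disease][0]]] = p
    _allocate_row(m[dia], dia, death, transitions)

    # tunnel states: survivors move to the follow-up partner
    for first, followup in FOLLOWUP_OF.items():
        i = STATE_INDEX[first]
        death = death_probability(first, age, sex, pack, country, arm_dist)
        m[i, STATE_INDEX[HealthState.DEATH]] = death
        m[i, STATE_INDEX[followup]] = 1.0 - death
        # follow-up states: survivors stay
        j = STATE_INDEX[followup]
        death_fu = death_probability(followup, age, sex, pack, country, arm_dist)
        m[j, STATE_INDEX[HealthState.DEATH]] = death_fu
        m[j, j] = 1.0 - death_fu

    d = STATE_INDEX[HealthState.DEATH]
    m[d, d] = 1.0
    return TransitionMatrix(m, age=age, country=country, sex=sex, label=label)


def matrices_by_age(
    pack: ParameterPack,
    country: str,
    sex: str,
    arm_dist: WeightDistribution,
    ref_dist: WeightDistribution | None = None,
) -> dict[int, np.ndarray]:
    """Precompute matrices for every model age (30..MAX_AGE); older ages
    reuse the MAX_AGE matrix."""
    return {
        age: build_transition_matrix(pack, country, sex, age, arm_dist, ref_dist).matrix
        for age in range(pack.markov.entry_age, MAX_AGE + 1)
    }


@dataclass
class CohortTrace:
    """State occupancy over the model horizon for one entry age.

    ``occupancy[t]`` is the distribution over the 11 states at the start
    of cycle ``t`` (t = 0..n_cycles); ``weight`` is the share of the
    total cohort entering at this age."""

    occupancy: np.ndarray  # (n_cycles + 1, 11)
    entry_age: int
    country: str
    sex: str
    weight: float = 1.0
    label: str = ""

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def deaths_in_cycle(self) -> np.ndarray:
        """Fraction of the cohort dying during each cycle t (length n_cycles)."""
        d = self.occupancy[:, STATE_INDEX[HealthState.DEATH]]
        return np.diff(d)


def run_cohort(
    pack: ParameterPack,
    country: str,
    sex: str,
    arm_dist: WeightDistribution,
    entry_schedule: dict[int, float] | None = None,
    ref_dist: WeightDistribution | None = None,
    label: str = "",
    _matrices: dict[int, np.ndarray] | None = None,
) -> list[CohortTrace]:
    """Run the deterministic cohort trace.

    Everyone starts in the at-risk state.  ``entry_schedule`` maps entry
    age to cohort weight (default: all mass at the Markov entry age, the
    children's case); one weighted trace per entry age is returned."""
    if entry_schedule is None:
        entry_schedule = {pack.markov.entry_age: 1.0}
    total = sum(entry_schedule.values())
    if abs(total - 1) > 1e-9:
        raise ValueError(f"entry weights sum to {total}, not 1")
    mats = _matrices if _matrices is not None else matrices_by_age(
        pack, country, sex, arm_dist, ref_dist
    )
    n = pack.markov.n_cycles
    traces = []
    for entry_age, w in entry_schedule.items():
        occ = np.zeros((n + 1, N_STATES))
        occ[0, STATE_INDEX[HealthState.AT_RISK]] = 1.0
        for t in range(n):
            age = min(entry_age + t, MAX_AGE)
            occ[t + 1] = occ[t] @ mats[age]
        traces.append(
            CohortTrace(occ, entry_age=entry_age, country=country, sex=sex,
                        weight=w, label=label)
        )
    return traces


def microsim_oracle(
    pack: ParameterPack,
    country: str,
    sex: str,
    arm_dist: WeightDistribution,
    n: int,
    seed: int,
    entry_age: int | None = None,
    ref_dist: WeightDistribution | None = None,
) -> CohortTrace:
    """Monte-Carlo estimate of the cohort trace from ``n`` simulated
    individual trajectories through the same transition matrices."""
    if n < 1:
        raise ValueError("need at least one individual")
    rng = np.random.default_rng(seed)
    entry_age = pack.markov.entry_age if entry_age is None else entry_age
    mats = matrices_by_age(pack, country, sex, arm_dist, ref_dist)
    n_cycles = pack.markov.n_cycles

    states = np.full(n, STATE_INDEX[HealthState.AT_RISK], dtype=np.int64)
    occ = np.zeros((n_cycles + 1, N_STATES))
    occ[0] = np.bincount(states, minlength=N_STATES) / n
    for t in range(n_cycles):
        age = min(entry_age + t, MAX_AGE)
        cum = np.cumsum(mats[age], axis=1)
        u = rng.random(n)
        states = (u[:, None] > cum[states]).sum(axis=1)
        occ[t + 1] = np.bincount(states, minlength=N_STATES) / n
    return CohortTrace(occ, entry_age=entry_age, country=country, sex=sex)
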