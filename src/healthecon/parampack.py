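"""Model inputs for the health-economic evaluation engine.

This module defines every typed input the decision-analytic / Markov
pipeline consumes — relative-risk tables, socio-economic-status (SES)
adjustments, energy-balance-related-behaviour (EBRB) effects,
epidemiology (incidence and mortality), utilities, disease-state costs,
friction-cost parameters, discounting, the intervention cost ledger and
the child-to-adult weight tracking matrix — together with

* directory-of-CSV readers/writers (plus a YAML manifest for scalars),
* report-style validation (``validate_pack``),
* Belgium-referenced imputation of missing country cells, and
* a deterministic synthetic pack generator used as the test fixture
  (``generate_synthetic_pack``).

All monetary amounts are EUR at 2016 value.  Ages are integer years;
the Markov model covers ages 30–99 and every age-banded table keys
bands by closed-open ``[age_lo, age_hi)`` intervals.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

# --------------------------------------------------------------------------
# Global constants
# --------------------------------------------------------------------------

COUNTRIES = ("belgium", "finland", "greece", "spain", "hungary", "bulgaria")
REFERENCE_COUNTRY = "belgium"
SEXES = ("male", "female")
WEIGHT_STATUSES = ("normal", "overweight", "obese")
DISEASES = ("diabetes", "stroke", "chd", "crc", "bc")
ENDPOINTS = ("mortality",) + DISEASES

ENTRY_AGE = 30
N_CYCLES = 70
MAX_AGE = 99  # ages past this reuse the oldest band / row

PARENT_AGE_GROUPS = ("<30", "30-34", "35-39", "40-44", "45-49", ">50")

# T2DM comorbidity cost fractions added to the comorbid disease states
COMORBIDITY_FRACTIONS = {"chd": 0.1791, "stroke": 0.1980, "bc": 0.2375, "crc": 0.3824}
# Indirect (productivity) cost as a multiple of the direct cost
INDIRECT_MULTIPLIERS = {"diabetes": 0.91, "bc": 0.71, "chd": 0.80, "stroke": 1.00}

MANIFEST_NAME = "manifest.yaml"


class HealthState(enum.Enum):
    """The eleven health states of the Markov model.

    Stroke, coronary heart disease (CHD), colorectal cancer (CRC) and
    breast cancer (BC) each split into a first-year (tunnel) state and a
    follow-up state because their costs and utilities differ markedly
    between the diagnosis year and later years.  Death is absorbing.
    """

    AT_RISK = "AtRisk"
    DIABETES = "Diabetes"
    STROKE1 = "Stroke1"
    STROKE1PLUS = "Stroke1plus"
    CHD1 = "CHD1"
    CHD1PLUS = "CHD1plus"
    CRC1 = "CRC1"
    CRC1PLUS = "CRC1plus"
    BC1 = "BC1"
    BC1PLUS = "BC1plus"
    DEATH = "Death"


STATES = tuple(HealthState)
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
N_STATES = len(STATES)

#: first-year tunnel state -> its follow-up partner
FOLLOWUP_OF = {
    HealthState.STROKE1: HealthState.STROKE1PLUS,
    HealthState.CHD1: HealthState.CHD1PLUS,
    HealthState.CRC1: HealthState.CRC1PLUS,
    HealthState.BC1: HealthState.BC1PLUS,
}

#: disease label -> (first-year state, follow-up state); diabetes has no tunnel
DISEASE_STATES = {
    "diabetes": (HealthState.DIABETES, HealthState.DIABETES),
    "stroke": (HealthState.STROKE1, HealthState.STROKE1PLUS),
    "chd": (HealthState.CHD1, HealthState.CHD1PLUS),
    "crc": (HealthState.CRC1, HealthState.CRC1PLUS),
    "bc": (HealthState.BC1, HealthState.BC1PLUS),
}

#: state -> (disease label, phase) for every disease-bearing state
STATE_DISEASE = {
    HealthState.DIABETES: ("diabetes", "first"),
    HealthState.STROKE1: ("stroke", "first"),
    HealthState.STROKE1PLUS: ("stroke", "followup"),
    HealthState.CHD1: ("chd", "first"),
    HealthState.CHD1PLUS: ("chd", "followup"),
    HealthState.CRC1: ("crc", "first"),
    HealthState.CRC1PLUS: ("crc", "followup"),
    HealthState.BC1: ("bc", "first"),
    HealthState.BC1PLUS: ("bc", "followup"),
}

#: endpoint -> closed-open age bands used by the relative-risk table
RR_AGE_BANDS = {
    "mortality": ((30, 50), (50, 60), (60, 70), (70, 120)),
    "chd": ((30, 55), (55, 65), (65, 120)),
    "stroke": ((30, 65), (65, 120)),
    "diabetes": ((30, 60), (60, 75), (75, 120)),
    "bc": ((30, 50), (50, 120)),
    "crc": ((30, 45), (45, 120)),
}


class PackValidationError(ValueError):
    """Raised when a parameter pack fails validation on load."""


class PackSchemaError(ValueError):
    """Raised when a pack directory is missing a table or a column."""


# --------------------------------------------------------------------------
# Weight distribution
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WeightDistribution:
    """Proportions of a population in the three BMI classes.

    normal weight (BMI < 25), overweight (25 <= BMI <= 30), obese (BMI > 30).
    Must sum to 1 within 1e-9.
    """

    p_normal: float
    p_overweight: float
    p_obese: float

    def __post_init__(self) -> None:
        for p in self.as_tuple():
            if not (-1e-12 <= p <= 1 + 1e-12):
                raise ValueError(f"weight-status proportion {p} outside [0, 1]")
        if abs(sum(self.as_tuple()) - 1.0) > 1e-9:
            raise ValueError(
                f"weight-status proportions sum to {sum(self.as_tuple())!r}, not 1"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_normal, self.p_overweight, self.p_obese)

    def as_array(self) -> np.ndarray:
        return np.array(self.as_tuple())

    @classmethod
    def from_array(cls, a) -> "WeightDistribution":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def mix(self, rr_overweight: float, rr_obese: float) -> float:
        """Population-average relative risk under this distribution
        (normal weight is the reference, RR = 1)."""
        return (
            self.p_normal
            + self.p_overweight * rr_overweight
            + self.p_obese * rr_obese
        )


# --------------------------------------------------------------------------
# Relative-risk table
# --------------------------------------------------------------------------


@dataclass
class RRTable:
    """Relative risks by sex, weight status, endpoint and age band.

    Two blocks:

    * ``group="at_risk"`` — overweight/obese vs normal-weight adults, for
      disease incidence and all-cause mortality;
    * ``group="diabetic"`` — diabetic vs healthy adults, for comorbidity
      incidence (stroke, CHD, CRC, BC) and mortality.

    Stored long-form; a nested dict index is built lazily for lookups.
    """

    df: pd.DataFrame  # columns: group, sex, weight_status, endpoint, age_lo, age_hi, rr

    _index: dict = field(default_factory=dict, repr=False)

    def _build_index(self) -> None:
        idx: dict = {}
        for row in self.df.itertuples(index=False):
            key = (row.group, row.sex, row.weight_status, row.endpoint)
            idx.setdefault(key, []).append((row.age_lo, row.age_hi, row.rr))
        self._index = idx

    def _lookup(self, key, age: float) -> float:
        if not self._index:
            self._build_index()
        bands = self._index.get(key)
        if bands is None:
            raise KeyError(f"no relative risk for {key}")
        for lo, hi, rr in bands:
            if lo <= age < hi:
                return float(rr)
        # ages past the oldest band reuse it
        lo, hi, rr = max(bands, key=lambda b: b[1])
        if age >= hi:
            return float(rr)
        raise KeyError(f"no age band containing {age} for {key}")

    def at_risk(self, sex: str, weight_status: str, endpoint: str, age: float) -> float:
        if weight_status == "normal":
            return 1.0
        return self._lookup(("at_risk", sex, weight_status, endpoint), age)

    def diabetic(self, sex: str, endpoint: str, age: float) -> float:
        return self._lookup(("diabetic", sex, "", endpoint), age)

    def mixed(self, sex: str, endpoint: str, age: float, dist: WeightDistribution) -> float:
        """Weight-status-mixed relative risk under ``dist``."""
        return dist.mix(
            self.at_risk(sex, "overweight", endpoint, age),
            self.at_risk(sex, "obese", endpoint, age),
        )


#: printed at-risk RR values: (sex, weight) -> endpoint -> per-band values.
#: BC risk is only defined for women (men cannot enter the BC state).
_AT_RISK_RR = {
    ("male", "overweight"): {
        "mortality": (1.20, 1.20, 1.19, 1.18),
        "chd": (1.35, 1.35, 1.25),
        "stroke": (1.20, 1.15),
        "diabetes": (2.25, 2.15, 2.13),
        "crc": (1.20, 1.18),
    },
    ("male", "obese"): {
        "mortality": (1.55, 1.54, 1.52, 1.50),
        "chd": (2.00, 2.00, 1.70),
        "stroke": (1.50, 1.38),
        "diabetes": (5.50, 5.14, 5.05),
        "crc": (1.40, 1.36),
    },
    ("female", "overweight"): {
        "mortality": (1.15, 1.15, 1.14, 1.14),
        "chd": (1.35, 1.35, 1.25),
        "stroke": (1.20, 1.15),
        "diabetes": (2.30, 2.20, 2.17),
        "bc": (1.00, 1.12),
        "crc": (1.08, 1.07),
    },
    ("female", "obese"): {
        "mortality": (1.50, 1.49, 1.48, 1.45),
        "chd": (2.00, 2.00, 1.70),
        "stroke": (1.55, 1.41),
        "diabetes": (7.00, 6.52, 6.40),
        "bc": (1.00, 1.12),
        "crc": (1.10, 1.09),
    },
}

#: diabetic-vs-healthy RRs; diabetes incidence itself is undefined here.
_DIABETIC_RR = {
    "male": {
        "mortality": (1.57, 1.57, 1.57, 1.57),
        "chd": (2.19, 1.43, 1.33),
        "stroke": (1.83, 1.83),
        "bc": (1.23, 1.23),
        "crc": (1.26, 1.26),
    },
    "female": {
        "mortality": (2.00, 2.00, 2.00, 2.00),
        "chd": (2.19, 1.43, 1.33),
        "stroke": (2.28, 2.28),
        "bc": (1.23, 1.23),
        "crc": (1.26, 1.26),
    },
}


def default_rr_table() -> RRTable:
    """The published relative-risk table used in the evaluation."""
    rows = []
    for (sex, ws), block in _AT_RISK_RR.items():
        for endpoint, values in block.items():
            for (lo, hi), rr in zip(RR_AGE_BANDS[endpoint], values):
                rows.append(("at_risk", sex, ws, endpoint, lo, hi, rr))
    for sex, block in _DIABETIC_RR.items():
        for endpoint, values in block.items():
            for (lo, hi), rr in zip(RR_AGE_BANDS[endpoint], values):
                rows.append(("diabetic", sex, "", endpoint, lo, hi, rr))
    df = pd.DataFrame(
        rows,
        columns=["group", "sex", "weight_status", "endpoint", "age_lo", "age_hi", "rr"],
    )
    return RRTable(df)


# --------------------------------------------------------------------------
# SES adjustment
# --------------------------------------------------------------------------


@dataclass
class SESAdjustmentTable:
    """Relative risk of excess weight in the lower-educated half of the adult
    population, versus the whole population.

    Defined only for overweight/obese and only for countries whose low-SES
    study regions are a subset of the country (Hungary and Bulgaria count
    entirely as low-SES and carry no adjustment)."""

    df: pd.DataFrame  # columns: country, sex, weight_status, rr

    def get(self, country: str, sex: str, weight_status: str) -> float | None:
        m = self.df[
            (self.df.country == country)
            & (self.df.sex == sex)
            & (self.df.weight_status == weight_status)
        ]
        if m.empty:
            return None
        return float(m.rr.iloc[0])

    def has_country(self, country: str) -> bool:
        return bool((self.df.country == country).any())


_SES_RR = {
    # country: ((men ow, men ob), (women ow, women ob))
    "belgium": ((1.05, 1.12), (1.24, 1.39)),
    "finland": ((0.97, 1.03), (1.04, 0.89)),
    "greece": ((1.07, 1.30), (1.33, 1.46)),
    "spain": ((1.07, 1.30), (1.33, 1.46)),
}


def default_ses_table() -> SESAdjustmentTable:
    rows = []
    for country, (men, women) in _SES_RR.items():
        for sex, (rr_ow, rr_ob) in zip(SEXES, (men, women)):
            rows.append((country, sex, "overweight", rr_ow))
            rows.append((country, sex, "obese", rr_ob))
    return SESAdjustmentTable(
        pd.DataFrame(rows, columns=["country", "sex", "weight_status", "rr"])
    )


# --------------------------------------------------------------------------
# EBRB effects
# --------------------------------------------------------------------------


@dataclass
class EBRBTable:
    """Energy balance-related behaviours mediating the intervention effect.

    Each behaviour carries the relative risk of its unhealthy exposure on
    overweight and on obesity, the exposure prevalence in each trial arm,
    and an inclusion flag.  Behaviours with inconclusive literature
    (children: fruits & berries, vegetables, sweets; adults: water, sweets)
    are present but excluded from analysis.
    """

    df: pd.DataFrame
    # columns: behaviour, population, rr_overweight, rr_obese,
    #          p_control, p_intervention, included

    def included(self, population: str) -> pd.DataFrame:
        return self.df[(self.df.population == population) & (self.df.included)]


#: (behaviour, population, rr_ow, rr_ob, included); NaN RR = inconclusive
_EBRB_RR = [
    ("water", "child", 1.33, 1.33, True),
    ("fruits_berries", "child", np.nan, np.nan, False),
    ("vegetables", "child", np.nan, np.nan, False),
    ("screen_time", "child", 2.00, 2.00, True),
    ("sweets", "child", np.nan, np.nan, False),
    ("sugar_sweetened_beverages", "child", 1.22, 1.22, True),
    ("physical_activity", "child", 1.35, 1.35, True),
    ("breakfast", "child", 3.03, 2.13, True),
    ("water", "adult", np.nan, np.nan, False),
    ("fruits_berries", "adult", 1.23, 1.25, True),
    ("vegetables", "adult", 1.19, 1.15, True),
    ("screen_time", "adult", 1.38, 1.38, True),
    ("sweets", "adult", np.nan, np.nan, False),
    ("sugar_sweetened_beverages", "adult", 1.30, 1.30, True),
    ("physical_activity", "adult", 1.07, 1.07, True),
    ("breakfast", "adult", 1.19, 1.19, True),
]


# --------------------------------------------------------------------------
# Epidemiology
# --------------------------------------------------------------------------

_EPI_VALUE_COLS = (
    ["inc_" + d for d in DISEASES]
    + ["mortality"]
    + [f"mort_{d}_{ph}" for d in ("stroke", "chd", "crc", "bc") for ph in ("first", "followup")]
)


@dataclass
class EpidemiologyTable:
    """Annual incidence and mortality probabilities per country, sex and age.

    Columns: ``inc_<disease>`` annual incidence from the at-risk state,
    ``mortality`` all-cause mortality, and ``mort_<disease>_<phase>``
    disease-state mortality for the four tunnel diseases (first year vs
    follow-up).  Diabetes-state mortality is all-cause mortality times the
    diabetic mortality RR, so it has no column here.
    """

    df: pd.DataFrame  # index columns: country, sex, age

    _index: dict = field(default_factory=dict, repr=False)

    def _build_index(self) -> None:
        self._index = {
            (r.country, r.sex, r.age): r for r in self.df.itertuples(index=False)
        }

    def _row(self, country: str, sex: str, age: int):
        if not self._index:
            self._build_index()
        age = int(min(age, MAX_AGE))
        row = self._index.get((country, sex, age))
        if row is None:
            raise KeyError(f"no epidemiology row for ({country}, {sex}, {age})")
        return row

    def incidence(self, country: str, sex: str, age: int, disease: str) -> float:
        v = float(getattr(self._row(country, sex, age), "inc_" + disease))
        if np.isnan(v):
            raise KeyError(f"missing incidence cell ({country}, {sex}, {age}, {disease})")
        return v

    def all_cause_mortality(self, country: str, sex: str, age: int) -> float:
        v = float(self._row(country, sex, age).mortality)
        if np.isnan(v):
            raise KeyError(f"missing all-cause mortality cell ({country}, {sex}, {age})")
        return v

    def disease_mortality(
        self, country: str, sex: str, age: int, disease: str, phase: str
    ) -> float:
        v = float(getattr(self._row(country, sex, age), f"mort_{disease}_{phase}"))
        if np.isnan(v):
            raise KeyError(
                f"missing disease mortality cell ({country}, {sex}, {age}, {disease}, {phase})"
            )
        return v


# --------------------------------------------------------------------------
# Utilities
# --------------------------------------------------------------------------


@dataclass
class UtilityTable:
    """Baseline (at-risk) utilities and per-disease utility decrements.

    Baseline utility is banded on age (10-year bands keyed by lower bound)
    per sex.  Each disease carries a first-year and a follow-up decrement;
    the follow-up decrement is relapse-adjusted downstream.
    """

    baseline: pd.DataFrame  # columns: sex, age_lo, u0
    decrements: pd.DataFrame  # columns: disease, first, followup
    relapse: dict[str, float]  # disease -> annual relapse probability

    def u0(self, sex: str, age: float) -> float:
        rows = self.baseline[self.baseline.sex == sex]
        rows = rows[rows.age_lo <= age]
        if rows.empty:
            raise KeyError(f"no baseline utility for ({sex}, {age})")
        return float(rows.loc[rows.age_lo.idxmax(), "u0"])

    def decrement(self, disease: str, phase: str) -> float:
        m = self.decrements[self.decrements.disease == disease]
        if m.empty:
            raise KeyError(f"no utility decrement for {disease}")
        return float(m[phase].iloc[0])


# --------------------------------------------------------------------------
# Costs
# --------------------------------------------------------------------------


@dataclass
class CostTable:
    """Direct annual disease-state costs (EUR 2016) with the scalar rules
    that derive indirect and comorbidity costs.

    Direct costs are stratified by age: < 65 / >= 65 for every disease,
    except T2DM which uses < 55 / >= 55.  Indirect costs are direct costs
    times a per-disease multiplier (stroke: indirect equals direct; CRC:
    a configurable indirect/direct ratio extrapolated from Finnish data).
    A fixed fraction of the T2DM direct cost is added to each comorbid
    disease state to account for diabetes as a comorbidity.
    """

    df: pd.DataFrame  # columns: country, disease, phase, age_lo, direct
    comorbidity_fractions: dict[str, float] = field(
        default_factory=lambda: dict(COMORBIDITY_FRACTIONS)
    )
    indirect_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(INDIRECT_MULTIPLIERS)
    )
    crc_indirect_ratio: float = 0.35

    def age_lo(self, disease: str, age: float) -> int:
        cut = 55 if disease == "diabetes" else 65
        return 30 if age < cut else cut

    def direct(self, country: str, disease: str, phase: str, age: float) -> float:
        if disease == "diabetes":
            phase = "all"
        m = self.df[
            (self.df.country == country)
            & (self.df.disease == disease)
            & (self.df.phase == phase)
            & (self.df.age_lo == self.age_lo(disease, age))
        ]
        if m.empty or np.isnan(m.direct.iloc[0]):
            raise KeyError(
                f"missing cost cell ({country}, {disease}, {phase}, age_lo="
                f"{self.age_lo(disease, age)})"
            )
        return float(m.direct.iloc[0])

    def indirect_multiplier(self, disease: str) -> float:
        if disease == "crc":
            return self.crc_indirect_ratio
        return self.indirect_multipliers[disease]


# --------------------------------------------------------------------------
# Scalar parameter blocks
# --------------------------------------------------------------------------


@dataclass
class FrictionParams:
    """Friction-cost parameters for productivity loss at death.

    A death removes a worker for one friction period; the hours normally
    worked in that period are valued at the average productivity cost per
    hour, corrected for the probability of being employed and for labour
    time elasticity (production falls 8% when labour time falls 10%,
    i.e. elasticity 0.8).  Applied only at ages 30–64.
    """

    period_days: float = 160.0
    hours_in_period: float = 160.0 * 5.0 / 7.0 * 8.0  # working-day hours in the period
    hourly_productivity: float = 30.0
    unemployment_rate: float = 0.08
    elasticity: float = 0.8
    age_min: int = 30
    age_max: int = 64


@dataclass
class DiscountSettings:
    """Annual discount rates and cohort lead times.

    Effects 1.50%, costs 3%.  Children receive the intervention in
    childhood but enter the Markov model at 30, so their effects and costs
    are additionally discounted over the lead time from the mean
    intervention age to model entry; parents have no lead time.
    """

    effect_rate: float = 0.015
    cost_rate: float = 0.03
    mean_child_age: float = 8.2
    child_lead_years: float = 22.0  # ENTRY_AGE - mean_child_age, rounded
    parent_lead_years: float = 0.0


@dataclass
class InterventionCostLedger:
    """Line items of intervention cost, per country cohort.

    Every item belongs to exactly one component — the school-based
    component delivered to all families, or the high-risk-family (HRF)
    component — and is tagged with whether the healthcare budget holder
    pays it (``payer=True``) or it is a societal-only cost such as family
    transport and time.  Amounts are EUR totals for the country cohort.
    Car-kilometre refunds scale with the country's unleaded-95 gasoline
    price relative to the Belgian reference refund.
    """

    df: pd.DataFrame  # columns: country, item, component, payer, amount

    def total(self, country: str, component: str, payer_only: bool = False) -> float:
        m = self.df[(self.df.country == country) & (self.df.component == component)]
        if payer_only:
            m = m[m.payer]
        return float(m.amount.sum())


def km_refund_rate(gas_price: float, gas_price_reference: float,
                   reference_rate: float = 0.3363) -> float:
    """Per-kilometre car refund scaled from the Belgian reference refund by
    the ratio of unleaded-95 gasoline prices."""
    if gas_price_reference <= 0:
        raise ValueError("reference gasoline price must be positive")
    return reference_rate * gas_price / gas_price_reference


@dataclass
class TrackingMatrix:
    """3x3 row-stochastic matrix extrapolating child weight status to adult
    weight status at Markov entry (rows: child normal/overweight/obese)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("tracking matrix must be 3x3")
        if (m < -1e-12).any() or (m > 1 + 1e-12).any():
            raise ValueError("tracking matrix entries must be in [0, 1]")
        if np.abs(m.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("tracking matrix rows must sum to 1")
        object.__setattr__(self, "matrix", m)


@dataclass
class CohortSettings:
    """Trial cohort composition per country and arm."""

    df: pd.DataFrame  # columns: country, arm, n_families, n_hrf
    parent_age_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "<30": 0.05, "30-34": 0.20, "35-39": 0.30,
            "40-44": 0.25, "45-49": 0.12, ">50": 0.08,
        }
    )
    parents_per_family: float = 2.0
    child_sex_split: float = 0.5  # share of boys

    def n_families(self, country: str, arm: str) -> float:
        m = self.df[(self.df.country == country) & (self.df.arm == arm)]
        if m.empty:
            raise KeyError(f"no cohort row for ({country}, {arm})")
        return float(m.n_families.iloc[0])

    def n_hrf(self, country: str, arm: str) -> float:
        m = self.df[(self.df.country == country) & (self.df.arm == arm)]
        if m.empty:
            raise KeyError(f"no cohort row for ({country}, {arm})")
        return float(m.n_hrf.iloc[0])


@dataclass
class MarkovSettings:
    entry_age: int = ENTRY_AGE
    n_cycles: int = N_CYCLES
    half_cycle_correction: bool = False
    rate_space_rr: bool = False  # apply RRs on rates instead of probabilities


# --------------------------------------------------------------------------
# The pack
# --------------------------------------------------------------------------


@dataclass
class ParameterPack:
    """Validated container of every model input for one country set."""

    rr: RRTable
    ses: SESAdjustmentTable
    ebrb: EBRBTable
    epidemiology: EpidemiologyTable
    utilities: UtilityTable
    costs: CostTable
    friction: dict[str, FrictionParams]
    discount: DiscountSettings
    ledger: InterventionCostLedger
    tracking: TrackingMatrix
    prevalence: dict[tuple[str, str], WeightDistribution]  # adults, (country, sex)
    child_prevalence: dict[tuple[str, str], WeightDistribution]
    cohorts: CohortSettings
    he_ratio: dict[str, float]  # health expenditure per capita / Belgian value
    markov: MarkovSettings = field(default_factory=MarkovSettings)
    meta: dict = field(default_factory=dict)

    def countries(self) -> tuple[str, ...]:
        return tuple(sorted({c for c, _ in self.prevalence}))


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------


def validate_pack(pack: ParameterPack) -> list[str]:
    """Check every type invariant; returns a list of violations (empty = valid)."""
    v: list[str] = []

    if len(STATES) != 11:  # pragma: no cover - structural constant
        v.append("HealthState: state registry does not have 11 members")

    if (pack.rr.df.rr <= 0).any():
        v.append("RRTable: non-positive relative risk")
    male_bc = pack.rr.df[
        (pack.rr.df.group == "at_risk")
        & (pack.rr.df.sex == "male")
        & (pack.rr.df.endpoint == "bc")
    ]
    if not male_bc.empty:
        v.append("RRTable: at-risk BC relative risks defined for males")

    if (pack.ses.df.rr <= 0).any():
        v.append("SESAdjustmentTable: non-positive relative risk")
    if (~pack.ses.df.weight_status.isin(["overweight", "obese"])).any():
        v.append("SESAdjustmentTable: adjustment defined outside overweight/obese")

    inc_ebrb = pack.ebrb.df[pack.ebrb.df.included]
    if inc_ebrb[["rr_overweight", "rr_obese"]].isna().any().any():
        v.append("EBRBTable: included behaviour missing a relative risk")
    for col in ("p_control", "p_intervention"):
        bad = inc_ebrb[(inc_ebrb[col] < 0) | (inc_ebrb[col] > 1)]
        if not bad.empty:
            v.append(f"EBRBTable: {col} outside [0, 1]")

    epi = pack.epidemiology.df
    vals = epi[[c for c in _EPI_VALUE_COLS if c in epi.columns]]
    if ((vals < 0) | (vals > 1)).any().any():
        v.append("EpidemiologyTable: probability outside [0, 1]")
    male_bc_inc = epi[(epi.sex == "male") & (epi.inc_bc > 0)]
    if not male_bc_inc.empty:
        v.append("EpidemiologyTable: non-zero male breast-cancer incidence")

    if ((pack.utilities.baseline.u0 < 0) | (pack.utilities.baseline.u0 > 1)).any():
        v.append("UtilityTable: baseline utility outside [0, 1]")
    dec = pack.utilities.decrements
    if (dec["first"] < dec["followup"]).any():
        v.append("UtilityTable: first-year utility exceeds follow-up utility")
    if ((dec[["first", "followup"]] < 0).any().any()):
        v.append("UtilityTable: negative decrement")
    for d, p in pack.utilities.relapse.items():
        if not (0 <= p <= 1):
            v.append(f"UtilityTable: relapse probability for {d} outside [0, 1]")

    if (pack.costs.df.direct.dropna() < 0).any():
        v.append("CostTable: negative direct cost")
    for d, f in pack.costs.comorbidity_fractions.items():
        if not (0 <= f <= 1):
            v.append(f"CostTable: comorbidity fraction for {d} outside [0, 1]")

    for country, fp in pack.friction.items():
        if not (0 < fp.elasticity <= 1):
            v.append(f"FrictionParams[{country}]: elasticity outside (0, 1]")
        if fp.period_days <= 0:
            v.append(f"FrictionParams[{country}]: non-positive friction period")
        if not (0 <= fp.unemployment_rate <= 1):
            v.append(f"FrictionParams[{country}]: unemployment rate outside [0, 1]")

    if pack.discount.effect_rate < 0 or pack.discount.cost_rate < 0:
        v.append("DiscountSettings: negative discount rate")

    if (pack.ledger.df.amount < 0).any():
        v.append("InterventionCostLedger: negative amount")
    if (~pack.ledger.df.component.isin(["school", "hrf"])).any():
        v.append("InterventionCostLedger: unknown component tag")

    try:
        TrackingMatrix(pack.tracking.matrix)
    except ValueError as e:
        v.append(f"TrackingMatrix: {e}")

    for (country, sex), dist in {**pack.prevalence, **pack.child_prevalence}.items():
        s = sum(dist.as_tuple())
        if abs(s - 1) > 1e-9:
            v.append(f"WeightDistribution[{country}, {sex}]: sums to {s}")

    props = pack.cohorts.parent_age_proportions
    if abs(sum(props.values()) - 1) > 1e-9:
        v.append("CohortSettings: parent age-group proportions do not sum to 1")
    if any(p < 0 for p in props.values()):
        v.append("CohortSettings: negative age-group proportion")

    if REFERENCE_COUNTRY not in pack.he_ratio:
        v.append("he_ratio: reference country missing")

    return v


# --------------------------------------------------------------------------
# Imputation (Belgium as reference country)
# --------------------------------------------------------------------------


def impute_cost(pack: ParameterPack, target_country: str) -> CostTable:
    """Fill missing cost cells for ``target_country`` from the Belgian cost
    times the ratio of health expenditure per capita.  Present cells are
    left untouched."""
    if target_country not in pack.he_ratio or REFERENCE_COUNTRY not in pack.he_ratio:
        raise KeyError(f"missing health-expenditure ratio for {target_country}")
    r = pack.he_ratio[target_country] / pack.he_ratio[REFERENCE_COUNTRY]

    df = pack.costs.df.copy()
    ref = df[df.country == REFERENCE_COUNTRY].set_index(["disease", "phase", "age_lo"])
    tgt_mask = df.country == target_country
    for i in df[tgt_mask].index:
        if np.isnan(df.at[i, "direct"]):
            key = (df.at[i, "disease"], df.at[i, "phase"], df.at[i, "age_lo"])
            df.at[i, "direct"] = float(ref.loc[key, "direct"]) * r
    # cells absent altogether for the target are added from the reference
    present = set(
        map(tuple, df[tgt_mask][["disease", "phase", "age_lo"]].itertuples(index=False))
    )
    new_rows = []
    for key, row in ref.iterrows():
        if key not in present:
            new_rows.append((target_country, *key, float(row.direct) * r))
    if new_rows:
        df = pd.concat(
            [df, pd.DataFrame(new_rows, columns=df.columns)], ignore_index=True
        )
    return dataclasses.replace(pack.costs, df=df)


def impute_epidemiology(
    pack: ParameterPack, target_country: str, quantity: str
) -> EpidemiologyTable:
    """Fill missing epidemiology cells for ``target_country``.

    For each disease the ratio of the target country's total (summed over
    cells present in both countries) to the Belgian total scales the
    Belgian cells into the gaps.  ``quantity`` selects the column group:
    ``"incidence"`` or ``"mortality"``.
    """
    if quantity == "incidence":
        cols = ["inc_" + d for d in DISEASES]
    elif quantity == "mortality":
        cols = ["mortality"] + [
            f"mort_{d}_{ph}" for d in ("stroke", "chd", "crc", "bc")
            for ph in ("first", "followup")
        ]
    else:
        raise ValueError(f"unknown quantity {quantity!r}")

    df = pack.epidemiology.df.copy()
    ref = df[df.country == REFERENCE_COUNTRY].set_index(["sex", "age"]).sort_index()
    tgt = df.country == target_country
    for col in cols:
        if col not in df.columns:
            continue
        tgt_vals = df.loc[tgt, col]
        missing = tgt_vals.isna()
        if not missing.any():
            continue
        both = df.loc[tgt & df[col].notna()]
        ref_aligned = ref.loc[
            list(zip(both.sex, both.age)), col
        ]
        ref_total = float(ref_aligned.sum())
        if ref_total == 0:
            raise ZeroDivisionError(
                f"Belgian total for {col} is zero; cannot impute {target_country}"
            )
        ratio = float(both[col].sum()) / ref_total
        for i in df.loc[tgt].index[missing.values]:
            df.at[i, col] = (
                float(ref.loc[(df.at[i, "sex"], df.at[i, "age"]), col]) * ratio
            )
    return EpidemiologyTable(df)


# --------------------------------------------------------------------------
# Synthetic pack generation
# --------------------------------------------------------------------------

# country-level synthetic anchors (plausible 2016 magnitudes, source=synthetic)
_HE_RATIO = {"belgium": 1.00, "finland": 0.95, "greece": 0.55,
             "spain": 0.65, "hungary": 0.35, "bulgaria": 0.25}
_UNEMPLOYMENT = {"belgium": 0.077, "finland": 0.087, "greece": 0.215,
                 "spain": 0.196, "hungary": 0.051, "bulgaria": 0.076}
_HOURLY_PRODUCTIVITY = {"belgium": 40.0, "finland": 38.0, "greece": 18.0,
                        "spain": 22.0, "hungary": 12.0, "bulgaria": 9.0}
_GAS_PRICE = {"belgium": 1.39, "finland": 1.48, "greece": 1.55,
              "spain": 1.21, "hungary": 1.15, "bulgaria": 1.05}

#: Belgian direct annual costs (EUR 2016, synthetic magnitudes):
#: disease -> phase -> {age_lo: cost}
_BELGIAN_DIRECT_COST = {
    "diabetes": {"all": {30: 3200.0, 55: 4100.0}},
    "stroke": {"first": {30: 12000.0, 65: 14000.0}, "followup": {30: 4000.0, 65: 5000.0}},
    "chd": {"first": {30: 9000.0, 65: 10000.0}, "followup": {30: 2500.0, 65: 3000.0}},
    "crc": {"first": {30: 25000.0, 65: 27000.0}, "followup": {30: 5000.0, 65: 6000.0}},
    "bc": {"first": {30: 20000.0, 65: 21000.0}, "followup": {30: 4000.0, 65: 4500.0}},
}

_UTILITY_DECREMENTS = {
    # disease: (first-year, follow-up) decrement
    "diabetes": (0.10, 0.10),
    "stroke": (0.25, 0.15),
    "chd": (0.20, 0.12),
    "crc": (0.25, 0.15),
    "bc": (0.20, 0.12),
}
_RELAPSE = {"diabetes": 0.0, "stroke": 0.10, "chd": 0.08, "crc": 0.05, "bc": 0.05}

#: adult weight-status prevalence anchors (normal, overweight, obese)
_ADULT_PREV = {
    ("belgium", "male"): (0.42, 0.42, 0.16),
    ("belgium", "female"): (0.55, 0.29, 0.16),
    ("finland", "male"): (0.38, 0.44, 0.18),
    ("finland", "female"): (0.50, 0.31, 0.19),
    ("greece", "male"): (0.36, 0.45, 0.19),
    ("greece", "female"): (0.52, 0.30, 0.18),
    ("spain", "male"): (0.39, 0.44, 0.17),
    ("spain", "female"): (0.53, 0.30, 0.17),
    ("hungary", "male"): (0.36, 0.42, 0.22),
    ("hungary", "female"): (0.48, 0.30, 0.22),
    ("bulgaria", "male"): (0.40, 0.42, 0.18),
    ("bulgaria", "female"): (0.54, 0.28, 0.18),
}
_CHILD_PREV = {
    ("belgium", "male"): (0.78, 0.15, 0.07),
    ("belgium", "female"): (0.79, 0.15, 0.06),
    ("finland", "male"): (0.76, 0.16, 0.08),
    ("finland", "female"): (0.78, 0.15, 0.07),
    ("greece", "male"): (0.60, 0.26, 0.14),
    ("greece", "female"): (0.64, 0.24, 0.12),
    ("spain", "male"): (0.66, 0.23, 0.11),
    ("spain", "female"): (0.69, 0.21, 0.10),
    ("hungary", "male"): (0.72, 0.18, 0.10),
    ("hungary", "female"): (0.73, 0.18, 0.09),
    ("bulgaria", "male"): (0.70, 0.19, 0.11),
    ("bulgaria", "female"): (0.72, 0.18, 0.10),
}

#: weight-status tracking from childhood into adulthood (synthetic, shaped
#: like published tracking studies: excess weight persists strongly)
_TRACKING = np.array([
    [0.85, 0.12, 0.03],
    [0.30, 0.50, 0.20],
    [0.10, 0.30, 0.60],
])


def _synthetic_epidemiology(rng: np.random.Generator) -> EpidemiologyTable:
    ages = np.arange(ENTRY_AGE, MAX_AGE + 1)
    rows = []
    for country in COUNTRIES:
        cf = float(rng.uniform(0.85, 1.15))  # country-level scaling
        for sex in SEXES:
            sf = 1.35 if sex == "male" else 1.0  # male excess mortality
            mortality = np.clip(2.6e-5 * sf * cf * np.exp(0.088 * (ages - 30)), 0, 0.6)
            inc_diabetes = np.clip(
                0.0015 * cf * np.exp(0.045 * (ages - 30)) / (1 + np.exp(0.08 * (ages - 75))),
                0, 0.05,
            )
            inc_chd = np.clip(4.0e-4 * sf * cf * np.exp(0.055 * (ages - 30)), 0, 0.08)
            inc_stroke = np.clip(2.0e-4 * sf * cf * np.exp(0.06 * (ages - 30)), 0, 0.06)
            inc_crc = np.clip(8.0e-5 * cf * np.exp(0.055 * (ages - 30)), 0, 0.03)
            if sex == "female":
                inc_bc = np.clip(4.0e-4 * cf * (1 + 0.02 * (ages - 30)), 0, 0.01)
            else:
                inc_bc = np.zeros_like(ages, dtype=float)
            age_ramp = 1 + 0.015 * (ages - 30)
            mort = {
                ("stroke", "first"): np.clip(0.15 * cf * age_ramp * 0.5, 0, 0.8),
                ("stroke", "followup"): np.clip(0.05 * cf * age_ramp * 0.5, 0, 0.5),
                ("chd", "first"): np.clip(0.10 * cf * age_ramp * 0.5, 0, 0.7),
                ("chd", "followup"): np.clip(0.03 * cf * age_ramp * 0.5, 0, 0.4),
                ("crc", "first"): np.clip(0.20 * cf * age_ramp * 0.5, 0, 0.8),
                ("crc", "followup"): np.clip(0.06 * cf * age_ramp * 0.5, 0, 0.5),
                ("bc", "first"): np.clip(0.05 * cf * age_ramp * 0.5, 0, 0.5),
                ("bc", "followup"): np.clip(0.02 * cf * age_ramp * 0.5, 0, 0.3),
            }
            for k, age in enumerate(ages):
                rows.append(
                    dict(
                        country=country, sex=sex, age=int(age),
                        inc_diabetes=inc_diabetes[k], inc_stroke=inc_stroke[k],
                        inc_chd=inc_chd[k], inc_crc=inc_crc[k], inc_bc=inc_bc[k],
                        mortality=mortality[k],
                        **{
                            f"mort_{d}_{ph}": mort[(d, ph)][k]
                            for (d, ph) in mort
                        },
                    )
                )
    return EpidemiologyTable(pd.DataFrame(rows))


def _synthetic_ledger(rng: np.random.Generator) -> InterventionCostLedger:
    rows = []
    for country in COUNTRIES:
        scale = _HE_RATIO[country]  # poorer countries: cheaper delivery
        rate = km_refund_rate(_GAS_PRICE[country], _GAS_PRICE[REFERENCE_COUNTRY])
        km_staff = 4000.0
        km_families = 9000.0
        school = [
            ("staff_school_communication", True, 9000.0 * scale),
            ("staff_training_delivery", True, 5000.0 * scale),
            ("staff_transport_km_refund", True, km_staff * rate),
            ("teacher_training_time", True, 7000.0 * scale),
            ("teacher_transport", False, 1500.0 * scale),
            ("teacher_implementation_time", False, 12000.0 * scale),
            ("community_stakeholder_time", False, 3000.0 * scale),
            ("newsletters_production_distribution", True, 2500.0 * scale),
            ("intervention_material", True, 4000.0 * scale),
        ]
        hrf = [
            ("staff_hrf_communication", True, 6000.0 * scale),
            ("staff_session_delivery", True, 11000.0 * scale),
            ("staff_transport_km_refund_hrf", True, km_staff * 0.5 * rate),
            ("hrf_family_transport_km_refund", False, km_families * rate),
            ("hrf_family_session_time", False, 8000.0 * scale),
            ("hrf_lifestyle_costs", False, 5000.0 * scale),
            ("findrisc_questionnaire_handling", True, 3500.0 * scale),
            ("sms_intervention", True, 4500.0 * scale),
        ]
        for item, payer, amount in school:
            rows.append((country, item, "school", payer, round(amount, 2)))
        for item, payer, amount in hrf:
            rows.append((country, item, "hrf", payer, round(amount, 2)))
    return InterventionCostLedger(
        pd.DataFrame(rows, columns=["country", "item", "component", "payer", "amount"])
    )


def generate_synthetic_pack(seed: int = 0) -> ParameterPack:
    """Deterministic synthetic parameter pack.

    Embeds every published constant (relative-risk tables, SES adjustments,
    EBRB relative risks, comorbidity fractions, indirect multipliers,
    discount rates, friction defaults) and fills the unpublished country
    tables (costs, utilities, incidence/mortality, tracking, cohort sizes,
    exposure prevalences) with plausible magnitudes.  Fully reproducible
    from ``seed``; the filled values are flagged ``source=synthetic`` in the
    pack metadata.
    """
    rng = np.random.default_rng(seed)

    # EBRB table: published RRs, synthetic arm exposure prevalences
    ebrb_rows = []
    for behaviour, population, rr_ow, rr_ob, included in _EBRB_RR:
        p_ctrl = float(np.round(rng.uniform(0.2, 0.6), 3))
        # intervention lowers unhealthy exposure by a relative 5-20%
        p_int = float(np.round(p_ctrl * rng.uniform(0.80, 0.95), 3))
        ebrb_rows.append(
            (behaviour, population, rr_ow, rr_ob, p_ctrl, p_int, included)
        )
    ebrb = EBRBTable(
        pd.DataFrame(
            ebrb_rows,
            columns=["behaviour", "population", "rr_overweight", "rr_obese",
                     "p_control", "p_intervention", "included"],
        )
    )

    epidemiology = _synthetic_epidemiology(rng)

    # baseline utilities: decline gently with age, women slightly higher
    base_rows = []
    for sex in SEXES:
        for age_lo in range(30, 100, 10):
            u = 0.93 - 0.012 * (age_lo - 30) / 10 - (0.01 if sex == "male" else 0.0)
            base_rows.append((sex, age_lo, round(u, 4)))
    utilities = UtilityTable(
        baseline=pd.DataFrame(base_rows, columns=["sex", "age_lo", "u0"]),
        decrements=pd.DataFrame(
            [(d, f, fu) for d, (f, fu) in _UTILITY_DECREMENTS.items()],
            columns=["disease", "first", "followup"],
        ),
        relapse=dict(_RELAPSE),
    )

    cost_rows = []
    for country in COUNTRIES:
        r = _HE_RATIO[country]
        for disease, phases in _BELGIAN_DIRECT_COST.items():
            for phase, bands in phases.items():
                for age_lo, cost in bands.items():
                    cost_rows.append(
                        (country, disease, phase, age_lo, round(cost * r, 2))
                    )
    costs = CostTable(
        pd.DataFrame(cost_rows, columns=["country", "disease", "phase", "age_lo", "direct"])
    )

    friction = {
        c: FrictionParams(
            hourly_productivity=_HOURLY_PRODUCTIVITY[c],
            unemployment_rate=_UNEMPLOYMENT[c],
        )
        for c in COUNTRIES
    }

    cohort_rows = []
    for country in COUNTRIES:
        n_int = int(rng.integers(900, 1200))
        n_ctrl = int(rng.integers(800, 1100))
        cohort_rows.append((country, "intervention", n_int, int(round(n_int * 0.20))))
        cohort_rows.append((country, "control", n_ctrl, int(round(n_ctrl * 0.17))))
    cohorts = CohortSettings(
        pd.DataFrame(cohort_rows, columns=["country", "arm", "n_families", "n_hrf"])
    )

    pack = ParameterPack(
        rr=default_rr_table(),
        ses=default_ses_table(),
        ebrb=ebrb,
        epidemiology=epidemiology,
        utilities=utilities,
        costs=costs,
        friction=friction,
        discount=DiscountSettings(),
        ledger=_synthetic_ledger(rng),
        tracking=TrackingMatrix(_TRACKING.copy()),
        prevalence={k: WeightDistribution(*v) for k, v in _ADULT_PREV.items()},
        child_prevalence={k: WeightDistribution(*v) for k, v in _CHILD_PREV.items()},
        cohorts=cohorts,
        he_ratio=dict(_HE_RATIO),
        meta={
            "source": "synthetic",
            "seed": int(seed),
            "currency": "EUR2016",
            "generator_version": 1,
            "gas_price_eur_per_l": dict(_GAS_PRICE),
        },
    )
    violations = validate_pack(pack)
    if violations:  # pragma: no cover - generator must always be valid
        raise PackValidationError("; ".join(violations))
    return pack


# --------------------------------------------------------------------------
# I/O: directory of CSVs + manifest.yaml
# --------------------------------------------------------------------------

_CSV_FILES = {
    "rr_table.csv": "rr",
    "ses_adjust.csv": "ses",
    "ebrb_effects.csv": "ebrb",
    "epidemiology.csv": "epidemiology",
    "utilities.csv": None,  # composite, handled separately
    "costs.csv": "costs",
    "intervention_costs.csv": "ledger",
    "tracking.csv": None,
    "weight_prevalence.csv": None,
}


def write_pack(pack: ParameterPack, path: str | Path) -> Path:
    """Write a pack as a directory of CSV tables plus ``manifest.yaml``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    pack.rr.df.to_csv(path / "rr_table.csv", index=False)
    pack.ses.df.to_csv(path / "ses_adjust.csv", index=False)
    pack.ebrb.df.to_csv(path / "ebrb_effects.csv", index=False)
    pack.epidemiology.df.to_csv(path / "epidemiology.csv", index=False)
    pack.costs.df.to_csv(path / "costs.csv", index=False)
    pack.ledger.df.to_csv(path / "intervention_costs.csv", index=False)
    pd.DataFrame(pack.tracking.matrix, columns=list(WEIGHT_STATUSES)).assign(
        child_status=list(WEIGHT_STATUSES)
    ).to_csv(path / "tracking.csv", index=False)

    util = pack.utilities.baseline.assign(kind="baseline", disease="", followup=np.nan)
    util = util.rename(columns={"u0": "first"})
    dec = pack.utilities.decrements.assign(kind="decrement", sex="", age_lo=np.nan)
    rel = pd.DataFrame(
        [("relapse", d, "", np.nan, p, np.nan) for d, p in pack.utilities.relapse.items()],
        columns=["kind", "disease", "sex", "age_lo", "first", "followup"],
    )
    cols = ["kind", "disease", "sex", "age_lo", "first", "followup"]
    pd.concat([util[cols], dec[cols], rel[cols]]).to_csv(
        path / "utilities.csv", index=False
    )

    prev_rows = [
        (kind, c, s, *d.as_tuple())
        for kind, table in (("adult", pack.prevalence), ("child", pack.child_prevalence))
        for (c, s), d in table.items()
    ]
    pd.DataFrame(
        prev_rows,
        columns=["population", "country", "sex", "p_normal", "p_overweight", "p_obese"],
    ).to_csv(path / "weight_prevalence.csv", index=False)

    manifest = {
        "meta": pack.meta,
        "discount": dataclasses.asdict(pack.discount),
        "markov": dataclasses.asdict(pack.markov),
        "he_ratio": pack.he_ratio,
        "friction": {c: dataclasses.asdict(f) for c, f in pack.friction.items()},
        "cost_scalars": {
            "comorbidity_fractions": pack.costs.comorbidity_fractions,
            "indirect_multipliers": pack.costs.indirect_multipliers,
            "crc_indirect_ratio": pack.costs.crc_indirect_ratio,
        },
        "cohorts": {
            "table": pack.cohorts.df.to_dict("records"),
            "parent_age_proportions": pack.cohorts.parent_age_proportions,
            "parents_per_family": pack.cohorts.parents_per_family,
            "child_sex_split": pack.cohorts.child_sex_split,
        },
    }
    with open(path / MANIFEST_NAME, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def load_pack(path: str | Path, validate: bool = True) -> ParameterPack:
    """Load a pack directory written by :func:`write_pack`.

    Raises :class:`PackSchemaError` for a missing table and
    :class:`PackValidationError` when validation fails (unless
    ``validate=False``).
    """
    path = Path(path)
    if not path.exists():
        raise PackSchemaError(f"pack path {path} does not exist")
    required = list(_CSV_FILES) + [MANIFEST_NAME]
    for name in required:
        if not (path / name).exists():
            raise PackSchemaError(f"pack is missing table {name}")

    with open(path / MANIFEST_NAME) as fh:
        manifest = yaml.safe_load(fh)

    rr = RRTable(pd.read_csv(path / "rr_table.csv").fillna({"weight_status": ""}))
    rr.df["weight_status"] = rr.df["weight_status"].fillna("")
    ses = SESAdjustmentTable(pd.read_csv(path / "ses_adjust.csv"))
    ebrb = EBRBTable(pd.read_csv(path / "ebrb_effects.csv"))
    epidemiology = EpidemiologyTable(pd.read_csv(path / "epidemiology.csv"))
    costs_df = pd.read_csv(path / "costs.csv")
    cs = manifest.get("cost_scalars", {})
    costs = CostTable(
        costs_df,
        comorbidity_fractions=dict(cs.get("comorbidity_fractions", COMORBIDITY_FRACTIONS)),
        indirect_multipliers=dict(cs.get("indirect_multipliers", INDIRECT_MULTIPLIERS)),
        crc_indirect_ratio=float(cs.get("crc_indirect_ratio", 0.35)),
    )
    ledger = InterventionCostLedger(pd.read_csv(path / "intervention_costs.csv"))

    track_df = pd.read_csv(path / "tracking.csv")
    tracking = TrackingMatrix(track_df[list(WEIGHT_STATUSES)].to_numpy(dtype=float))

    util_df = pd.read_csv(path / "utilities.csv")
    base = util_df[util_df.kind == "baseline"][["sex", "age_lo", "first"]].rename(
        columns={"first": "u0"}
    )
    base["age_lo"] = base["age_lo"].astype(int)
    dec = util_df[util_df.kind == "decrement"][["disease", "first", "followup"]]
    relapse = {
        str(r.disease): float(getattr(r, "first"))  # "first" column holds the probability
        for r in util_df[util_df.kind == "relapse"].itertuples(index=False)
    }
    utilities = UtilityTable(
        baseline=base.reset_index(drop=True),
        decrements=dec.reset_index(drop=True),
        relapse=relapse,
    )

    prev_df = pd.read_csv(path / "weight_prevalence.csv")
    prevalence, child_prevalence = {}, {}
    for r in prev_df.itertuples(index=False):
        dist = WeightDistribution(r.p_normal, r.p_overweight, r.p_obese)
        target = prevalence if r.population == "adult" else child_prevalence
        target[(r.country, r.sex)] = dist

    cohorts = CohortSettings(
        df=pd.DataFrame(manifest["cohorts"]["table"]),
        parent_age_proportions=dict(manifest["cohorts"]["parent_age_proportions"]),
        parents_per_family=float(manifest["cohorts"]["parents_per_family"]),
        child_sex_split=float(manifest["cohorts"]["child_sex_split"]),
    )

    pack = ParameterPack(
        rr=rr,
        ses=ses,
        ebrb=ebrb,
        epidemiology=epidemiology,
        utilities=utilities,
        costs=costs,
        friction={c: FrictionParams(**f) for c, f in manifest["friction"].items()},
        discount=DiscountSettings(**manifest["discount"]),
        ledger=ledger,
        tracking=tracking,
        prevalence=prevalence,
        child_prevalence=child_prevalence,
        cohorts=cohorts,
        he_ratio={c: float(v) for c, v in manifest["he_ratio"].items()},
        markov=MarkovSettings(**manifest["markov"]),
        meta=dict(manifest.get("meta", {})),
    )
    if validate:
        violations = validate_pack(pack)
        if violations:
            raise PackValidationError("; ".join(violations))
    return pack
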