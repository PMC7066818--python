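"""Payer-perspective budget impact analysis.

Annual, undiscounted net cost to the healthcare budget holder of rolling
the intervention out every three years over a 1-30-year horizon.  Only
ledger items the payer actually funds count (family transport and time
are societal costs and drop out); cost offsets are restricted to avoided
direct healthcare costs in the parent cohorts, because children's
benefits fall beyond the horizon.  Each re-implementation launches a
fresh parent cohort whose offsets accrue from its own first year and
stack with those of earlier cohorts.  The target population is assumed
stable over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision_front import parent_entry_schedule
from .markov_engine import run_cohort
from .outcomes import _entry_distributions, direct_cost_stream
from .parampack import ParameterPack


@dataclass
class BIAConfig:
    horizon: int = 30
    period: int = 3  # years between implementations
    population_families: float = 1000.0  # constant target population

    def __post_init__(self) -> None:
        if not (1 <= self.horizon <= 30):
            raise ValueError("horizon must be in [1, 30] years")
        if self.period < 1:
            raise ValueError("re-implementation period must be >= 1 year")


def implementation_schedule(horizon: int, period: int = 3) -> list[int]:
    """Implementation years {1, 1+period, 1+2*period, ...} within the horizon."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    return list(range(1, horizon + 1, period))


def payer_intervention_cost(pack: ParameterPack, country: str) -> float:
    """Per-family payer cost of one implementation (school component over
    all families plus HRF component over HRF families, payer items only)."""
    if "payer" not in pack.ledger.df.columns:
        raise KeyError("intervention ledger has no payer tags")
    n_fam = pack.cohorts.n_families(country, "intervention")
    n_hrf = pack.cohorts.n_hrf(country, "intervention")
    school = pack.ledger.total(country, "school", payer_only=True) / n_fam
    hrf = pack.ledger.total(country, "hrf", payer_only=True) / n_hrf
    hrf_share = n_hrf / n_fam
    return school + hrf * hrf_share


def parent_offset_stream(pack: ParameterPack, country: str, horizon: int) -> np.ndarray:
    """Avoided direct healthcare cost per family per year after one
    implementation (control minus intervention parent cohort), undiscounted.

    Index 0 is the implementation year itself."""
    arms = _entry_distributions(pack, country, None, None)
    sched = parent_entry_schedule(pack.cohorts.parent_age_proportions)
    streams = {}
    for arm in ("control", "intervention"):
        per_parent = pack.cohorts.parents_per_family / 2.0
        total = None
        for sex in ("male", "female"):
            traces = run_cohort(
                pack, country, sex, arms[arm][("adult", sex)], entry_schedule=sched,
                _matrices=arms[arm][("mats_adult", sex)],
            )
            s = direct_cost_stream(traces, pack, country) * per_parent
            total = s if total is None else total + s
        streams[arm] = total
    diff = streams["control"] - streams["intervention"]
    out = np.zeros(horizon)
    k = min(horizon, len(diff))
    out[:k] = diff[:k]
    return out


def annual_budget_impact(
    payer_cost_per_family: float,
    offset_stream: np.ndarray,
    config: BIAConfig,
) -> pd.DataFrame:
    """Year-by-year net payer cost.

    ``offset_stream[k]`` is the per-family offset accruing k years after an
    implementation; offsets from all prior implementations stack.  Returns
    columns: year, intervention_cost, offsets, net, cumulative."""
    years = np.arange(1, config.horizon + 1)
    impl = set(implementation_schedule(config.horizon, config.period))
    pop = config.population_families
    rows = []
    cumulative = 0.0
    for y in years:
        cost = payer_cost_per_family * pop if y in impl else 0.0
        offsets = sum(
            offset_stream[y - y0]
            for y0 in impl
            if y0 <= y and (y - y0) < len(offset_stream)
        ) * pop
        net = cost - offsets
        cumulative += net
        rows.append((int(y), cost, offsets, net, cumulative))
    return pd.DataFrame(
        rows, columns=["year", "intervention_cost", "offsets", "net", "cumulative"]
    )


def run_bia(pack: ParameterPack, country: str, config: BIAConfig) -> pd.DataFrame:
    """End-to-end budget impact for one country (child offsets excluded)."""
    cost = payer_intervention_cost(pack, country)
    offsets = parent_offset_stream(pack, country, config.horizon)
    return annual_budget_impact(cost, offsets, config)
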