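"""One-way (tornado) and probabilistic sensitivity analysis.

The tornado perturbs one parameter group at a time by a +/-30% span and
ranks parameters by the width of the induced interval in the chosen
outcome.  The probabilistic sensitivity analysis (second-order Monte
Carlo) jointly redraws parameters from their assigned families — gamma
for costs, beta for probabilities and utilities, lognormal for relative
risks and risk reductions — and summarises the cloud of incremental
(cost, QALY) pairs and the cost-effectiveness acceptability curve.

The published protocol assigns distribution families but no dispersions;
the default standard error is 30% of the base value (mirroring the
tornado span) and can be overridden per parameter class.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parampack import DISEASES, ParameterPack

# parameter groups addressable by the tornado
TORNADO_PARAMETERS = (
    ["cost:" + d for d in DISEASES]
    + ["utility_decrement:" + d for d in DISEASES]
    + ["incidence:" + d for d in DISEASES]
    + ["mortality:all_cause"]
    + ["intervention_cost:school", "intervention_cost:hrf"]
    + ["effect:rrr"]
)


def scale_parameter(pack: ParameterPack, name: str, factor: float) -> ParameterPack:
    """Return a deep-copied pack with one parameter group scaled by
    ``factor``.  Probabilities are clipped to [0, 1] with a warning."""
    p = copy.deepcopy(pack)
    kind, _, target = name.partition(":")
    if kind == "cost":
        mask = p.costs.df.disease == target
        if not mask.any():
            raise KeyError(f"unknown cost parameter {name!r}")
        p.costs.df.loc[mask, "direct"] *= factor
    elif kind == "utility_decrement":
        mask = p.utilities.decrements.disease == target
        if not mask.any():
            raise KeyError(f"unknown utility parameter {name!r}")
        for col in ("first", "followup"):
            p.utilities.decrements.loc[mask, col] = _clip_prob(
                p.utilities.decrements.loc[mask, col] * factor, name
            )
    elif kind == "incidence":
        col = "inc_" + target
        if col not in p.epidemiology.df.columns:
            raise KeyError(f"unknown incidence parameter {name!r}")
        p.epidemiology.df[col] = _clip_prob(p.epidemiology.df[col] * factor, name)
        p.epidemiology._index = {}
    elif kind == "mortality":
        cols = ["mortality"] + [
            c for c in p.epidemiology.df.columns if c.startswith("mort_")
        ]
        for c in cols:
            p.epidemiology.df[c] = _clip_prob(p.epidemiology.df[c] * factor, name)
        p.epidemiology._index = {}
    elif kind == "intervention_cost":
        mask = p.ledger.df.component == target
        if not mask.any():
            raise KeyError(f"unknown ledger component {name!r}")
        p.ledger.df.loc[mask, "amount"] *= factor
    elif kind == "effect":
        # scale the intervention-driven exposure reduction in every behaviour
        df = p.ebrb.df
        gap = df.p_control - df.p_intervention
        df["p_intervention"] = _clip_prob(df.p_control - gap * factor, name)
    else:
        raise KeyError(f"unknown parameter {name!r}")
    return p


def _clip_prob(values, name: str):
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        warnings.warn(f"{name}: perturbed probability clipped to [0, 1]", stacklevel=3)
    return np.clip(arr, 0.0, 1.0)


@dataclass
class TornadoBar:
    parameter: str
    low: float
    high: float
    base: float
    failed: bool = False

    @property
    def width(self) -> float:
        return abs(self.high - self.low)


def tornado(
    runner,
    pack: ParameterPack,
    parameters: list[str] | None = None,
    span: float = 0.30,
) -> list[TornadoBar]:
    """One-way sensitivity analysis.

    ``runner(pack) -> scalar outcome``; each parameter group is evaluated
    at (1 - span) and (1 + span) of base.  Bars are sorted by interval
    width, widest first.  A model failure at an extreme flags the bar
    instead of aborting."""
    parameters = list(TORNADO_PARAMETERS) if parameters is None else parameters
    try:
        base = runner(pack)
    except Exception:
        base = np.nan
    bars = []
    for name in parameters:
        try:
            lo = runner(scale_parameter(pack, name, 1 - span))
            hi = runner(scale_parameter(pack, name, 1 + span))
            bars.append(TornadoBar(name, lo, hi, base))
        except Exception:
            bars.append(TornadoBar(name, np.nan, np.nan, base, failed=True))
    bars.sort(key=lambda b: (-1.0 if b.failed else b.width), reverse=True)
    return bars


def tornado_to_frame(bars: list[TornadoBar]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.parameter, b.low, b.high, b.base, b.width, b.failed) for b in bars],
        columns=["parameter", "low", "high", "base", "width", "failed"],
    )


# --------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# --------------------------------------------------------------------------


@dataclass
class PSAConfig:
    """Second-order Monte Carlo settings.

    ``cv`` is the coefficient of variation (standard error / base value)
    applied to every varied parameter unless overridden per class."""

    n: int = 100
    seed: int = 0
    cv: float = 0.30
    cv_by_class: dict = field(default_factory=dict)
    thresholds: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 100_000.0, 101)
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one draw")
        if self.cv < 0:
            raise ValueError("dispersion must be non-negative")

    def class_cv(self, cls: str) -> float:
        return float(self.cv_by_class.get(cls, self.cv))


def _gamma_draw(rng, base, cv):
    """Mean-preserving gamma via method of moments (shape = 1/cv^2)."""
    base = np.asarray(base, dtype=float)
    out = base.copy()
    ok = base > 0
    if cv > 0 and ok.any():
        shape = 1.0 / cv**2
        out[ok] = rng.gamma(shape, base[ok] * cv**2)
    return out


def _beta_draw(rng, base, cv):
    """Mean-preserving beta via method of moments; infeasible moments
    (mean 0 or 1, or variance >= m(1-m)) hold the value fixed."""
    base = np.asarray(base, dtype=float)
    out = base.copy()
    if cv <= 0:
        return out
    sd = base * cv
    var = sd**2
    feas = (base > 0) & (base < 1) & (var < base * (1 - base)) & (var > 0)
    if feas.any():
        m, v = base[feas], var[feas]
        nu = m * (1 - m) / v - 1
        out[feas] = rng.beta(m * nu, (1 - m) * nu)
    if (~feas & (base != 0)).any():
        warnings.warn("beta draw infeasible for some cells; held fixed", stacklevel=3)
    return out


def _lognormal_draw(rng, base, cv):
    """Median-preserving lognormal for ratio parameters: log-space normal
    centred at ln(base) with sigma = sqrt(ln(1 + cv^2))."""
    base = np.asarray(base, dtype=float)
    out = base.copy()
    ok = base > 0
    if cv > 0 and ok.any():
        sigma = np.sqrt(np.log1p(cv**2))
        out[ok] = np.exp(np.log(base[ok]) + sigma * rng.standard_normal(ok.sum()))
    return out


def draw_parameters(pack: ParameterPack, config: PSAConfig, draw_index: int) -> ParameterPack:
    """One joint redraw of the varied parameters.

    Costs (state costs and intervention ledger) ~ gamma; incidence,
    mortality, utilities and behaviour exposure prevalences ~ beta;
    relative risks ~ lognormal.  Deterministic given (seed, draw_index)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, draw_index]))
    p = copy.deepcopy(pack)

    cv = config.class_cv("cost")
    p.costs.df["direct"] = _gamma_draw(rng, p.costs.df["direct"], cv)
    p.ledger.df["amount"] = _gamma_draw(rng, p.ledger.df["amount"], cv)

    cv = config.class_cv("probability")
    epi = p.epidemiology.df
    for col in epi.columns:
        if col.startswith(("inc_", "mort")):
            epi[col] = _beta_draw(rng, epi[col], cv)
    p.epidemiology._index = {}

    cv = config.class_cv("utility")
    p.utilities.baseline["u0"] = _beta_draw(rng, p.utilities.baseline["u0"], cv)
    for col in ("first", "followup"):
        p.utilities.decrements[col] = _beta_draw(rng, p.utilities.decrements[col], cv)
    # keep the tunnel-worse-than-followup invariant after independent draws
    dec = p.utilities.decrements
    dec["first"] = np.maximum(dec["first"], dec["followup"])

    cv = config.class_cv("rr")
    p.rr.df["rr"] = _lognormal_draw(rng, p.rr.df["rr"], cv)
    p.rr._index = {}
    for col in ("rr_overweight", "rr_obese"):
        vals = p.ebrb.df[col].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        vals[ok] = _lognormal_draw(rng, vals[ok], cv)
        p.ebrb.df[col] = vals

    cv = config.class_cv("effect")
    p.ebrb.df["p_control"] = _beta_draw(rng, p.ebrb.df["p_control"], cv)
    # redraw the exposure reduction, keeping it a reduction
    gap = np.maximum(
        0.0, _lognormal_draw(rng, (pack.ebrb.df.p_control - pack.ebrb.df.p_intervention), cv)
    )
    p.ebrb.df["p_intervention"] = np.clip(p.ebrb.df["p_control"] - gap, 0.0, 1.0)
    return p


@dataclass
class PSAResult:
    points: pd.DataFrame  # columns: draw, delta_cost, delta_qaly
    ceac: pd.DataFrame  # columns: threshold, probability
    mean_delta_cost: float
    mean_delta_qaly: float


def run_psa(runner, pack: ParameterPack, config: PSAConfig) -> PSAResult:
    """Second-order Monte Carlo: ``runner(pack) -> (delta_cost,
    delta_qaly)`` evaluated on ``config.n`` joint parameter draws.

    The CEAC reports, per willingness-to-pay threshold, the fraction of
    draws with non-negative net monetary benefit."""
    rows = []
    for k in range(config.n):
        drawn = pack if config.cv == 0 and not config.cv_by_class else draw_parameters(
            pack, config, k
        )
        dc, dq = runner(drawn)
        rows.append((k, dc, dq))
    points = pd.DataFrame(rows, columns=["draw", "delta_cost", "delta_qaly"])

    thresholds = np.asarray(config.thresholds, dtype=float)
    dc = points.delta_cost.to_numpy()
    dq = points.delta_qaly.to_numpy()
    prob = [float(np.mean(t * dq - dc >= 0.0)) for t in thresholds]
    ceac = pd.DataFrame({"threshold": thresholds, "probability": prob})
    return PSAResult(
        points=points,
        ceac=ceac,
        mean_delta_cost=float(points.delta_cost.mean()),
        mean_delta_qaly=float(points.delta_qaly.mean()),
    )


#: named scenario presets for discount-rate scenario analyses
DISCOUNT_SCENARIOS = {
    "base": (0.015, 0.03),
    "min_discount": (0.0, 0.0),
    "max_discount": (0.05, 0.05),
}


def apply_discount_scenario(pack: ParameterPack, name: str) -> ParameterPack:
    try:
        effect, cost = DISCOUNT_SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(DISCOUNT_SCENARIOS)}"
        ) from None
    p = copy.deepcopy(pack)
    p.discount.effect_rate = effect
    p.discount.cost_rate = cost
    return p
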