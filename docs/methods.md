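# Methods

This note documents the model implemented in `healthecon`, its
assumptions, parameter defaults, numerical choices and limitations. It
describes what the code computes; every number quoted here is produced
by the test suite or by `scripts/acceptance.py` at run time.

## Model structure

The engine has two stages.

1. **Decision-analytic front end** (`decision_front`). Trial effects
   are converted into one adult weight-status distribution (normal
   weight BMI < 25, overweight 25–30, obese > 30) per arm, per country,
   sex and population (child / parent). Two effect modes exist:
   * *direct BMI mode* — measured per-arm distributions, used whenever
     supplied (it has priority);
   * *EBRB-mediated mode* — relative risk reductions in energy
     balance-related behaviours are combined into overweight- and
     obesity-specific RRRs by attributable-fraction arithmetic and
     applied to the control distribution.
2. **Markov cohort model** (`markov_engine`). An 11-state,
   70-one-year-cycle deterministic cohort trace from age 30: at risk,
   diabetes, stroke / CHD / CRC / BC each with a first-year tunnel state
   and a follow-up state, and absorbing death. Only women can enter the
   breast-cancer states. Everyone starts at risk.

### Entry

Children all enter at age 30; their childhood weight distribution is
first extrapolated to adult status with a 3×3 row-stochastic tracking
matrix (excess weight persists strongly into adulthood). Parents enter
according to the six age-group proportions (<30, 30–34, …, >50): the
under-30 mass enters at 30, the over-50 mass at 50, and each five-year
group is spread evenly over its five ages. Each entry age is traced
separately and the traces are weight-averaged.

### Transition probabilities

Transitions out of *at risk* are weight-status-mixed. The population
incidence i_pop of each disease refers to the national weight
distribution, so a normal-weight baseline is calibrated as

    i_normal = i_pop / (p_n + p_ow·RR_ow + p_ob·RR_ob)

against the reference (population) distribution and re-mixed with the
arm's distribution. This guarantees that an arm with the national
distribution reproduces i_pop exactly, and that shifting mass toward
normal weight lowers every incidence (all RRs ≥ 1).

From *diabetes*, comorbidity transitions multiply the at-risk (arm-
mixed) probability by the diabetic relative risk (1.23–2.19 in the male
block; diabetic women carry a higher sex-specific stroke RR of 2.28).
Mortality: at risk = all-cause mortality × the weight-mixed mortality
RR; diabetes = all-cause mortality × 1.57 (men) / 2.00 (women); disease
states use state-specific first-year / follow-up mortality. Tunnel
survivors move to the follow-up partner with probability 1 − death.

Relative risks act multiplicatively on annual probabilities with capping
at 1. This is the spreadsheet idiom the model family uses; an optional
rate-space transform (`MarkovSettings.rate_space_rr`) applies the RR to
the instantaneous rate instead, which is better behaved at high baseline
risks. Within a row, death is claimed first; if incident transitions
would exceed the remaining mass they are scaled proportionally with a
warning. There is no half-cycle correction by default (an optional
setting exists); ages beyond 99 reuse the age-99 parameters. Once a
cohort member has left at-risk/diabetes, only that disease is tracked —
diabetes as a comorbidity is handled purely through cost add-ons.

A seeded microsimulation (`microsim_oracle`) pushes n individual
trajectories through the same matrices and serves as an independent
check of the deterministic trace: at n = 50 000, state/cycle occupancies
agree at binomial sampling accuracy (the tests allow chance-level 3-SE
exceedances over the 781 cells and require every cell within 5 SE).

### Valuation (`outcomes`)

* **Discounting**: effects at 1.50%/year, costs at 3%/year (Belgian HTA
  guideline values); factor (1+r)^−(t+L). Children carry lead time
  L = 22 years (model entry at 30 minus mean intervention age 8.2),
  because discounting starts at the intervention, not at model entry;
  parents have L = 0.
* **Utilities**: baseline at-risk utility by sex and 10-year age band
  minus a per-disease decrement (first-year ≥ follow-up). Follow-up
  decrements are relapse-adjusted: value = (1−p)·followup + p·first.
  Death contributes 0.
* **Costs** (EUR 2016, no inflation machinery): direct annual disease
  cost, age-stratified <65/≥65 (T2DM: <55/≥55); indirect cost = direct ×
  0.91 (T2DM), 0.71 (BC), 0.8 (CHD); stroke indirect = direct; CRC uses
  a configurable indirect/direct ratio (default 0.35, the
  Finnish-data-extrapolation rule). A fixed fraction of the *direct*
  T2DM cost is added to the comorbid states: 17.91% (CHD), 19.80%
  (stroke), 23.75% (BC), 38.24% (CRC) — the worked example
  2000·1.8 + 0.1791·1000 = 3779.1 EUR for a CHD first year fixes this
  interpretation. Follow-up costs are relapse-adjusted like utilities.
* **Friction costs**: a death at ages 30–64 costs
  hours-in-friction-period × hourly productivity × (1 − unemployment) ×
  elasticity. Defaults: 160-day period, working-hours content
  160 × 5/7 × 8 ≈ 914.3 h (the sources do not define the hours; this is
  the package's choice and it is configurable), elasticity 0.8 — a 10%
  labour-time reduction is applied as an 8% production loss.
* **ICER**: ΔC/ΔQ with dominance flags on the four sign quadrants and an
  undefined flag at ΔQ = 0. Results scale linearly to per-1000 targeted
  boys/girls. The all-families component carries the school-based
  intervention cost over every family; the HRF component carries the
  high-risk-family session costs over HRF families only. Intervention
  costs are charged once at cycle 0, undiscounted (no timing rule is
  specified by the sources; the two delivery years are collapsed).

### Sensitivity (`sensitivity`)

Tornado: each parameter group (state costs, utility decrements,
incidences, mortality, intervention costs, intervention effect) is run
at ±30%; bars are ranked by interval width; probabilities are clipped to
[0,1] with a warning; a failing extreme flags the bar rather than
aborting. PSA: gamma for costs (method-of-moments, mean-preserving),
beta for probabilities and utilities (method-of-moments; infeasible
moments — e.g. a zero mean, or a variance that no beta with that mean
attains, which happens for high baseline utilities at the default
dispersion — hold the cell fixed with a warning), lognormal for RR/RRR
(log-space normal centred at ln RR, median-preserving — the
conventional choice for ratio parameters). The default dispersion is a
30% coefficient of variation, mirroring the tornado span, overridable
per class. Draws are deterministic given (seed, draw index) via a
`SeedSequence`. CEAC = fraction of draws with λ·ΔQ − ΔC ≥ 0 on a
0–100 000 EUR/QALY grid. Discount-rate scenarios are exposed as presets
(0% / 5% bounds).

### Budget impact (`budget_impact`)

Undiscounted (ISPOR convention), payer perspective: only ledger items
tagged as payer costs count (family transport and time drop out).
Implementations occur in years {1, 4, 7, …} within a 1–30-year horizon.
Offsets are avoided *direct* healthcare costs in parent cohorts only —
children's benefits accrue beyond the horizon by construction — and each
re-implementation launches a fresh parent cohort whose offsets accrue
from its own year 1 and stack with earlier cohorts. The target
population is constant.

## The synthetic parameter pack

No real country input tables are distributed. `generate_synthetic_pack`
produces a fully validated pack that embeds every published constant:

* the relative-risk table (weight status → mortality/incidence; diabetic
  comorbidity and mortality RRs) with its closed-open age bands;
* the low-SES excess-weight adjustments for Belgium, Finland, Greece and
  Spain (largest RR 1.46; Finnish women's obesity RR 0.89 is the one
  protective cell); Hungary and Bulgaria count entirely as low-SES and
  carry no adjustment;
* behaviour-level RRs on overweight/obesity with the inconclusive
  behaviours excluded (children: fruits & berries, vegetables, sweets;
  adults: water, sweets);
* comorbidity cost fractions, indirect multipliers, discount rates and
  friction defaults.

Everything not printed in public sources — country incidence and
mortality curves (Gompertz-type), state costs, utilities, the tracking
matrix, cohort sizes, exposure prevalences, unemployment rates, gasoline
prices for the km-refund rule, health-expenditure ratios — is generated
at plausible 2016 magnitudes, deterministic in the seed, and flagged
`source=synthetic` in the pack metadata. Packs round-trip losslessly
through a directory of CSVs plus `manifest.yaml`, are validated
report-style (`validate_pack`), and missing country cells can be imputed
Belgium-referenced: costs scale by the health-expenditure-per-capita
ratio, epidemiology by the per-disease total incidence/mortality ratio.

Because the country tables are synthetic, passing tests demonstrate the
*mechanics* — calibration, conservation, discounting, component
attribution, distributional draws — not the cost-effectiveness of any
real programme. Headline ICERs from synthetic packs are illustrative
only. Real analyses should load a user-supplied pack with
`load_pack`, overriding any subset of cells.

## Problem sizes used in the tests

The suite runs one stratum per check (70-cycle traces are cheap); the
microsimulation check uses 50 000 individuals; conservation properties
run over 100 generator seeds; the OR→RR conversion is checked against
1000 brute-force 2×2 tables; PSA reproducibility uses small draw counts
(the per-draw cost is a full two-arm, two-sex, child+parent model run).

## Known limitations

* The at-risk all-cause mortality already contains disease deaths, so
  modelled disease mortality may double-count slightly; implemented as
  specified by the model family, not corrected.
* Diabetes-state members use the diabetic mortality RR only (not
  additionally the weight-mixed RR).
* Comorbidity beyond "diabetes as cost add-on" is not modelled; no
  diabetes complication sub-states.
* One child per family and a fixed two-parent composition are assumed in
  the per-family aggregation.
* BIA offset stacking across triennial cohorts assumes no overlap of the
  target populations.
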