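# Methods

This note records the model structure, the calibration procedure, the
parameter defaults and why they were chosen, and what the synthetic world
does and does not emulate.  Nothing here states an empirical result the
test suite or `scripts/acceptance.py` does not itself compute.

## The synthetic world

The world has seven leaf model regions — Northern, Western, Eastern,
Central, and Southern Africa, an other-developing aggregate, and a
developed aggregate — plus reporting aggregates (South of the Sahara,
Africa, Developing, World) that are strict sums of their children.  The
North-Africa-and-West-Asia grouping appears only as a costing/reporting
label.  Seven commodity groups (cereals, meats, pulses, roots & tubers,
oils, sugar, fruits & vegetables) match the price-reporting resolution of
the analysis.  Money is constant 2005 USD, quantities Mt, energy kcal.

**Base-year calibration order.**  2010 regional food demand is drawn from
dietary-energy anchors and diet-composition shares; world supply is then
set equal to world demand per commodity and allocated across regions by
production shares.  This guarantees the base year is itself an equilibrium
at base prices (clearing residual < 1e-10 by construction) — the
orientation is demand-first because the kcal anchors are the quantities
the analysis is accountable to.

Fixed 2010 anchors (not seed-jittered): Northern Africa 3000, Eastern
2150, Central 2050, Southern 2950, developed 3400 kcal/person/day; Western
Africa and other-developing are solved so the population-weighted Africa
and developing aggregates equal 2500 and 2700 exactly.  Seeded jitter
(log-normal, 3–5 %) applies to diet shares, production shares, prices,
margins, and price elasticities, so different seeds give structurally
similar but numerically distinct worlds; identical seeds give
byte-identical serialized worlds.

**What the generator does not emulate:** no sub-national production units,
no irrigated/rainfed split, no bilateral trade or stocks, no year-to-year
weather variability (paths are smooth trends), a single representative
consumer per region.  Passing tests therefore demonstrate the mechanisms
and their orderings, not forecast accuracy for real economies.

## Macro trajectories

Population and GDP follow the SSP2-style decade anchors per region;
between anchors the path is geometric interpolation (log-linear in time),
which reproduces the printed levels exactly and implies constant
within-decade growth.  Beyond 2030 the 2020–2030 rate is extrapolated.
Average income is always recomputed from summed GDP and population.  Note
that printed GDP at one decimal of a trillion is too coarse to reproduce
every printed income cell at one decimal; the package's consistency check
bounds the discrepancy by the rounding the printed GDP carries
(±0.05 trillion), which every cell satisfies.

## Climate shocks and baseline productivity

The constant-climate scenario has all shock multipliers exactly 1.  The
severe-climate scenario fixes 2030 endpoints by region: African regions at
0.93 (production-value-weighted), other-developing solved so the developing
aggregate is 0.95, developed solved so the world aggregate is 0.94 — the
two printed aggregates force the developed endpoint below the world mean
(≈0.92 at default weights).  Per-commodity dispersion (±0.03, drawn once
per seed) is recentred so the value-weighted regional mean matches the
endpoint to 1e-6.  Phase-in is linear from 1.0 in 2010 to the endpoint in
2030 — the simplest monotone path consistent with endpoint-only
information, and swappable.

Intrinsic productivity growth rates are solved so cumulative 2010–2030
multipliers hit 1.38 for Africa and 1.32 for the developing aggregate
(value-weighted; other-developing is backed out from the aggregate), with
1.25 assumed for the developed region.  Commodity-level dispersion is
recentred the same way.

## Markets

Constant-elasticity supply and demand with a single world price per
commodity; regions trade residuals frictionlessly apart from marketing
margins, split 50/50 into producer and consumer wedges (the incidence of
the wedge is not documented in the source; half-and-half is the neutral
choice and is config-exposed).  Without cross-price terms the markets
separate and each year is solved per commodity by Brent's method on the log
price — log excess supply is strictly increasing, so the root is unique;
with cross-price terms a damped Newton iteration on the log-price vector
is used (step halving on residual increase, initialization at the previous
year's prices).  Years are solved sequentially with no expectations,
matching a recursive-dynamic structure.

Elasticity defaults (the source system's values are unpublished; these are
stylized, documented ranges): supply price elasticity 0.40 (0.65 for
meats — livestock supply responds through herd size as well as yields and
is substantially more price-elastic than crops), demand price elasticity
−0.35, demand income elasticities 0.20–0.42 in African regions, 0.25–0.48
in other-developing, 0.05–0.15 in the developed region, rising from
staples to animal products (Engel-consistent).  These were chosen once so
that the no-climate-change 2030 price indices land inside the +10–30 %
anchor band and the 2030 kcal trajectories stay plausible (Africa
~2700–2800; Eastern/Central Africa low), and then frozen.  A known
consequence of the constant-elasticity form with no saturation is that
other-developing kcal availability overshoots ~3000 kcal by roughly 10 %
by 2030.

## R&D, the perpetual inventory method, and costing

Knowledge stocks follow `K_t = (1−δ)K_{t−1} + Σ w_l I_eff,t−l`.  Defaults:
δ = 0.10/yr; trapezoidal lag weights over 10 years peaking at year 5 for
CGIAR-type (more basic) research, over 6 years peaking at year 3 for
NARS-type (more applied); spillover weight 0.2 on foreign CGIAR investment
into every developing region's effective investment, none among NARS.  The
stream is padded backwards with its first-year level to feed the lag
window; the initial stock defaults to the steady state of that pre-period
level.  TFP growth is `η (K_t/K_{t−1} − 1)`.

Baseline CGIAR streams grow at 6.3 %/yr to 2030 (4.1 %/yr beyond), NARS at
2 %/yr, with 2010–2030 averages matching the printed baseline cost table.
The additional (COMP) stream per region is a geometric ramp (25 %/yr)
starting after 2015, scaled by bisection so the TFP multiplier of
(baseline + additional) over baseline reaches the region's 2030 uplift
target to 1e-6.

**Calibration of η.**  The knowledge-stock elasticities are the one free
parameter set jointly by two printed constraints: the 2030 productivity
uplift targets (Africa 1.51/(1.38·0.93) ≈ 1.177 over the climate-change
path; other-developing 1.12, stylized) and the printed average additional
CGIAR streams (0.67 bn/yr South of the Sahara, 0.01 North Africa, 0.07
other-developing).  For each region η is solved by bisection so the
inverse costing returns the printed stream; the resulting values
(≈0.3–0.6) sit in the range the returns-to-research literature reports.
Because η is calibrated to those stream totals, the costing module's
reproduction of them is a consistency check of the pipeline, not an
independent prediction — the genuine content is the inverse-consistency
property (stream → TFP → stream recovers scale to solver tolerance), which
is tested separately with uncalibrated parameters.

Capital costing: annualized cost = capex spread linearly over 2016–2030
plus a 2 %/yr maintenance fraction on the cumulatively installed cost.
Unit costs are backed out from the printed scenario cost totals and the
physical increments implied by the percent targets (assumed 2030 baseline
irrigated areas: 12 Mha South of the Sahara, 26 Mha North Africa & West
Asia, 200 Mha other-developing), yielding ≈10,500 USD per incremental
irrigated hectare in Sub-Saharan Africa — within the engineering range.
Costing is exactly linear in increments and unit costs.  Water-use
efficiency targets affect cost only; a config hook exists for a yield-side
effect but defaults to off, since the mapping from efficiency points to
yields is not documented.

## Income feedback

Regional real-income deviations from the baseline trajectory are
`κ · va_r · Δτ_r`: food value-added share times the realized
productivity deviation (supply-value-weighted shock × additional-TFP
multiplier minus one, measured against the constant-climate path).  The
market solve and the income update are iterated to a fixed point
(tolerance 1e-8 on income ratios); because productivity deviations depend
on equilibrium supply weights only weakly, the loop contracts and
converges in ~3 iterations.  κ = 0 decouples the models exactly.  κ is
calibrated once so the Africa 2030 income gain of the investment scenario
over the climate-change scenario equals +5 % (the documented anchor);
with the default value-added shares (0.10–0.35 across African regions,
GDP-weighted Africa ≈0.24) this gives κ ≈ 1.3.

## Hunger

kcal availability = Σ demand × energy density / (population × 365).  The
prevalence curve is piecewise log-linear in the ratio of kcal availability
to a 2400 kcal/day requirement, with a 2 % floor: the exact prevalence
relation of the source system is not published, so the curve is anchored
at the built world's own 2010 ratios so that Eastern Africa maps to 35 %,
Central to 41 %, and the population-weighted Africa aggregate to 21 %
(Northern and Southern Africa fixed at 5 % and 6 % by convention; Western
Africa solved from the aggregate, ≈12.5 %).  The functional form is
pluggable.  Aggregates always sum persons at risk, never average shares.
The threshold report uses the ≤5 % operational target, inclusive at the
boundary.

## Numerical conventions

- Clearing residual contract: < 1e-6 relative per commodity-year
  (typically ~1e-12 with Brent at machine tolerance).
- PIM inverse solver: bisection, relative tolerance 1e-6, bracket doubling
  capped at 2^20×.
- Fixture-sum checks: a printed marginal matches the sum of its printed
  components within half a printed unit-in-last-place per component.
- Determinism: all randomness flows from the single world seed through
  `numpy.random.default_rng`; two runs with equal seeds are bit-identical.
- Degenerate inputs (non-positive populations, prices, stocks; negative
  streams; non-monotone hunger anchors) raise typed configuration errors
  rather than propagating NaNs.

## Problem sizes

Default runs use the 7-leaf-region × 7-commodity world over 2010–2030
(annual), chosen as the smallest resolution that preserves every reported
aggregate; a three-scenario run with calibration completes in a few
seconds on one CPU, and the test suite in well under a minute.

## Known limitations

- Headline 2030 hunger *changes* are sensitive to the unpublished
  prevalence relation and to distributional detail the desk-scale model
  lacks; the package reproduces 2010 levels, orderings, and the threshold
  pattern, not head-count deltas.
- The income feedback is a one-parameter linear reduced form; it cannot
  capture sectoral reallocation, factor markets, or terms-of-trade
  effects.
- No endogenous response of NARS or private R&D to CGIAR spending; no
  probabilistic ensembles over climate models or socioeconomic pathways.
- Printed sub-regional rows of the investment-landscape table include
  residual countries only in their marginals; the loader stores the
  printed values and asserts only the identities that close.
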