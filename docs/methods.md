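# Methods

## Decision model

The planning unit is the stand (or inventory plot). A management regime is a
full trajectory of silvicultural decisions over the horizon; the simulator
output gives, for each simulated (stand, regime) pair, the value of every
indicator at every period. The decision variables are allocation shares
x[s, r] ∈ [0, 1] with one simplex row Σ_r x[s, r] = 1 per stand — the
fractional ("Model I"-style) relaxation in which part of a stand may follow
one regime and part another. A binary mode declares the same variables
integral for whole-stand assignment; it is exact but a MILP, and is off by
default because exported plans are naturally fractional ("how much of the
stand is managed according to each regime"). A (stand, regime) pair absent
from the input table means the regime was not simulated for that stand; no
variable is created for it.

Years are ordinal period labels. Spacing may be irregular (annual or 5-year
periods), and all "yearly" differences in temporal operators are taken
between consecutive available labels, never calendar-interpolated.

## Objectives

An objective is declared by key, label, indicator, sense, temporal operator,
spatial mode and an operator parameter. Spatial aggregation produces one
linear form per year:

* `sum` — Σ_s Σ_r x[s,r]·d[s,r,t]; with `per_hectare: true` each value is
  multiplied by stand area first (hectares), so per-hectare simulator outputs
  aggregate to landscape totals. Area defaults to 1.0 when the input has no
  area column, in which case per-stand values already behave as totals.
* `areaWeightedMean` — Σ area_s·d·x / Σ area_s, always area-weighted (that is
  the definition of the mean), appropriate for bounded indices such as a
  recreation index.

The twelve temporal operators are reduced to canonical maximization form with
at most one auxiliary variable and at most T (or T−N) rows each; solving for
the tightest auxiliary value reproduces the operator's direct arithmetic
definition exactly, which the test suite checks operator by operator and
property-based on random sequences. Two interpretation choices were genuinely
open and are fixed as follows:

* **sense="min"** negates the per-year forms *before* the temporal operator
  is applied. For the linear operators (average, sum, first/last/target year)
  this equals negating the finished expression, and max/min declarations are
  exact negations of each other. For the maximin-style operators the
  negate-first reading is the only LP-representable one ("minimize the
  maximum" rather than the non-concave "maximize the negated minimum"), and
  it is also the natural planning reading.
* **targetYearWithSlope** means: reach level m by the target year and sustain
  it afterwards with a relative per-period growth of `slope` —
  V(t_k) ≥ m·(1 + slope·(k − k₀)) for periods k ≥ k₀, pre-target years
  unconstrained, expression m. The slope multiplies the period-index offset,
  not the calendar-year difference, so 5-year-step data behaves like annual
  data. Default slope 0 ("reach and hold").
* **periodicTargets** measures the worst *relative* fulfilment m =
  min_t V(t)/τ_t with strictly positive targets, so heterogeneous units
  normalize away.

## Constraints

* **allowed_regimes** fixes x[s, r] = 0 (upper bound) for every regime
  outside the whitelist on stands carrying the named boolean flag. A flagged
  stand with no simulated allowed regime triggers a warning and leaves the
  infeasibility to the solver report.
* **indicator_threshold** adds V(t) ≥ α·V(t₁) for all t > t₁. Both sides are
  linear in x: the plan is compared with its *own* first-period aggregate,
  not a fixed pre-optimization constant, so the baseline moves with the
  allocation. α = 1 is "no decline allowed"; α is configurable per
  constraint.
* **ε-constraints** bound the compiled max-form objective expression from
  below. When a solve is infeasible the report lists any ε exceeding its
  payoff-table ideal as the candidate cause; no irreducible-infeasible-set
  computation is attempted (keeps the solver contract minimal).

## Payoff table and scalarization

The payoff table solves one maximization per objective over S (enabled
structural constraints included; ε-constraints and the reference point
excluded, so preference iteration never moves the normalization). Row i holds
every objective *re-evaluated by plain arithmetic* at the maximizer of
objective i — never auxiliary-variable values, which are meaningless in
solves that do not press on them. The diagonal is the ideal vector; column
minima estimate the nadir. This estimate can be optimistic for more than two
objectives; it is the standard payoff-table approximation and is accepted
here.

The preference solve maximizes α + ρ·Σ_i F_i/r_i subject to
α ≤ (F_i − z_ref,i)/r_i, ε rows, and x ∈ S, with r_i = ideal_i − nadir_i.
α is the worst normalized deviation from the reference point (Chebyshev
distance), and the augmentation term makes the optimum Pareto optimal rather
than weakly so; because every F_i appears with positive weight, it also
presses each auxiliary variable to its tight value. ρ defaults to 1e-6 and is
exposed in configuration (suitable values depend on solver tolerances; a
warning fires above 1e-3 where the aggregate term starts competing with the
Chebyshev term). Degenerate ranges |r_i| < `range_floor` (default 1e-9) are
replaced by 1 with a warning — they occur when an objective's ideal equals
its nadir, i.e. the objective is not actually in conflict with the others.
Aspiration levels outside [nadir, ideal] are clamped with a warning,
mirroring preference sliders bounded by those values; objectives without an
aspiration level default to their ideal (the most ambitious aspiration).

Reported solutions always carry objective values recomputed from the shares
and the raw table; the exporter re-derives every aggregate the same way, so
any disagreement with the solver would surface in the round-trip checks.

Relaxation monotonicity (disabling a constraint cannot worsen the optimum)
holds for a fixed scalarization; the session layer recomputes the payoff
table after a structural toggle, which changes the normalization, so the
invariant is asserted in its guaranteed form — the previously optimal plan
remains feasible and its ASF under the new normalization never beats the new
optimum.

## Solver

All LPs and MILPs go through one thin interface (build rows → solve →
extract) backed by HiGHS via `scipy.optimize.milp`. Tests compare objective
values only, never which vertex was returned: degenerate alternative optima
are solver-dependent. The allocation polytope is compact, so an "unbounded"
status is reported as a modeling bug.

## Synthetic data generator

The generator emulates the *structure* of simulator output, not silvicultural
truth: logistic stock growth toward a site-quality-scaled capacity
(r = 0.035 yr⁻¹·quality, K = 420·quality), deadwood as mortality inflow
(0.004·stock yr⁻¹) minus decay (0.02 yr⁻¹), clearcut pulses removing 95%
(rotation, cycle 60–90 yr) or 75% (extensive, 90–120 yr) of stock with the
first cut placed inside the horizon for rotation regimes, continuous cover
regimes skimming half the stock above 55% of capacity each period, and
set-aside never harvesting. The recreation index is a logistic squash of
stock, deciduous share and large trees, hence always in [0, 1]. Lognormal
multiplicative noise (sd 0.1 by default) perturbs the volume-like indicators;
~20% of stands are flagged PEAT; areas are uniform on 0.5–5 ha. Defaults
(21 five-year periods from 2016) mirror a century-long national-scale
simulation. Everything derives from one seeded `numpy` Generator, so datasets
are pure functions of the config.

What passing tests on these data do show: the compiled LPs agree with
arithmetic definitions, enumeration and grid-search oracles, and the pipeline
scales. What they do not show: realism of growth dynamics, inter-indicator
correlations of real simulators, or behavior on their CSV dialects beyond the
documented schema.

## Problem sizes and numerical choices

The enumeration-oracle studies use 20 seeded instances of 2–4 stands,
2–3 regimes and 3 periods (≤ 81 whole-stand assignments each); the scale
study uses 1,000 stands × 7 regimes × 21 periods (7,000 allocation variables,
~1,100 rows), chosen as a realistic national-sample size that a single CPU
solves in seconds. Share clipping tolerates −1e-9 numerical dust; simplex
sums are checked to 1e-6; dominance uses a 1e-9 tolerance by default (1e-6
in solver-facing checks). Exports format floats at 6 significant digits so
repeated runs are byte-identical.

## Known limitations

* The nadir estimate can be optimistic for n > 2 objectives (payoff-table
  approximation).
* No spatial adjacency/green-up constraints, no discounted economics, no
  Pareto-front sampling beyond the reference-point method.
* One CSV dialect; native readers for specific simulator formats are out of
  scope.
* The GUI of interactive planning tools is replaced by a line-oriented
  `interactive` CLI subcommand plus re-runnable declarative configs.
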