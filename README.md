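# forestopt

Multi-objective forest management planning from simulator outputs.

Forest growth simulators project, for every stand in a landscape and every
candidate management regime (rotation forestry, continuous cover forestry,
set-aside, ...), the time path of indicators such as harvested volume,
standing biomass, deadwood, and recreation value. The planning question is
which regime — or fractional mix of regimes — to assign to each stand so that
the landscape balances conflicting goals: timber even-flow, biodiversity,
recreation. `forestopt` compiles those simulator tables plus a declarative
scenario description into linear programs and returns Pareto optimal
management portfolios, i.e. plans in which no objective can be improved
without worsening another.

## The optimization model

Decision variables are allocation shares x[s, r] ∈ [0, 1] with
Σ_r x[s, r] = 1 for every stand s (optionally binary for whole-stand
assignment). Each objective i is declared by six attributes — key, label,
indicator column, sense (max/min), a temporal operator, and a spatial
aggregation mode — and compiles to a linear expression F_i(x) over the yearly
landscape aggregates V_i(t) = Σ_s Σ_r x[s,r]·d[s,r,t]. Twelve temporal
operators are supported (minimum over the horizon, average, sum, first/last/
target year, target year with sustained growth, periodic targets, and four
smooth-flow operators on period-to-period changes).

Preferences enter in two ways:

* **ε-constraints** — hard floors `F_i(x) ≥ ε_i`;
* **a reference point** z_ref of aspiration levels, one per objective.

A payoff table (one single-objective maximization per objective) provides the
ideal vector z\* (diagonal) and a nadir estimate z^nad (column minima). The
solved problem is the augmented Chebyshev achievement scalarizing function in
canonical maximization form:

```
max  α + ρ · Σ_i F_i(x) / r_i
s.t. α ≤ (F_i(x) − z_ref,i) / r_i    for every objective i
     F_i(x) ≥ ε_i                    for ε-constrained objectives
     x ∈ S                           (simplex + structural constraints)
```

with ranges r_i = z\*_i − z^nad_i and a small augmentation weight ρ (default
1e-6) that guarantees Pareto optimality of the optimum. Structural
constraints cover regime whitelists on flagged stands (e.g. only continuous
cover or set-aside on peatland) and no-decline rules
`V(t) ≥ α·V(t_first)` whose baseline moves with the plan. LPs/MILPs are
solved with HiGHS via SciPy.

## Worked example

Generate a synthetic 25-stand landscape (the bundled generator emulates
simulator output: harvest pulses under rotation regimes, monotone deadwood
accumulation under set-aside) and solve a three-objective scenario:

```
$ forestopt synth --stands 25 --seed 7 --out forest.csv
wrote 2100 rows to forest.csv
```

with `scenario.yaml`:

```yaml
data:
  path: forest.csv
objectives:
  - {key: even_harvest,  indicator: harvested_volume, temporal: min}
  - {key: deadwood_2116, indicator: deadwood_volume,  temporal: lastYear}
  - {key: recreation,    indicator: recreation_index, temporal: average,
     spatial: areaWeightedMean}
constraints:
  - {key: ccf_on_peat, kind: allowed_regimes, allowed: [CCF_1, SA], flag: PEAT,
     enabled: true}
  - {key: deadwood_no_decline, kind: indicator_threshold,
     indicator: deadwood_volume, alpha: 1.0, enabled: true}
epsilon:
  even_harvest: 5.0
output: out
```

```
$ forestopt payoff --config scenario.yaml
               even_harvest  deadwood_2116  recreation
even_harvest        140.438        952.983    0.398928
deadwood_2116             0        1457.57    0.807888
recreation                0        1442.47    0.821116
ideal: even_harvest=140.438, deadwood_2116=1457.57, recreation=0.821116
nadir: even_harvest=0, deadwood_2116=952.983, recreation=0.398928

$ forestopt solve --config scenario.yaml
status: optimal
  even_harvest: 83.9785 (achievement 0.598)
  deadwood_2116: 1254.71 (achievement 0.598)
  recreation: 0.651386 (achievement 0.598)
exports written to out
```

Row i of the payoff table shows all objective values at the plan maximizing
objective i: maximizing even-flow harvest alone would sustain 140.4 units per
period but depress deadwood to its nadir, while the deadwood- or
recreation-optimal plans harvest nothing in at least one period. With the
reference point left at the ideal vector, the scalarization equalizes the
normalized achievements (0.598 for all three objectives here — each objective
reaches 59.8% of the way from its nadir to its ideal), and the exported
`out/stand_solution.csv` lists the per-stand regime shares:

```
stand,regime,share
S0001,EXT,0.777574
S0001,SA,0.222426
S0002,SA,1
S0003,CCF_1,1
```

Iterate interactively (`forestopt interactive --config scenario.yaml`) by
moving aspiration levels, adding ε floors, or toggling constraints; the payoff
table is cached across preference changes and recomputed when structural
constraints change.

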