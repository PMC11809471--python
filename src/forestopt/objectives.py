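"""Objective declarations and their linear-program realizations.

An objective is declared by six attributes mirroring the simulator-tool
convention: a unique key, a human-readable label, the indicator column, the
optimization sense (``max``/``min``), a temporal aggregation operator, and a
spatial aggregation mode (plus an operator-specific parameter where needed).

Spatial aggregation first turns the per-(stand, regime, year) indicator values
into one linear form per year over the allocation variables,
``V(t) = Σ_s Σ_r x[s,r] · d[s,r,t]`` (optionally area-weighted).  The temporal
operator then collapses the per-year forms into a single linear expression,
introducing at most one auxiliary variable and T-ish constraints for the
maximin-style operators.

Temporal operators (canonical maximization form; V(t) is the year-t form):

========================== ====================================================
min                        maximize the minimum value over the horizon
average                    maximize the mean value over the horizon
firstYear / lastYear       maximize the value of the first / last year
sum                        maximize the sum over the horizon
targetYear                 maximize the value at a given year
targetYearWithSlope        reach a level by the target year and sustain or
                           linearly grow it afterwards (slope per period)
periodicTargets            maximize the worst relative fulfilment V(t)/τ_t of
                           positive per-year targets
minYearlyIncrease          minimize the largest consecutive-period increase
maxYearlyIncrease          maximize the smallest consecutive-period increase
minDecreaseDuringNPeriods  minimize the largest decrease over any N periods
maxIncreaseDuringNPeriods  maximize the smallest increase over any N periods
========================== ====================================================

"Yearly" always means consecutive data periods, whatever their calendar
spacing.  A ``sense="min"`` declaration negates the yearly forms before the
operator is applied, which keeps every operator linear (so ``min`` under
``sense="min"`` reads "minimize the maximum value").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .data import IndicatorTable, StandInfo
from .lp import LinearForm, ProblemModel, Row

TEMPORAL_OPERATORS = (
    "min", "average", "firstYear", "sum", "targetYear", "targetYearWithSlope",
    "lastYear", "periodicTargets", "minYearlyIncrease", "maxYearlyIncrease",
    "minDecreaseDuringNPeriods", "maxIncreaseDuringNPeriods",
)

_NEEDS_YEAR = {"targetYear", "targetYearWithSlope"}
_NEEDS_WINDOW = {"minDecreaseDuringNPeriods", "maxIncreaseDuringNPeriods"}


class ObjectiveSpec(BaseModel):
    """Declarative objective: the six-attribute description of one criterion."""

    key: str
    label: str = ""
    indicator: str
    sense: Literal["max", "min"] = "max"
    temporal: Literal[TEMPORAL_OPERATORS]  # type: ignore[valid-type]
    spatial: Literal["sum", "areaWeightedMean"] = "sum"
    param: int | dict[int, float] | None = None
    slope: float = Field(0.0, ge=0.0)

    @model_validator(mode="after")
    def _check_param(self) -> "ObjectiveSpec":
        t = self.temporal
        if t in _NEEDS_YEAR or t in _NEEDS_WINDOW:
            if not isinstance(self.param, int):
                raise ValueError(f"temporal operator {t!r} requires an integer param")
        elif t == "periodicTargets":
            if not isinstance(self.param, dict) or not self.param:
                raise ValueError("periodicTargets requires a {year: target} map")
        elif self.param is not None:
            raise ValueError(f"temporal operator {t!r} takes no param")
        return self


@dataclass
class CompiledObjective:
    """Linear realization of an ObjectiveSpec over a problem model.

    ``expression`` is always in canonical maximization form.  ``yearly_forms``
    keeps the raw (sense-unadjusted) per-year aggregates so solutions can be
    re-evaluated by plain arithmetic, independently of the solver.
    """

    key: str
    spec: ObjectiveSpec
    expression: LinearForm
    yearly_forms: dict[int, LinearForm]
    aux_variable: int | None = None
    aux_rows: list[Row] = field(default_factory=list)
    canonical_sense: str = "max"


def aggregate_per_year(table: IndicatorTable, indicator: str, spatial: str,
                       variables: Mapping[tuple[str, str], int],
                       stands: list[StandInfo] | None = None,
                       per_hectare: bool = False) -> dict[int, LinearForm]:
    """One linear form per year: the landscape aggregate of an indicator.

    ``spatial="sum"`` gives ``Σ_s Σ_r x[s,r]·d[s,r,t]`` (each value weighted by
    stand area when ``per_hectare`` is set); ``"areaWeightedMean"`` gives the
    area-weighted mean ``Σ area_s·d[s,r,t]·x[s,r] / Σ area_s``.
    """
    if spatial not in ("sum", "areaWeightedMean"):
        raise ValueError(f"unknown spatial mode {spatial!r}")
    pairs, values = table.wide(indicator)
    areas = {s.stand_id: s.area for s in stands} if stands else {}
    missing = set(variables) - set(pairs)
    if missing:
        raise ValueError(f"variables declared for unsimulated pairs: {sorted(missing)[:3]}")

    weigh_by_area = spatial == "areaWeightedMean" or per_hectare
    total_area = None
    if spatial == "areaWeightedMean":
        var_stands = {s for s, _ in variables}
        if not var_stands:
            raise ValueError("no allocation variables: every stand needs a regime")
        total_area = sum(areas.get(s, 1.0) for s in var_stands)

    forms: dict[int, LinearForm] = {t: LinearForm() for t in table.years}
    for p, (stand, regime) in enumerate(pairs):
        idx = variables.get((stand, regime))
        if idx is None:
            continue  # pair simulated but no variable (e.g. stand filtered out)
        w = areas.get(stand, 1.0) if weigh_by_area else 1.0
        if total_area is not None:
            w /= total_area
        for k, year in enumerate(table.years):
            forms[year].add_term(idx, w * values[p, k])
    return forms


def _pick_years(yearly_forms: Mapping[int, LinearForm]) -> list[int]:
    if not yearly_forms:
        raise ValueError("yearly_forms is empty")
    return sorted(yearly_forms)


def compile_objective(spec: ObjectiveSpec, yearly_forms: Mapping[int, LinearForm],
                      model: ProblemModel) -> CompiledObjective:
    """Realize one objective as a linear expression (+ auxiliaries) on the model.

    The auxiliary rows never restrict the allocation variables on their own
    (the auxiliary is free), so they are safe to keep attached to the model
    across solves; the augmentation/objective pressure makes them tight.
    """
    years = _pick_years(yearly_forms)
    sign = -1.0 if spec.sense == "min" else 1.0
    V = [sign * yearly_forms[t] for t in years]
    T = len(years)
    aux_rows: list[Row] = []
    aux_var: int | None = None

    def new_aux() -> tuple[int, LinearForm]:
        idx = model.ensure_variable(f"_obj[{spec.key}]")
        return idx, LinearForm({idx: 1.0})

    t = spec.temporal
    if t == "min":
        aux_var, m = new_aux()
        aux_rows = [Row(V[k] - m, 0.0, np.inf, f"{spec.key}:min@{years[k]}")
                    for k in range(T)]
        expression = m
    elif t == "average":
        expression = LinearForm()
        for f in V:
            expression = expression + f
        expression = expression * (1.0 / T)
    elif t == "sum":
        expression = LinearForm()
        for f in V:
            expression = expression + f
    elif t in ("firstYear", "lastYear", "targetYear"):
        if t == "targetYear":
            if spec.param not in yearly_forms:
                raise ValueError(f"target year {spec.param} not in years {years}")
            expression = V[years.index(spec.param)].copy()
        else:
            expression = V[0 if t == "firstYear" else -1].copy()
    elif t == "targetYearWithSlope":
        if spec.param not in yearly_forms:
            raise ValueError(f"target year {spec.param} not in years {years}")
        k0 = years.index(spec.param)
        aux_var, m = new_aux()
        for k in range(k0, T):
            factor = 1.0 + spec.slope * (k - k0)  # per-period relative growth
            aux_rows.append(Row(V[k] - factor * m, 0.0, np.inf,
                                f"{spec.key}:slope@{years[k]}"))
        expression = m
    elif t == "periodicTargets":
        targets = spec.param
        missing = [y for y in years if y not in targets]
        if missing:
            raise ValueError(f"periodicTargets missing targets for years {missing}")
        if any(targets[y] <= 0 for y in years):
            raise ValueError("periodicTargets requires strictly positive targets")
        aux_var, m = new_aux()
        aux_rows = [Row(V[k] - targets[years[k]] * m, 0.0, np.inf,
                        f"{spec.key}:target@{years[k]}") for k in range(T)]
        expression = m
    elif t in ("maxYearlyIncrease", "minYearlyIncrease",
               "maxIncreaseDuringNPeriods", "minDecreaseDuringNPeriods"):
        N = 1 if t.endswith("YearlyIncrease") else int(spec.param)
        if N < 1 or N >= T:
            raise ValueError(f"window N={N} must be in [1, {T - 1}] for {T} periods")
        aux_var, m = new_aux()
        if t in ("maxYearlyIncrease", "maxIncreaseDuringNPeriods"):
            # m ≤ V(t_{k+N}) − V(t_k): maximize the smallest windowed increase
            aux_rows = [Row(V[k + N] - V[k] - m, 0.0, np.inf,
                            f"{spec.key}:inc@{years[k]}") for k in range(T - N)]
            expression = m
        else:
            # m ≥ windowed increase (resp. decrease): minimize the largest one
            diff = (lambda k: V[k + N] - V[k]) if t == "minYearlyIncrease" \
                else (lambda k: V[k] - V[k + N])
            aux_rows = [Row(m - diff(k), 0.0, np.inf,
                            f"{spec.key}:dec@{years[k]}") for k in range(T - N)]
            expression = -m
    else:  # pragma: no cover - pydantic blocks unknown names
        raise ValueError(f"unknown temporal operator {t!r}")

    model.rows.extend(aux_rows)
    return CompiledObjective(spec.key, spec, expression,
                             {y: yearly_forms[y].copy() for y in years},
                             aux_var, aux_rows)


def evaluate_temporal(spec: ObjectiveSpec, yearly_values: Mapping[int, float]) -> float:
    """Direct-arithmetic value of an objective given per-year aggregates.

    This is the solver-independent definition of every temporal operator; the
    compiled LP realization must agree with it at any fixed allocation.
    """
    years = sorted(yearly_values)
    sign = -1.0 if spec.sense == "min" else 1.0
    v = np.array([sign * yearly_values[t] for t in years], dtype=float)
    T = len(v)
    t = spec.temporal
    if t == "min":
        return float(v.min())
    if t == "average":
        return float(v.mean())
    if t == "sum":
        return float(v.sum())
    if t == "firstYear":
        return float(v[0])
    if t == "lastYear":
        return float(v[-1])
    if t == "targetYear":
        return float(v[years.index(spec.param)])
    if t == "targetYearWithSlope":
        k0 = years.index(spec.param)
        factors = np.array([1.0 + spec.slope * (k - k0) for k in range(k0, T)])
        return float((v[k0:] / factors).min())
    if t == "periodicTargets":
        taus = np.array([spec.param[y] for y in years], dtype=float)
        return float((v / taus).min())
    diffs = {"maxYearlyIncrease": 1, "minYearlyIncrease": 1,
             "maxIncreaseDuringNPeriods": spec.param,
             "minDecreaseDuringNPeriods": spec.param}[t]
    window = np.asarray(v[diffs:]) - np.asarray(v[:-diffs])
    if t == "maxYearlyIncrease" or t == "maxIncreaseDuringNPeriods":
        return float(window.min())
    if t == "minYearlyIncrease":
        return float(-window.max())
    return float(-(-window).max())  # minDecreaseDuringNPeriods


def evaluate_objective(obj: CompiledObjective, x: np.ndarray) -> float:
    """Re-evaluate a compiled objective at a solution vector by plain arithmetic."""
    yearly = {t: f.evaluate(x) for t, f in obj.yearly_forms.items()}
    return evaluate_temporal(obj.spec, yearly)
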