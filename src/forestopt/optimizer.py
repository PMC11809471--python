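"""Payoff-table estimation and the augmented Chebyshev scalarization solve.

The decision model assigns each stand a mix of management regimes: continuous
shares x[s, r] ∈ [0, 1] with Σ_r x[s, r] = 1 per stand (the classic
harvest-scheduling "Model I" relaxation), or whole-stand binary assignment in
the optional MILP mode.

Workflow for one preference iteration:

1. :func:`compute_payoff` — solve one single-objective maximization per
   objective; row i of the payoff matrix holds every objective re-evaluated at
   the maximizer of objective i.  The diagonal is the ideal vector z*, the
   column minima estimate the nadir z^nad (a standard approximation that can
   be optimistic for n > 2 objectives).
2. :func:`solve_scalarized` — maximize the achievement scalarizing function

       α + ρ · Σ_i F_i(x) / r_i      s.t.  α ≤ (F_i(x) − z_ref,i) / r_i ∀i,
                                            F_i(x) ≥ ε_i (ε-constraints), x ∈ S

   with ranges r_i = z*_i − z^nad_i.  The Chebyshev scalar α measures the worst
   normalized deviation from the user's reference point; the small augmentation
   term (ρ, default 1e-6) guarantees the optimum is Pareto optimal rather than
   merely weakly so.

All reported objective values come from plain-arithmetic re-evaluation of the
allocation, never from auxiliary solver variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .constraints import ConstraintSpec, compile_allowed_regimes, compile_threshold, \
    compile_epsilon
from .data import IndicatorTable, StandInfo
from .lp import LinearForm, ProblemModel, Row, SolveResult, solve
from .objectives import CompiledObjective, ObjectiveSpec, aggregate_per_year, \
    compile_objective, evaluate_objective


class ScalarizationParams(BaseModel):
    """Augmentation weight ρ and the floor protecting degenerate ranges."""

    rho: float = Field(1e-6, gt=0.0)
    range_floor: float = Field(1e-9, gt=0.0)

    def model_post_init(self, _ctx) -> None:
        if self.rho > 1e-3:
            warnings.warn(f"augmentation coefficient rho={self.rho} is large; "
                          "the solve may trade Chebyshev balance for aggregate gain")


@dataclass
class PayoffTable:
    """n×n cross-objective values; diagonal = ideal, column minima = nadir."""

    keys: list[str]
    matrix: np.ndarray
    ideal: np.ndarray
    nadir: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.keys, columns=self.keys)

    def range(self, floor: float = 1e-9) -> np.ndarray:
        r = self.ideal - self.nadir
        out = r.copy()
        degenerate = np.abs(r) < floor
        if degenerate.any():
            warnings.warn(
                "objective range(s) below floor for "
                f"{[self.keys[i] for i in np.flatnonzero(degenerate)]}; using 1.0")
            out[degenerate] = 1.0
        return out


@dataclass
class AllocationSolution:
    """Solved management portfolio with solver-independent re-evaluations."""

    status: str
    shares: dict[tuple[str, str], float] = field(default_factory=dict)
    objective_values: dict[str, float] = field(default_factory=dict)
    achievements: dict[str, float] = field(default_factory=dict)
    alpha: float | None = None
    scalar_value: float | None = None
    diagnosis: str = ""
    x: np.ndarray | None = None


def check_dominance(candidate: Sequence[float], others: Sequence[Sequence[float]],
                    tol: float = 1e-9) -> bool:
    """True iff some other vector Pareto-dominates ``candidate`` (max form)."""
    cand = np.asarray(candidate, dtype=float)
    for other in others:
        o = np.asarray(other, dtype=float)
        if o.shape != cand.shape:
            raise ValueError("objective vectors must have equal length")
        if np.all(o >= cand - tol) and np.any(o > cand + tol):
            return True
    return False


def build_base_model(table: IndicatorTable, stands: Sequence[StandInfo],
                     binary: bool = False) -> ProblemModel:
    """Allocation variables for every simulated (stand, regime) pair plus the
    per-stand simplex rows Σ_r x[s, r] = 1."""
    model = ProblemModel()
    by_stand: dict[str, list[int]] = {}
    for stand, regime in table.pairs():
        idx = model.add_alloc_variable(stand, regime, integer=binary)
        by_stand.setdefault(stand, []).append(idx)
    known = {s.stand_id for s in stands}
    for stand in sorted(table.stands):
        if stand not in known:
            raise ValueError(f"stand {stand!r} has no metadata entry")
        idxs = by_stand.get(stand)
        if not idxs:
            raise ValueError(f"stand {stand!r} has no simulated regime")
        model.add_row(LinearForm({i: 1.0 for i in idxs}), 1.0, 1.0,
                      f"simplex[{stand}]")
    return model


def compile_problem(table: IndicatorTable, stands: Sequence[StandInfo],
                    objective_specs: Sequence[ObjectiveSpec],
                    constraint_specs: Sequence[ConstraintSpec] = (),
                    per_hectare: bool = False,
                    binary: bool = False) -> tuple[ProblemModel, list[CompiledObjective]]:
    """Assemble the full model: base + enabled structural constraints + objectives."""
    if not objective_specs:
        raise ValueError("at least one objective is required")
    keys = [o.key for o in objective_specs]
    if len(set(keys)) != len(keys):
        raise ValueError("objective keys must be unique")
    model = build_base_model(table, stands, binary=binary)

    def forms_for(indicator: str, spatial: str) -> dict[int, LinearForm]:
        return aggregate_per_year(table, indicator, spatial, model.alloc,
                                  list(stands), per_hectare)

    for cspec in constraint_specs:
        if not cspec.enabled:
            continue
        if cspec.kind == "allowed_regimes":
            compile_allowed_regimes(cspec, list(stands), model)
        else:
            rows = compile_threshold(cspec, forms_for(cspec.indicator, cspec.spatial))
            model.rows.extend(rows)

    compiled = [compile_objective(spec, forms_for(spec.indicator, spec.spatial), model)
                for spec in objective_specs]
    return model, compiled


def compute_payoff(model: ProblemModel, objectives: Sequence[CompiledObjective]) -> PayoffTable:
    """Solve one maximization per objective over S (enabled structural
    constraints included, preferences excluded) and tabulate cross values."""
    if not objectives:
        raise ValueError("need at least one objective")
    n = len(objectives)
    matrix = np.zeros((n, n))
    for i, obj in enumerate(objectives):
        res = solve(model, obj.expression, maximize=True)
        if res.status != "optimal":
            raise RuntimeError(
                f"payoff solve for objective {obj.key!r} ended {res.status}: "
                f"{res.message}")
        matrix[i] = [evaluate_objective(o, res.x) for o in objectives]
    ideal = matrix.diagonal().copy()
    nadir = matrix.min(axis=0)
    return PayoffTable([o.key for o in objectives], matrix, ideal, nadir)


def _clamped_reference(ref: Mapping[str, float], payoff: PayoffTable,
                       keys: list[str]) -> np.ndarray:
    z = np.empty(len(keys))
    clamped = []
    for i, key in enumerate(keys):
        want = float(ref.get(key, payoff.ideal[i]))  # missing aspiration -> aim at ideal
        lo, hi = payoff.nadir[i], payoff.ideal[i]
        z[i] = min(max(want, lo), hi)
        if z[i] != want:
            clamped.append(key)
    if clamped:
        warnings.warn(f"reference point clamped into [nadir, ideal] for {clamped}")
    return z


def solve_scalarized(model: ProblemModel, objectives: Sequence[CompiledObjective],
                     payoff: PayoffTable, ref: Mapping[str, float],
                     eps: Mapping[str, float] | None = None,
                     params: ScalarizationParams | None = None) -> AllocationSolution:
    """Maximize the augmented achievement scalarizing function under ε-rows."""
    params = params or ScalarizationParams()
    eps = eps or {}
    keys = [o.key for o in objectives]
    if payoff.keys != keys:
        raise ValueError("payoff table computed for a different objective set")
    ranges = payoff.range(params.range_floor)
    z_ref = _clamped_reference(ref, payoff, keys)

    a_idx = model.ensure_variable("_asf_alpha")
    alpha = LinearForm({a_idx: 1.0})
    extra: list[Row] = []
    scalar_obj = alpha.copy()
    for i, obj in enumerate(objectives):
        # α ≤ (F_i − z_ref,i)/r_i  ⇔  F_i − r_i·α ≥ z_ref,i
        extra.append(Row(obj.expression - ranges[i] * alpha, z_ref[i], np.inf,
                         f"asf[{obj.key}]"))
        scalar_obj = scalar_obj + (params.rho / ranges[i]) * obj.expression
    extra.extend(compile_epsilon(eps, objectives))

    res = solve(model, scalar_obj, maximize=True, extra_rows=extra)
    if res.status != "optimal":
        diagnosis = _diagnose(res, eps, payoff, keys)
        return AllocationSolution(status=res.status, diagnosis=diagnosis)

    values = {o.key: evaluate_objective(o, res.x) for o in objectives}
    fvec = np.array([values[k] for k in keys])
    achievements = {k: float((fvec[i] - payoff.nadir[i]) / ranges[i])
                    for i, k in enumerate(keys)}
    # Recompute the ASF value from the re-evaluated objectives, not solver aux.
    scalar_value = float(((fvec - z_ref) / ranges).min()
                         + params.rho * (fvec / ranges).sum())
    return AllocationSolution(
        status="optimal",
        shares=model.shares(res.x),
        objective_values=values,
        achievements=achievements,
        alpha=float(res.x[a_idx]),
        scalar_value=scalar_value,
        x=res.x,
    )


def _diagnose(res: SolveResult, eps: Mapping[str, float], payoff: PayoffTable,
              keys: list[str]) -> str:
    if res.status == "unbounded":
        return ("model unbounded although the allocation set is compact — "
                "this indicates a modeling bug")
    suspects = [k for k in eps
                if k in keys and eps[k] > payoff.ideal[keys.index(k)] + 1e-9]
    msg = f"solver status: {res.status}"
    if suspects:
        msg += ("; candidate cause: ε-constraint(s) above the payoff ideal for "
                + ", ".join(repr(k) for k in suspects))
    return msg


def asf_value(objective_vector: Sequence[float], z_ref: Sequence[float],
              ranges: Sequence[float], rho: float) -> float:
    """Augmented achievement value of a fixed objective vector (max form)."""
    f = np.asarray(objective_vector, dtype=float)
    zr = np.asarray(z_ref, dtype=float)
    r = np.asarray(ranges, dtype=float)
    return float(((f - zr) / r).min() + rho * (f / r).sum())
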