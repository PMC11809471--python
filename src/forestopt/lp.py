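"""Sparse linear expressions, the allocation model, and the HiGHS solver wrapper.

Every optimization problem in this package is a linear (or mixed-binary) program
over fractional stand-to-regime allocation variables ``x[s, r]`` plus a handful
of auxiliary scalars introduced by maximin-style objectives and by the Chebyshev
scalarization.  This module provides the three pieces everything else builds on:

* :class:`LinearForm` — an immutable-ish sparse linear expression
  ``sum(c_j * v_j) + const`` over variable indices;
* :class:`ProblemModel` — variable registry (bounds, integrality) plus the
  persistent constraint rows (per-stand allocation simplex, structural
  constraints, objective auxiliaries);
* :func:`solve` — one call into :func:`scipy.optimize.milp` (HiGHS), used both
  for pure LPs and for the optional whole-stand binary mode.

Solver contract: callers only ever consume objective values and variable
values; degenerate alternative optima are solver-dependent and never asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp


class LinearForm:
    """Sparse linear expression over model variables: ``Σ c_j·x_j + const``."""

    __slots__ = ("coeffs", "const")

    def __init__(self, coeffs: dict[int, float] | None = None, const: float = 0.0):
        self.coeffs: dict[int, float] = dict(coeffs) if coeffs else {}
        self.const = float(const)

    def copy(self) -> "LinearForm":
        return LinearForm(self.coeffs, self.const)

    def add_term(self, idx: int, coef: float) -> None:
        if coef == 0.0:
            return
        new = self.coeffs.get(idx, 0.0) + coef
        if new == 0.0:
            self.coeffs.pop(idx, None)
        else:
            self.coeffs[idx] = new

    def __add__(self, other: "LinearForm | float") -> "LinearForm":
        out = self.copy()
        if isinstance(other, LinearForm):
            for j, c in other.coeffs.items():
                out.add_term(j, c)
            out.const += other.const
        else:
            out.const += float(other)
        return out

    def __sub__(self, other: "LinearForm | float") -> "LinearForm":
        return self + (other * -1.0 if isinstance(other, LinearForm) else -float(other))

    def __mul__(self, scalar: float) -> "LinearForm":
        s = float(scalar)
        return LinearForm({j: c * s for j, c in self.coeffs.items()}, self.const * s)

    __rmul__ = __mul__

    def __neg__(self) -> "LinearForm":
        return self * -1.0

    def evaluate(self, x: np.ndarray) -> float:
        """Plain-arithmetic value of the form at a variable vector."""
        return self.const + sum(c * x[j] for j, c in self.coeffs.items())

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        terms = " + ".join(f"{c:g}·v{j}" for j, c in sorted(self.coeffs.items()))
        return f"LinearForm({terms or '0'} + {self.const:g})"


@dataclass
class Row:
    """Two-sided linear constraint ``lb ≤ form ≤ ub`` (constants folded at solve)."""

    form: LinearForm
    lb: float
    ub: float
    name: str = ""


@dataclass
class SolveResult:
    status: str  # "optimal" | "infeasible" | "unbounded" | "error"
    x: np.ndarray | None
    objective: float | None
    message: str = ""


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


class ProblemModel:
    """Variable registry + persistent rows of the allocation problem.

    Allocation variables live in ``alloc`` keyed by ``(stand, regime)``;
    auxiliary variables (objective auxiliaries, the scalarization scalar) are
    registered by name and reused on repeated solves.
    """

    def __init__(self) -> None:
        self.names: list[str] = []
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.integer: list[bool] = []
        self.rows: list[Row] = []
        self.alloc: dict[tuple[str, str], int] = {}
        self._by_name: dict[str, int] = {}

    @property
    def n_variables(self) -> int:
        return len(self.names)

    def add_variable(self, name: str, lb: float = 0.0, ub: float = 1.0,
                     integer: bool = False) -> int:
        if name in self._by_name:
            raise ValueError(f"variable {name!r} already declared")
        idx = len(self.names)
        self.names.append(name)
        self.lb.append(float(lb))
        self.ub.append(float(ub))
        self.integer.append(bool(integer))
        self._by_name[name] = idx
        return idx

    def ensure_variable(self, name: str, lb: float = -np.inf, ub: float = np.inf) -> int:
        """Get-or-create a named auxiliary variable (bounds reset on reuse)."""
        if name in self._by_name:
            idx = self._by_name[name]
            self.lb[idx] = float(lb)
            self.ub[idx] = float(ub)
            return idx
        return self.add_variable(name, lb, ub)

    def add_alloc_variable(self, stand: str, regime: str, integer: bool = False) -> int:
        idx = self.add_variable(f"x[{stand},{regime}]", 0.0, 1.0, integer)
        self.alloc[(stand, regime)] = idx
        return idx

    def fix_to_zero(self, stand: str, regime: str) -> None:
        self.ub[self.alloc[(stand, regime)]] = 0.0

    def add_row(self, form: LinearForm, lb: float, ub: float, name: str = "") -> Row:
        row = Row(form, float(lb), float(ub), name)
        self.rows.append(row)
        return row

    def shares(self, x: np.ndarray, clip_tol: float = 1e-9) -> dict[tuple[str, str], float]:
        """Allocation values at a solution, with sub-tolerance negatives clipped."""
        out = {}
        for key, idx in self.alloc.items():
            v = float(x[idx])
            if -clip_tol < v < 0.0:
                v = 0.0
            out[key] = v
        return out


def _assemble(rows: list[Row], n: int):
    data, ri, ci, lbs, ubs = [], [], [], [], []
    for k, row in enumerate(rows):
        for j, c in row.form.coeffs.items():
            data.append(c)
            ri.append(k)
            ci.append(j)
        lbs.append(row.lb - row.form.const)
        ubs.append(row.ub - row.form.const)
    A = sparse.csr_array((data, (ri, ci)), shape=(len(rows), n))
    return LinearConstraint(A, np.array(lbs), np.array(ubs))


def solve(model: ProblemModel, objective: LinearForm, maximize: bool = True,
          extra_rows: list[Row] | None = None) -> SolveResult:
    """Optimize a linear form over the model's rows and bounds via HiGHS.

    The model's persistent rows are always included; ``extra_rows`` carry
    per-solve preference constraints (ε rows, scalarization rows) so the base
    model never needs rebuilding between preference iterations.
    """
    n = model.n_variables
    c = np.zeros(n)
    for j, coef in objective.coeffs.items():
        c[j] = coef
    sign = -1.0 if maximize else 1.0

    rows = model.rows + list(extra_rows or [])
    constraints = [_assemble(rows, n)] if rows else []
    res = milp(
        sign * c,
        constraints=constraints,
        bounds=Bounds(np.array(model.lb), np.array(model.ub)),
        integrality=np.array(model.integer, dtype=int),
        options={"mip_rel_gap": 0.0},  # exact branch-and-bound optima
    )
    status = _STATUS.get(res.status, "error")
    if status != "optimal" or res.x is None:
        return SolveResult(status if status != "optimal" else "error", None, None,
                           message=str(res.message))
    value = float(c @ res.x) + objective.const
    return SolveResult("optimal", np.asarray(res.x), value, message=str(res.message))
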