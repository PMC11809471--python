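"""Structural and ε-constraints compiled into linear rows.

Two structural constraint families cover the common planning restrictions:

* ``allowed_regimes`` — on stands carrying a boolean site flag (e.g. drained
  peatland, ``PEAT``), only a whitelist of regimes may be assigned; realized
  by fixing the disallowed allocation variables to zero.
* ``indicator_threshold`` — a landscape aggregate may never fall below a
  fraction α of its own first-period value under the chosen plan
  (``V(t) ≥ α·V(t₁)`` for all later years); α = 1 is a "no decline" rule.
  Both sides are linear in the allocation, so the baseline moves with the plan.

ε-constraints turn an objective into a hard floor: the compiled (canonical
max-form) objective expression must reach at least ε.
"""

from __future__ import annotations

import warnings
from typing import Literal, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .data import IndicatorTable, StandInfo
from .lp import LinearForm, ProblemModel, Row
from .objectives import CompiledObjective


class ConstraintSpec(BaseModel):
    """Declarative structural constraint mirroring the 4-element list convention."""

    key: str
    kind: Literal["allowed_regimes", "indicator_threshold"]
    label: str = ""
    enabled: bool = True
    # allowed_regimes fields
    allowed: list[str] | None = None
    flag: str | None = None
    # indicator_threshold fields
    indicator: str | None = None
    spatial: Literal["sum", "areaWeightedMean"] = "sum"
    alpha: float = Field(1.0, gt=0.0)

    @model_validator(mode="after")
    def _check_fields(self) -> "ConstraintSpec":
        if self.kind == "allowed_regimes":
            if not self.allowed:
                raise ValueError("allowed_regimes needs a non-empty regime whitelist")
            if not self.flag:
                raise ValueError("allowed_regimes needs a stand-flag column name")
        else:
            if not self.indicator:
                raise ValueError("indicator_threshold needs an indicator name")
        return self


class InfeasiblePreferenceWarning(UserWarning):
    """A restriction leaves a stand without any assignable regime."""


def compile_allowed_regimes(spec: ConstraintSpec, stands: Sequence[StandInfo],
                            model: ProblemModel) -> list[tuple[str, str]]:
    """Fix x[s, r] = 0 for disallowed regimes on flagged stands.

    Returns the list of (stand, regime) variables fixed.  A flagged stand with
    no allowed regime simulated triggers a warning (its allocation simplex will
    make the model infeasible, which the solver then reports).
    """
    if spec.kind != "allowed_regimes":
        raise ValueError("spec kind must be allowed_regimes")
    known_flags = {f for s in stands for f in s.flags}
    if spec.flag not in known_flags:
        raise ValueError(f"unknown stand flag column {spec.flag!r}")
    allowed = set(spec.allowed)
    fixed: list[tuple[str, str]] = []
    for stand in stands:
        if not stand.flags.get(spec.flag, False):
            continue
        simulated = [r for (s, r) in model.alloc if s == stand.stand_id]
        if not set(simulated) & allowed:
            warnings.warn(
                f"constraint {spec.key!r}: stand {stand.stand_id!r} has no allowed "
                f"regime among its simulated regimes {sorted(simulated)}; "
                "the model will be infeasible", InfeasiblePreferenceWarning)
        for regime in simulated:
            if regime not in allowed:
                model.fix_to_zero(stand.stand_id, regime)
                fixed.append((stand.stand_id, regime))
    return fixed


def compile_threshold(spec: ConstraintSpec,
                      yearly_forms: Mapping[int, LinearForm]) -> list[Row]:
    """Rows ``V(t) − α·V(t_first) ≥ 0`` for every year after the first."""
    if spec.kind != "indicator_threshold":
        raise ValueError("spec kind must be indicator_threshold")
    years = sorted(yearly_forms)
    if len(years) < 2:
        return []
    base = yearly_forms[years[0]]
    return [Row(yearly_forms[t] - spec.alpha * base, 0.0, np.inf,
                f"{spec.key}@{t}") for t in years[1:]]


def compile_epsilon(eps: Mapping[str, float],
                    objectives: Sequence[CompiledObjective]) -> list[Row]:
    """One row per entry: canonical max-form objective expression ≥ ε."""
    by_key = {o.key: o for o in objectives}
    rows = []
    for key, value in eps.items():
        if key not in by_key:
            raise KeyError(f"ε-constraint references unknown objective {key!r}")
        if not np.isfinite(value):
            raise ValueError(f"ε value for {key!r} must be finite")
        rows.append(Row(by_key[key].expression.copy(), float(value), np.inf,
                        f"eps[{key}]"))
    return rows
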