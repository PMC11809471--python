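"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's linear-form machinery: they
evaluate objectives, constraints and the achievement scalarizing function by
plain pandas/numpy arithmetic over explicit regime assignments, so they can
serve as a second, solver-free route against which the LP implementation is
checked.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from forestopt import IndicatorTable, ObjectiveSpec, StandInfo


# ---------------------------------------------------------------------------
# Tiny fixed fixtures


def make_table(records: dict[tuple[str, str, int], dict[str, float]]) -> IndicatorTable:
    """Build an IndicatorTable from {(stand, regime, year): {indicator: value}}."""
    idx = pd.MultiIndex.from_tuples(list(records), names=["stand", "regime", "year"])
    frame = pd.DataFrame(list(records.values()), index=idx)
    return IndicatorTable(frame)


@pytest.fixture
def toy_table() -> IndicatorTable:
    """1 stand, 2 regimes, 1 year: harvest (A:10, B:0), deadwood (A:0, B:8)."""
    return make_table({
        ("s1", "A", 2020): {"harvest": 10.0, "deadwood": 0.0},
        ("s1", "B", 2020): {"harvest": 0.0, "deadwood": 8.0},
    })


@pytest.fixture
def toy_stands() -> list[StandInfo]:
    return [StandInfo("s1")]


@pytest.fixture
def toy_objectives() -> list[ObjectiveSpec]:
    return [
        ObjectiveSpec(key="harvest", indicator="harvest", temporal="firstYear"),
        ObjectiveSpec(key="deadwood", indicator="deadwood", temporal="firstYear"),
    ]


def sequence_table(values: list[float], indicator: str = "v") -> tuple[IndicatorTable, list[StandInfo]]:
    """One stand, one regime, one indicator following a fixed sequence."""
    years = [2020 + 5 * k for k in range(len(values))]
    table = make_table({("s1", "R", y): {indicator: v} for y, v in zip(years, values)})
    return table, [StandInfo("s1")]


# ---------------------------------------------------------------------------
# Independent oracles


def oracle_yearly_aggregate(table: IndicatorTable, indicator: str,
                            assignment: dict[str, str],
                            areas: dict[str, float] | None = None,
                            spatial: str = "sum") -> dict[int, float]:
    """Landscape aggregate per year for a pure regime assignment (pandas only)."""
    areas = areas or {}
    out = {}
    for year in table.years:
        total, atot = 0.0, 0.0
        for stand, regime in assignment.items():
            v = float(table.frame.loc[(stand, regime, year), indicator])
            a = areas.get(stand, 1.0)
            if spatial == "areaWeightedMean":
                total += a * v
                atot += a
            else:
                total += v
        out[year] = total / atot if spatial == "areaWeightedMean" else total
    return out


def oracle_temporal(temporal: str, values: list[float], sense: str = "max",
                    param=None, slope: float = 0.0, years: list[int] | None = None) -> float:
    """Direct arithmetic definition of every temporal operator (loop-based)."""
    v = [(-x if sense == "min" else x) for x in values]
    T = len(v)
    if temporal == "min":
        return min(v)
    if temporal == "average":
        return sum(v) / T
    if temporal == "sum":
        return sum(v)
    if temporal == "firstYear":
        return v[0]
    if temporal == "lastYear":
        return v[-1]
    if temporal == "targetYear":
        return v[years.index(param)]
    if temporal == "targetYearWithSlope":
        k0 = years.index(param)
        return min(v[k] / (1.0 + slope * (k - k0)) for k in range(k0, T))
    if temporal == "periodicTargets":
        return min(v[k] / param[years[k]] for k in range(T))
    if temporal == "maxYearlyIncrease":
        return min(v[k + 1] - v[k] for k in range(T - 1))
    if temporal == "minYearlyIncrease":
        return -max(v[k + 1] - v[k] for k in range(T - 1))
    if temporal == "maxIncreaseDuringNPeriods":
        return min(v[k + param] - v[k] for k in range(T - param))
    if temporal == "minDecreaseDuringNPeriods":
        return -max(v[k] - v[k + param] for k in range(T - param))
    raise ValueError(temporal)


def oracle_objective_value(table: IndicatorTable, spec: ObjectiveSpec,
                           assignment: dict[str, str],
                           areas: dict[str, float] | None = None) -> float:
    yearly = oracle_yearly_aggregate(table, spec.indicator, assignment, areas,
                                     spec.spatial)
    return oracle_temporal(spec.temporal, [yearly[y] for y in table.years],
                           spec.sense, spec.param, spec.slope, table.years)


def enumerate_assignments(table: IndicatorTable) -> list[dict[str, str]]:
    """Every whole-stand regime assignment (the binary-mode decision space)."""
    stands = sorted(table.stands)
    options = [table.regimes_of(s) for s in stands]
    return [dict(zip(stands, combo)) for combo in itertools.product(*options)]


def oracle_asf(fvec: np.ndarray, z_ref: np.ndarray, ranges: np.ndarray,
               rho: float) -> float:
    return float(min((f - z) / r for f, z, r in zip(fvec, z_ref, ranges))
                 + rho * sum(f / r for f, r in zip(fvec, ranges)))


def oracle_best_assignment(table: IndicatorTable, specs: list[ObjectiveSpec],
                           z_ref: np.ndarray, ranges: np.ndarray, rho: float,
                           eps: dict[str, float] | None = None,
                           areas: dict[str, float] | None = None):
    """Exhaustive search for the best ASF value over pure assignments.

    Returns (best value, best objective vector, all feasible vectors).
    """
    eps = eps or {}
    best, best_vec, vectors = -np.inf, None, []
    for assignment in enumerate_assignments(table):
        fvec = np.array([oracle_objective_value(table, s, assignment, areas)
                         for s in specs])
        if any(fvec[i] < eps[s.key] - 1e-12 for i, s in enumerate(specs)
               if s.key in eps):
            continue
        vectors.append(fvec)
        value = oracle_asf(fvec, z_ref, ranges, rho)
        if value > best:
            best, best_vec = value, fvec
    return best, best_vec, vectors
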