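"""Scenario orchestration: config → load → compile → payoff → solve → export.

A scenario is one declarative YAML file (no code): where the simulator table
lives, the objective declarations, the structural constraints with their
enabled toggles, the reference point, the ε-vector and the scalarization
parameters.  :class:`Session` keeps the compiled problem and the payoff table
alive across preference iterations — re-solving after a reference-point or
ε change reuses the cached payoff, while toggling a structural constraint
recompiles the model and invalidates it (the normalization ranges depend on
the feasible set).

Exports are four CSV tables (floats at 6 significant digits so re-runs are
byte-identical): per-stand regime shares, landscape aggregates of every
indicator under the optimal plan, the payoff table, and per-objective
achievements.  Plots (regime portfolio, normalized achievements, indicator
trajectories) are best-effort: failures are logged, never fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .constraints import ConstraintSpec
from .data import IndicatorTable, StandInfo, load_forest_data
from .objectives import ObjectiveSpec
from .optimizer import AllocationSolution, PayoffTable, ScalarizationParams, \
    compile_problem, compute_payoff, solve_scalarized

log = logging.getLogger("forestopt")

FLOAT_FORMAT = "%.6g"


class DataConfig(BaseModel):
    path: str
    schema_map: dict = Field(default_factory=dict, alias="schema")
    per_hectare: bool = False

    model_config = {"populate_by_name": True}


class ScenarioConfig(BaseModel):
    """Full declarative description of one optimization scenario."""

    data: DataConfig
    objectives: list[ObjectiveSpec]
    constraints: list[ConstraintSpec] = Field(default_factory=list)
    reference_point: dict[str, float] = Field(default_factory=dict)
    epsilon: dict[str, float] = Field(default_factory=dict)
    params: ScalarizationParams = Field(default_factory=ScalarizationParams)
    binary: bool = False
    output: str = "results"

    @model_validator(mode="after")
    def _check_keys(self) -> "ScenarioConfig":
        if not self.objectives:
            raise ValueError("a scenario needs at least one objective")
        keys = [o.key for o in self.objectives]
        if len(set(keys)) != len(keys):
            raise ValueError("objective keys must be unique")
        for section, mapping in (("reference_point", self.reference_point),
                                 ("epsilon", self.epsilon)):
            unknown = set(mapping) - set(keys)
            if unknown:
                raise ValueError(f"{section} references undeclared objectives: "
                                 f"{sorted(unknown)}")
        ckeys = [c.key for c in self.constraints]
        if len(set(ckeys)) != len(ckeys):
            raise ValueError("constraint keys must be unique")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))


@dataclass
class SolutionExport:
    stand_table: pd.DataFrame
    aggregate_table: pd.DataFrame
    payoff_table: pd.DataFrame
    achievement_table: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in [("stand_solution", self.stand_table),
                            ("aggregate_solution", self.aggregate_table),
                            ("payoff", self.payoff_table),
                            ("achievement", self.achievement_table)]:
            p = outdir / f"{name}.csv"
            frame.to_csv(p, index=False, float_format=FLOAT_FORMAT)
            paths[name] = p
        return paths


class Session:
    """One loaded dataset + compiled problem, reused across preference updates."""

    def __init__(self, config: ScenarioConfig,
                 table: IndicatorTable | None = None,
                 stands: list[StandInfo] | None = None):
        self.config = config
        if table is None or stands is None:
            table, stands = _stage("load", load_forest_data,
                                   config.data.path, config.data.schema_map)
        self.table = table
        self.stands = stands
        self._payoff: PayoffTable | None = None
        self.history: list[tuple[dict, dict, AllocationSolution]] = []
        self.solution: AllocationSolution | None = None
        self._compile()

    def _compile(self) -> None:
        self.model, self.objectives = _stage(
            "compile", compile_problem, self.table, self.stands,
            self.config.objectives, self.config.constraints,
            self.config.data.per_hectare, self.config.binary)

    @property
    def payoff(self) -> PayoffTable:
        if self._payoff is None:
            self._payoff = _stage("payoff", compute_payoff, self.model, self.objectives)
            log.info("payoff table:\n%s", self._payoff.as_frame())
        return self._payoff

    def solve(self) -> AllocationSolution:
        sol = _stage("solve", solve_scalarized, self.model, self.objectives,
                     self.payoff, self.config.reference_point,
                     self.config.epsilon, self.config.params)
        log.info("solve status: %s%s", sol.status,
                 f" ({sol.diagnosis})" if sol.diagnosis else "")
        if sol.status == "optimal":
            self.solution = sol
            self.history.append((dict(self.config.reference_point),
                                 dict(self.config.epsilon), sol))
        return sol

    def update_preferences(self, reference_point: Mapping[str, float] | None = None,
                           epsilon: Mapping[str, float] | None = None,
                           enable: Mapping[str, bool] | None = None) -> AllocationSolution:
        """Apply new preferences and re-solve.

        Reference-point / ε changes reuse the cached payoff table; toggling a
        structural constraint recompiles the model and recomputes the payoff.
        An infeasible preference set is reported while the previous solution
        is retained.
        """
        if reference_point is not None:
            self.config.reference_point = dict(reference_point)
        if epsilon is not None:
            self.config.epsilon = dict(epsilon)
        if enable:
            by_key = {c.key: c for c in self.config.constraints}
            for key, state in enable.items():
                if key not in by_key:
                    raise KeyError(f"unknown constraint {key!r}")
                by_key[key].enabled = bool(state)
            self._compile()
            self._payoff = None
        # re-validate cross-references after the in-place edits
        ScenarioConfig.model_validate(self.config.model_dump(by_alias=True))
        return self.solve()

    # -- export ------------------------------------------------------------

    def export(self, solution: AllocationSolution | None = None) -> SolutionExport:
        solution = solution or self.solution
        if solution is None or solution.status != "optimal":
            raise RuntimeError("no optimal solution available to export")
        return build_export(solution, self.payoff, self.table, self.stands,
                            self.config.data.per_hectare)


def _stage(name, fn, *args):
    try:
        return fn(*args)
    except Exception as exc:
        raise type(exc)(f"[stage: {name}] {exc}") from exc


def build_export(solution: AllocationSolution, payoff: PayoffTable,
                 table: IndicatorTable, stands: list[StandInfo],
                 per_hectare: bool = False) -> SolutionExport:
    """Assemble the four export tables, recomputing aggregates from shares."""
    rows = [(s, r, share) for (s, r), share in sorted(solution.shares.items())
            if share > 1e-9]
    stand_table = pd.DataFrame(rows, columns=["stand", "regime", "share"])

    areas = {s.stand_id: s.area for s in stands}
    agg_rows = []
    for indicator in table.indicator_names:
        pairs, values = table.wide(indicator)
        shares = np.array([solution.shares.get(p, 0.0) for p in pairs])
        weights = np.array([areas.get(s, 1.0) for s, _ in pairs]) if per_hectare \
            else np.ones(len(pairs))
        totals = (shares * weights) @ values
        for k, year in enumerate(table.years):
            agg_rows.append((year, indicator, totals[k]))
    aggregate_table = pd.DataFrame(agg_rows, columns=["year", "indicator", "value"])

    payoff_table = payoff.as_frame().reset_index().rename(columns={"index": "maximized"})
    achievement_table = pd.DataFrame(
        [(k, solution.objective_values[k], payoff.nadir[i], payoff.ideal[i],
          solution.achievements[k])
         for i, k in enumerate(payoff.keys)],
        columns=["objective", "value", "nadir", "ideal", "achievement"])
    return SolutionExport(stand_table, aggregate_table, payoff_table, achievement_table)


def run_scenario(config: ScenarioConfig,
                 table: IndicatorTable | None = None,
                 stands: list[StandInfo] | None = None,
                 outdir: str | Path | None = None,
                 plots: bool = False) -> tuple[AllocationSolution, SolutionExport]:
    """One-shot pipeline: load → compile → payoff → solve → export (→ plots)."""
    session = Session(config, table, stands)
    solution = session.solve()
    if solution.status != "optimal":
        raise RuntimeError(f"[stage: solve] scenario infeasible: {solution.diagnosis}")
    export = session.export(solution)
    if outdir is not None:
        export.write(outdir)
        if plots:
            plot_solution(export, Path(outdir) / "figures")
    return solution, export


def plot_solution(export: SolutionExport, outdir: str | Path) -> list[Path]:
    """Write the three standard figures; plotting problems are logged only."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _try(name, fn):
        try:
            fig = fn()
            path = outdir / name
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append(path)
        except Exception:  # pragma: no cover - defensive: plotting is best-effort
            log.exception("plot %s failed", name)

    def portfolio():
        shares = export.stand_table.groupby("regime")["share"].sum()
        shares = shares / shares.sum() * 100.0
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(shares.index, shares.values, color="forestgreen")
        ax.set_ylabel("share of landscape (%)")
        ax.set_title("Optimal management portfolio")
        ax.tick_params(axis="x", rotation=45)
        return fig

    def achievement():
        t = export.achievement_table
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(t["objective"], t["achievement"], color="steelblue")
        ax.set_ylim(0, 1.05)
        ax.set_ylabel("achievement (0 = nadir, 1 = ideal)")
        ax.set_title("Objective achievement")
        ax.tick_params(axis="x", rotation=45)
        return fig

    def trajectories():
        t = export.aggregate_table
        indicators = t["indicator"].unique()
        ncol = 2
        nrow = int(np.ceil(len(indicators) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(9, 2.6 * nrow), squeeze=False)
        for ax, ind in zip(axes.flat, indicators):
            sub = t[t["indicator"] == ind]
            ax.plot(sub["year"], sub["value"], marker=".", color="darkolivegreen")
            ax.set_title(ind, fontsize=9)
        for ax in axes.flat[len(indicators):]:
            ax.axis("off")
        fig.tight_layout()
        return fig

    _try("portfolio.png", portfolio)
    _try("achievement.png", achievement)
    _try("trajectories.png", trajectories)
    return written
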