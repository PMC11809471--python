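"""Seeded generator of simulator-like forest datasets.

Real inputs to the optimizer come from forest growth simulators that project
indicator trajectories per stand under alternative management regimes.  This
generator emulates the structural shape of those outputs — not their
silvicultural fidelity — so the whole pipeline is testable offline:

* ``rotation`` / ``extensive`` regimes produce clearcut harvest pulses
  (standing stock collapses, harvested volume spikes, then regrowth);
* ``ccf`` (continuous cover forestry) removes a steady fraction of the
  increment each period, giving an even harvest flow;
* ``set_aside`` never harvests and accumulates deadwood monotonically in
  expectation (mortality inflow above decay while stock grows).

Stock follows logistic growth; deadwood follows a linear inflow/decay balance;
the recreation index is a logistic squash of stock, deciduous share and large
trees, hence always in [0, 1].  Multiplicative lognormal noise (sd
``noise_sd``) perturbs the volume-like indicators.  Everything is driven by a
single ``numpy`` Generator, so output is a pure function of the config.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .data import IndicatorTable, StandInfo

Behavior = Literal["rotation", "extensive", "ccf", "set_aside"]

INDICATORS = ["harvested_volume", "biomass", "deadwood_volume",
              "deciduous_share", "large_trees", "recreation_index"]


class RegimeTemplate(BaseModel):
    name: str
    behavior: Behavior


DEFAULT_REGIMES = [
    RegimeTemplate(name="BAU", behavior="rotation"),
    RegimeTemplate(name="EXT", behavior="extensive"),
    RegimeTemplate(name="CCF_1", behavior="ccf"),
    RegimeTemplate(name="SA", behavior="set_aside"),
]


class SynthConfig(BaseModel):
    """Generator settings; defaults mirror a 105-year, 5-year-step simulation."""

    n_stands: int = Field(50, gt=0)
    regimes: list[RegimeTemplate] = Field(default_factory=lambda: list(DEFAULT_REGIMES))
    year_start: int = 2016
    year_step: int = Field(5, gt=0)
    n_periods: int = Field(21, gt=1)
    seed: int = 0
    noise_sd: float = Field(0.1, ge=0.0)
    peat_fraction: float = Field(0.2, ge=0.0, le=1.0)

    @field_validator("regimes")
    @classmethod
    def _regime_mix(cls, v: list[RegimeTemplate]) -> list[RegimeTemplate]:
        if len(v) < 2:
            raise ValueError("need at least 2 regimes")
        if not any(r.behavior == "set_aside" for r in v):
            raise ValueError("need at least one set_aside regime")
        if len({r.name for r in v}) != len(v):
            raise ValueError("regime names must be unique")
        return v


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def generate(config: SynthConfig) -> tuple[IndicatorTable, list[StandInfo]]:
    """Simulate every (stand, regime) trajectory; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_stands
    years = np.array([config.year_start + k * config.year_step
                      for k in range(config.n_periods)])
    dt = float(config.year_step)

    # Per-stand site properties (shared across regimes).
    quality = rng.lognormal(0.0, 0.25, n)              # site productivity multiplier
    v0 = rng.uniform(80.0, 220.0, n) * quality         # initial stock, m3/ha-like
    dw0 = rng.uniform(2.0, 10.0, n)                    # initial deadwood
    decid0 = rng.uniform(0.05, 0.45, n)                # initial deciduous share
    area = np.round(rng.uniform(0.5, 5.0, n), 2)       # ha
    peat = rng.random(n) < config.peat_fraction
    capacity = 420.0 * quality
    growth_rate = 0.035 * quality                      # yr^-1

    stand_ids = [f"S{i + 1:04d}" for i in range(n)]
    stands = [StandInfo(stand_ids[i], float(area[i]), {"PEAT": bool(peat[i])})
              for i in range(n)]

    # Clearcut schedules: rotation cuts every ~60-90 yr, extensive ~90-120 yr.
    # The first rotation cut is placed inside the horizon so at least one pulse
    # is guaranteed regardless of the number of periods.
    def schedule(lo_years: float, hi_years: float, guarantee: bool) -> tuple[np.ndarray, np.ndarray]:
        cycle = np.maximum(1, np.round(rng.uniform(lo_years, hi_years, n) / dt)).astype(int)
        hi = np.minimum(cycle, config.n_periods) if guarantee else cycle
        offset = rng.integers(0, hi)  # first cut period; inside horizon if guaranteed
        return cycle, offset

    frames = []
    for regime in config.regimes:
        b = regime.behavior
        if b == "rotation":
            cycle, offset = schedule(60.0, 90.0, guarantee=True)
        elif b == "extensive":
            cycle, offset = schedule(90.0, 120.0, guarantee=False)
        else:
            cycle = offset = None

        stock = v0.copy()
        deadwood = dw0.copy()
        decid = decid0.copy()
        cols = {name: np.empty((config.n_periods, n)) for name in INDICATORS}

        for k in range(config.n_periods):
            harvest = np.zeros(n)
            if b in ("rotation", "extensive"):
                cut = (k >= offset) & ((k - offset) % cycle == 0)
                frac = 0.95 if b == "rotation" else 0.75
                harvest[cut] = frac * stock[cut]
                deadwood[cut] += 0.08 * harvest[cut]   # slash left on site
                stock[cut] *= (1.0 - frac)
                decid[cut] = 0.5 * decid[cut] + 0.5 * decid0[cut]
            elif b == "ccf":
                surplus = np.maximum(0.0, stock - 0.55 * capacity)
                harvest = 0.5 * surplus
                stock -= harvest

            # annual dynamics integrated over the period
            mortality = 0.004 * stock * dt
            deadwood = deadwood + mortality - 0.02 * deadwood * dt
            stock = stock + growth_rate * stock * (1.0 - stock / capacity) * dt
            drift = {"rotation": -0.002, "extensive": -0.001,
                     "ccf": 0.001, "set_aside": 0.002}[b]
            decid = np.clip(decid + drift * dt, 0.01, 0.95)

            large = np.maximum(0.0, stock - 0.45 * capacity) * 0.12
            recreation = _sigmoid(-1.2 + 2.5 * stock / capacity + 1.5 * decid
                                  + 0.05 * large - 2.0 * (harvest > 0))

            noise = rng.lognormal(0.0, config.noise_sd, (4, n)) if config.noise_sd > 0 \
                else np.ones((4, n))
            cols["harvested_volume"][k] = harvest * noise[0]
            cols["biomass"][k] = stock * noise[1]
            cols["deadwood_volume"][k] = deadwood * noise[2]
            cols["large_trees"][k] = large * noise[3]
            cols["deciduous_share"][k] = decid
            cols["recreation_index"][k] = recreation

        idx = pd.MultiIndex.from_product(
            [stand_ids, [regime.name], years.tolist()],
            names=["stand", "regime", "year"])
        block = pd.DataFrame(
            {name: cols[name].T.reshape(-1) for name in INDICATORS}, index=idx)
        frames.append(block)

    frame = pd.concat(frames)
    return IndicatorTable(frame, INDICATORS), stands
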