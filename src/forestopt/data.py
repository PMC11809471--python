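"""Reading, validating and indexing forest-simulator output tables.

Forest growth simulators (SIMO, SiTree, Silva, Heureka, ...) emit one long
table: a row per (stand, management regime, simulation year) with numeric
indicator columns — harvested volume, standing biomass, deadwood volume,
recreation indices and so on.  This module turns one documented CSV dialect of
that table into the canonical :class:`IndicatorTable` the optimizer consumes,
plus per-stand metadata (:class:`StandInfo`: area in hectares and boolean site
flags such as ``PEAT``).

Schema conventions
------------------
CSV, UTF-8, header row, "." decimal separator.  Key columns default to
``standid``, ``regime``, ``year`` and are renameable through the ``schema``
mapping.  An optional ``area`` column (constant per stand, hectares) and any
column whose values are all in {0, 1, true, false} (constant per stand) are
routed to stand metadata; every remaining column must be numeric and becomes
an indicator.  A missing (stand, regime) combination is legal and means the
regime was not simulated for that stand; within a present combination every
year of the simulation period must be covered.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_SCHEMA = {"stand": "standid", "regime": "regime", "year": "year", "area": "area"}

_BOOL_TOKENS = {"0", "1", "true", "false", "0.0", "1.0"}


class SchemaError(ValueError):
    """A required key column is missing or the schema is inconsistent."""


class IntegrityError(ValueError):
    """Duplicate keys, ragged years, or inconsistent per-stand metadata."""


@dataclass
class StandInfo:
    """Per-stand metadata: area (ha, default 1.0) and boolean site flags."""

    stand_id: str
    area: float = 1.0
    flags: dict[str, bool] = field(default_factory=dict)


class IndicatorTable:
    """Validated long table of per-(stand, regime, year) indicator values.

    Internally a pandas DataFrame with a sorted (stand, regime, year)
    MultiIndex; the class enforces the structural invariants on construction:
    unique keys, strictly increasing years, and rectangularity within every
    (stand, regime) pair (each present pair covers every year of the period).
    """

    def __init__(self, frame: pd.DataFrame, indicator_names: list[str] | None = None):
        if list(frame.index.names) != ["stand", "regime", "year"]:
            raise SchemaError("frame must be indexed by (stand, regime, year)")
        frame = frame.sort_index()
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise IntegrityError(f"duplicate (stand, regime, year) key: {dup}")
        self.frame = frame
        self.indicator_names: list[str] = (
            list(indicator_names) if indicator_names is not None else list(frame.columns)
        )
        self.years: list[int] = sorted(frame.index.get_level_values("year").unique())
        self.stands: set[str] = set(frame.index.get_level_values("stand"))
        self.regimes: set[str] = set(frame.index.get_level_values("regime"))
        self._validate_rectangular()
        self._pairs = sorted({(s, r) for s, r, _ in frame.index})

    def _validate_rectangular(self) -> None:
        sizes = self.frame.groupby(level=["stand", "regime"]).size()
        bad = sizes[sizes != len(self.years)]
        if not bad.empty:
            pair = bad.index[0]
            have = set(self.frame.loc[pair].index)
            missing = sorted(set(self.years) - have)
            raise IntegrityError(
                f"(stand, regime) pair {pair} does not cover every simulation year; "
                f"missing years: {missing or 'duplicated years'}"
            )

    # -- access -----------------------------------------------------------

    def pairs(self) -> list[tuple[str, str]]:
        """All simulated (stand, regime) combinations, sorted."""
        return list(self._pairs)

    def regimes_of(self, stand: str) -> list[str]:
        return sorted({r for s, r in self._pairs if s == stand})

    def value(self, stand: str, regime: str, year: int, indicator: str) -> float:
        return float(self.frame.loc[(stand, regime, year), indicator])

    def series(self, stand: str, regime: str, indicator: str) -> np.ndarray:
        """Indicator trajectory of one (stand, regime) pair over ``years``."""
        return self.frame.loc[(stand, regime), indicator].to_numpy(dtype=float)

    def wide(self, indicator: str) -> tuple[list[tuple[str, str]], np.ndarray]:
        """(pairs, values) with values shaped (n_pairs, n_years), pair-major.

        Relies on the rectangularity invariant: the sorted frame is a stack of
        equally sized (stand, regime) blocks.
        """
        if indicator not in self.frame.columns:
            raise KeyError(f"unknown indicator {indicator!r}")
        vals = self.frame[indicator].to_numpy(dtype=float)
        return self._pairs, vals.reshape(len(self._pairs), len(self.years))

    def __len__(self) -> int:
        return len(self.frame)

    # -- derived indicators ------------------------------------------------

    def add_relative_indicator(self, indicator: str, base_year: int,
                               baseline_regime: str | None = None,
                               name: str | None = None) -> str:
        """Add a percent-of-baseline indicator column.

        Each record's value becomes ``100 · value / baseline`` where the
        baseline is the stand's own value of ``indicator`` at ``base_year``
        under ``baseline_regime`` (default: the stand's first regime in
        alphabetical order).  Returns the new column name.
        """
        if indicator not in self.frame.columns:
            raise KeyError(f"unknown indicator {indicator!r}")
        if base_year not in self.years:
            raise ValueError(f"base year {base_year} not in simulation years {self.years}")
        name = name or f"relative_{indicator}"
        baselines: dict[str, float] = {}
        for stand in sorted(self.stands):
            regime = baseline_regime or self.regimes_of(stand)[0]
            if (stand, regime) not in set(self._pairs):
                raise ValueError(
                    f"baseline regime {regime!r} not simulated for stand {stand!r}")
            base = self.value(stand, regime, base_year, indicator)
            if base == 0.0:
                raise ZeroDivisionError(
                    f"zero baseline for stand {stand!r}: {indicator} at {base_year} "
                    f"under regime {regime!r}")
            baselines[stand] = base
        stand_level = self.frame.index.get_level_values("stand")
        denom = np.array([baselines[s] for s in stand_level])
        self.frame[name] = 100.0 * self.frame[indicator].to_numpy(dtype=float) / denom
        if name not in self.indicator_names:
            self.indicator_names.append(name)
        return name


def relative_indicator(table: IndicatorTable, indicator: str, base_year: int,
                       baseline_regime: str | None = None,
                       name: str | None = None) -> str:
    """Functional alias for :meth:`IndicatorTable.add_relative_indicator`."""
    return table.add_relative_indicator(indicator, base_year, baseline_regime, name)


def _resolve_schema(schema: dict[str, str] | None) -> dict[str, str]:
    out = dict(DEFAULT_SCHEMA)
    if schema:
        unknown = set(schema) - {"stand", "regime", "year", "area", "flags", "indicators"}
        if unknown:
            raise SchemaError(f"unknown schema entries: {sorted(unknown)}")
        out.update({k: v for k, v in schema.items() if k in ("stand", "regime", "year", "area")})
    return out


def _is_flag_column(col: pd.Series) -> bool:
    vals = {str(v).strip().lower() for v in col.dropna().unique()}
    return bool(vals) and vals <= _BOOL_TOKENS


def load_forest_data(path: str | Path | io.StringIO,
                     schema: dict | None = None) -> tuple[IndicatorTable, list[StandInfo]]:
    """Read one simulator-output CSV into an IndicatorTable plus stand metadata.

    ``schema`` may rename the key columns (``stand``, ``regime``, ``year``,
    ``area``) and may pin column roles with ``flags`` (list of columns to route
    to StandInfo) and ``indicators`` (list of columns to keep as indicators even
    if boolean-valued).  Unpinned {0,1}-valued columns are auto-detected flags.
    """
    names = _resolve_schema(schema)
    raw = pd.read_csv(path, dtype={names["stand"]: str, names["regime"]: str},
                      float_precision="round_trip")
    for role in ("stand", "regime", "year"):
        if names[role] not in raw.columns:
            raise SchemaError(f"missing required column {names[role]!r} (role: {role})")

    key_cols = [names["stand"], names["regime"], names["year"]]
    try:
        raw[names["year"]] = raw[names["year"]].astype(int)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"year column {names['year']!r} is not integer-valued") from exc

    dup_mask = raw.duplicated(subset=key_cols, keep=False)
    if dup_mask.any():
        first = raw.loc[dup_mask, key_cols].iloc[0]
        raise IntegrityError(
            "duplicate (stand, regime, year) key: "
            f"({first.iloc[0]!r}, {first.iloc[1]!r}, {int(first.iloc[2])})")

    forced_flags = list((schema or {}).get("flags", []))
    forced_indicators = set((schema or {}).get("indicators", []))
    value_cols = [c for c in raw.columns if c not in key_cols]

    flag_cols, indicator_cols = [], []
    area_col = names["area"] if names["area"] in value_cols else None
    for col in value_cols:
        if col == area_col or col in forced_flags:
            continue
        if col not in forced_indicators and _is_flag_column(raw[col]):
            flag_cols.append(col)
        else:
            indicator_cols.append(col)
    flag_cols = forced_flags + flag_cols
    for col in forced_flags:
        if col not in raw.columns:
            raise SchemaError(f"declared flag column {col!r} not in file")

    for col in indicator_cols:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() & raw[col].notna()
        if bad.any() or raw[col].isna().any():
            rownum = int((bad | raw[col].isna()).idxmax()) + 2  # header + 1-based
        else:
            rownum = None
        if rownum is not None:
            raise IntegrityError(
                f"non-numeric or missing value in indicator column {col!r} "
                f"at file row {rownum}")
        raw[col] = numeric

    frame = raw.set_index(key_cols)[indicator_cols]
    frame.index.names = ["stand", "regime", "year"]
    table = IndicatorTable(frame, indicator_cols)

    stands_meta: list[StandInfo] = []
    grouped = raw.groupby(names["stand"], sort=True)
    for stand_id, grp in grouped:
        area = 1.0
        if area_col is not None:
            vals = grp[area_col].astype(float).unique()
            if len(vals) > 1:
                raise IntegrityError(f"stand {stand_id!r} has inconsistent area values")
            area = float(vals[0])
            if area < 0:
                raise IntegrityError(f"stand {stand_id!r} has negative area {area}")
        flags = {}
        for col in flag_cols:
            tokens = {str(v).strip().lower() for v in grp[col].unique()}
            if len(tokens) > 1:
                raise IntegrityError(
                    f"stand {stand_id!r} has inconsistent values in flag column {col!r}")
            flags[col] = tokens.pop() in {"1", "true", "1.0"}
        stands_meta.append(StandInfo(str(stand_id), area, flags))
    return table, stands_meta


def write_forest_data(table: IndicatorTable, stands: list[StandInfo],
                      path: str | Path, schema: dict | None = None) -> None:
    """Write the canonical CSV dialect back out (round-trips with the loader)."""
    names = _resolve_schema(schema)
    out = table.frame.reset_index()
    out = out.rename(columns={"stand": names["stand"], "regime": names["regime"],
                              "year": names["year"]})
    info = {s.stand_id: s for s in stands}
    flag_names = sorted({f for s in stands for f in s.flags})
    if any(s.area != 1.0 for s in stands):
        out[names["area"]] = [info[s].area for s in out[names["stand"]]]
    for flag in flag_names:
        out[flag] = [int(info[s].flags.get(flag, False)) for s in out[names["stand"]]]
    out.to_csv(path, index=False)
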