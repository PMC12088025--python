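"""Risk tables over access-time intervals and MWH move-date scenarios.

The published decision tables (and the rotating-wheel device that
embodies them) tabulate P(SBA) for a grid of SBA access-time intervals
against six MWH scenarios.  Because a woman's travel-time estimate is
uncertain, each interval conservatively reports the *lowest* P(SBA) it
contains — by monotonicity of Gk, the value at the interval's upper
bound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .distributions import LatentPhaseDistribution, OnsetDistribution, Parity
from .model import (
    DEFAULT_MOVE_DATES,
    RiskEstimate,
    Scenario,
    _move_date_key,
    p_sba,
)

__all__ = [
    "AccessTimeInterval",
    "TableCell",
    "RiskTable",
    "default_interval_grid",
    "cell_value",
    "build_risk_table",
    "export_table",
    "read_table",
    "wheel_data",
]


@dataclass(frozen=True)
class AccessTimeInterval:
    """Half-open access-time interval (lower, upper], in hours.

    The conservative evaluation point is the upper bound; endpoint
    ownership therefore never affects a table value.
    """

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0 <= self.lower < self.upper:
            raise ValueError(f"need 0 <= lower < upper, got [{self.lower}, {self.upper}]")

    @property
    def label(self) -> str:
        def fmt(v: float) -> str:
            return f"{v:g}"

        return f"{fmt(self.lower)}-{fmt(self.upper)}"


def default_interval_grid() -> list[AccessTimeInterval]:
    """The published 22-row grid: 1-hour rows up to 3 h, then 30-minute
    rows from 3 h to 12.5 h."""
    edges = [0.0, 1.0, 2.0, 3.0] + list(np.arange(3.5, 12.51, 0.5))
    return [AccessTimeInterval(a, b) for a, b in zip(edges[:-1], edges[1:])]


@dataclass(frozen=True)
class TableCell:
    """One table entry: the conservative P(SBA) and optional bootstrap CI."""

    p_sba: float
    gk_of_t: float
    f_of_d: float
    category: str
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError("ci_low and ci_high must be given together")
        if self.ci_low is not None and not self.ci_low <= self.p_sba <= self.ci_high:
            raise ValueError("CI must contain the point estimate")

    @property
    def display(self) -> str:
        """Two-decimal display value (exports keep full precision)."""
        return f"{round2(self.p_sba):.2f}"


def round2(p: float) -> float:
    """Half-up rounding to two decimals, as in the printed tables."""
    return float(np.floor(p * 100 + 0.5) / 100)


def cell_value(
    interval: AccessTimeInterval,
    move_date: float,
    parity: Parity,
    onset: OnsetDistribution,
    latent: LatentPhaseDistribution,
) -> RiskEstimate:
    """Conservative P(SBA) for an interval: the value at its upper bound."""
    return p_sba(Scenario(parity, interval.upper, move_date), onset, latent)


@dataclass(frozen=True)
class RiskTable:
    """Grid of access-time intervals × MWH move-date scenarios."""

    parity: Parity
    intervals: tuple[AccessTimeInterval, ...]
    move_dates: tuple[float, ...]
    cells: tuple[tuple[TableCell, ...], ...] = field(repr=False)

    @property
    def column_keys(self) -> list[str]:
        return [_move_date_key(d) for d in self.move_dates]

    def cell(self, row: int, col: int) -> TableCell:
        return self.cells[row][col]

    def to_dataframe(self) -> pd.DataFrame:
        """Full-precision tabular view, one row per interval."""
        records = []
        for interval, row in zip(self.intervals, self.cells):
            rec: dict = {"access_time": interval.label}
            for key, cell in zip(self.column_keys, row):
                rec[key] = cell.p_sba
            for key, cell in zip(self.column_keys, row):
                if cell.ci_low is not None:
                    rec[f"{key}_ci_low"] = cell.ci_low
                    rec[f"{key}_ci_high"] = cell.ci_high
            for key, cell in zip(self.column_keys, row):
                rec[f"{key}_category"] = cell.category
            records.append(rec)
        return pd.DataFrame.from_records(records)


def build_risk_table(
    parity: Parity,
    onset: OnsetDistribution,
    latent: LatentPhaseDistribution,
    grid: Sequence[AccessTimeInterval] | None = None,
    move_dates: Sequence[float] = DEFAULT_MOVE_DATES,
    cis: dict[tuple[int, int], tuple[float, float]] | None = None,
) -> RiskTable:
    """Fill the whole table via the conservative per-interval convention.

    ``cis`` optionally maps (row, column) indices to bootstrap
    confidence bounds, as produced by :func:`sbarisk.bootstrap.bootstrap_cis`.
    """
    grid = list(grid) if grid is not None else default_interval_grid()
    if not grid or not move_dates:
        raise ValueError("grid and move_dates must be non-empty")
    rows = []
    for i, interval in enumerate(grid):
        row = []
        for j, d in enumerate(move_dates):
            est = cell_value(interval, d, parity, onset, latent)
            lo, hi = (cis or {}).get((i, j), (None, None))
            if lo is not None:
                # percentile intervals can (rarely) exclude the plug-in
                # value; displayed CIs are widened to contain it
                lo, hi = min(lo, est.p_sba), max(hi, est.p_sba)
            row.append(
                TableCell(
                    p_sba=est.p_sba,
                    gk_of_t=est.gk_of_t,
                    f_of_d=est.f_of_d,
                    category=est.category,
                    ci_low=lo,
                    ci_high=hi,
                )
            )
        rows.append(tuple(row))
    return RiskTable(
        parity=parity,
        intervals=tuple(grid),
        move_dates=tuple(float(d) for d in move_dates),
        cells=tuple(rows),
    )


def export_table(table: RiskTable, path: str | Path, format: str | None = None) -> Path:
    """Serialise a table to CSV (flat) or JSON (nested rows/columns).

    Numeric cells are written at full precision so a round-trip read
    reproduces them exactly.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = table.to_dataframe()
        df.to_csv(path, index=False, float_format="%.17g")
        return path
    if fmt == "json":
        payload = {
            "parity": table.parity,
            "move_dates": [None if np.isinf(d) else d for d in table.move_dates],
            "column_keys": table.column_keys,
            "rows": [
                {
                    "access_time": interval.label,
                    "lower": interval.lower,
                    "upper": interval.upper,
                    "cells": {
                        key: {
                            "p_sba": cell.p_sba,
                            "gk_of_t": cell.gk_of_t,
                            "f_of_d": cell.f_of_d,
                            "category": cell.category,
                            "ci": None
                            if cell.ci_low is None
                            else [cell.ci_low, cell.ci_high],
                        }
                        for key, cell in zip(table.column_keys, row)
                    },
                }
                for interval, row in zip(table.intervals, table.cells)
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return path
    raise ValueError(f"unsupported table format {fmt!r}; use 'csv' or 'json'")


def read_table(path: str | Path) -> RiskTable:
    """Re-read a JSON table export, reproducing all numeric cells exactly."""
    path = Path(path)
    if path.suffix.lower() != ".json":
        raise ValueError("round-trip reading is supported for JSON exports")
    payload = json.loads(path.read_text())
    move_dates = tuple(np.inf if d is None else float(d) for d in payload["move_dates"])
    intervals, rows = [], []
    for row in payload["rows"]:
        intervals.append(AccessTimeInterval(row["lower"], row["upper"]))
        cells = []
        for key in payload["column_keys"]:
            c = row["cells"][key]
            ci = c.get("ci")
            cells.append(
                TableCell(
                    p_sba=c["p_sba"],
                    gk_of_t=c["gk_of_t"],
                    f_of_d=c["f_of_d"],
                    category=c["category"],
                    ci_low=None if ci is None else ci[0],
                    ci_high=None if ci is None else ci[1],
                )
            )
        rows.append(tuple(cells))
    return RiskTable(
        parity=payload["parity"],
        intervals=tuple(intervals),
        move_dates=move_dates,
        cells=tuple(rows),
    )


def wheel_data(table: RiskTable) -> dict:
    """Reshape a table as the lower-wheel data of the physical device:
    six concentric rings (one per MWH scenario), each keyed by the
    access-time interval labels on the outer edge."""
    return {
        "parity": table.parity,
        "outer_edge": [iv.label for iv in table.intervals],
        "rings": [
            {
                "scenario": key,
                "values": {
                    iv.label: round2(row[j].p_sba)
                    for iv, row in zip(table.intervals, table.cells)
                },
            }
            for j, key in enumerate(table.column_keys)
        ],
    }
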