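"""Fishing-ground analytics on logbook records.

Catch and CPUE are aggregated on a 0.5-degree grid (half-open cells indexed
by their lower-left corner, so every position belongs to exactly one cell),
annual fishing-ground gravity centers are catch-weighted planar means of the
operation positions, and Spearman rank correlations relate per-operation
CPUE to year, month, longitude and latitude.

CPUE is defined as catch per net deployment (tonnes/net). Cell-level CPUE is
the total-catch-over-total-nets ratio, not the mean of per-operation ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, ParameterError
from .tables import LogbookRecord

__all__ = [
    "CenterOfGravity",
    "cpue_per_operation",
    "grid_aggregate",
    "center_of_gravity",
    "spearman_rho",
    "cpue_correlations",
]


@dataclass(frozen=True)
class CenterOfGravity:
    """Catch-weighted mean position of one year's fishing operations."""

    year: int
    lat: float
    lon: float


def cpue_per_operation(record: LogbookRecord) -> float:
    """Catch per net deployment for a single operation (t/net)."""
    if record.nets < 1:
        raise ParameterError("nets must be >= 1")
    return record.catch_t / record.nets


def _frame(records: Iterable[LogbookRecord]) -> pd.DataFrame:
    rows = [
        (r.date.year, r.date.month, r.lat, r.lon, r.nets, r.catch_t)
        for r in records
    ]
    return pd.DataFrame(rows, columns=["year", "month", "lat", "lon", "nets",
                                       "catch_t"])


def grid_aggregate(records: Iterable[LogbookRecord], cell_deg: float = 0.5
                   ) -> pd.DataFrame:
    """Per-(cell, year) totals and CPUE.

    Columns: ``cell_lat, cell_lon`` (lower edges, multiples of ``cell_deg``),
    ``year, total_catch, total_nets, n_ops, cpue``. Aggregation conserves
    total catch and total operations exactly; empty input yields an empty
    frame with the same columns.
    """
    if not cell_deg > 0:
        raise ParameterError("cell_deg must be positive")
    df = _frame(records)
    if df.empty:
        return pd.DataFrame(columns=["cell_lat", "cell_lon", "year",
                                     "total_catch", "total_nets", "n_ops", "cpue"])
    df["cell_lat"] = np.floor(df["lat"] / cell_deg) * cell_deg
    df["cell_lon"] = np.floor(df["lon"] / cell_deg) * cell_deg
    out = (
        df.groupby(["cell_lat", "cell_lon", "year"], as_index=False)
        .agg(total_catch=("catch_t", "sum"), total_nets=("nets", "sum"),
             n_ops=("catch_t", "size"))
    )
    out["cpue"] = out["total_catch"] / out["total_nets"]
    return out


def center_of_gravity(records: Iterable[LogbookRecord], year: int | None = None
                      ) -> CenterOfGravity:
    """Catch-weighted arithmetic mean position, optionally for one year."""
    df = _frame(records)
    if year is not None:
        df = df[df["year"] == year]
    if df.empty:
        raise DataError(f"no records{f' for year {year}' if year else ''}")
    w = df["catch_t"].to_numpy()
    if w.sum() <= 0:
        raise DataError("zero total catch: gravity center undefined")
    return CenterOfGravity(
        year=int(year) if year is not None else int(df["year"].iloc[0]),
        lat=float(np.average(df["lat"], weights=w)),
        lon=float(np.average(df["lon"], weights=w)),
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties and its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise DataError("need two equal-length 1-D vectors with >= 3 elements")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("constant input: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def cpue_correlations(records: Iterable[LogbookRecord]) -> pd.DataFrame:
    """Spearman rho and p of per-operation CPUE against year, month,
    longitude and latitude (constant covariates are reported as NaN)."""
    df = _frame(records)
    if len(df) < 3:
        raise DataError("need at least 3 records")
    cpue = (df["catch_t"] / df["nets"]).to_numpy()
    rows = []
    for name, col in (("year", "year"), ("month", "month"),
                      ("longitude", "lon"), ("latitude", "lat")):
        try:
            rho, p = spearman_rho(df[col].to_numpy(), cpue)
        except DataError:
            rho, p = float("nan"), float("nan")
        rows.append({"covariate": name, "rho": rho, "p_value": p})
    return pd.DataFrame(rows)
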