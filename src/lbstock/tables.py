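"""Tabular containers and CSV readers/writers.

Two interchange formats drive the pipeline:

* length-frequency CSV with header ``year,bin_lower_mm,count`` — fork-length
  bins (half-open ``[lower, lower+width)``, lower edge in mm) with the number
  of measured fish per bin and year;
* logbook CSV with header ``date,lat,lon,nets,catch_t`` — one purse-seine
  operation per row (ISO-8601 date, decimal degrees, net deployments, catch
  in tonnes).

Readers validate rather than coerce: malformed rows raise
:class:`~lbstock.exceptions.FormatError`.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError

__all__ = [
    "LengthFrequencyTable",
    "LogbookRecord",
    "read_length_frequency",
    "write_length_frequency",
    "read_logbook",
    "write_logbook",
    "logbook_frame",
]


@dataclass
class LengthFrequencyTable:
    """Binned counts of fork length for one year.

    Parameters
    ----------
    year : int
        Calendar year of the sample.
    bin_lower : array of float
        Lower edges of the length bins, in mm. Bins are half-open
        ``[lower, lower + bin_width)``. Gaps are filled with zero-count bins
        so the stored grid is contiguous.
    counts : array of int
        Number of fish per bin; zero-count bins are retained.
    bin_width : float
        Uniform bin width in mm (10 mm by default throughout the package).
    """

    year: int
    bin_lower: np.ndarray
    counts: np.ndarray
    bin_width: float = 10.0

    def __post_init__(self) -> None:
        lower = np.asarray(self.bin_lower, dtype=float)
        counts = np.asarray(self.counts)
        if lower.ndim != 1 or counts.shape != lower.shape:
            raise FormatError("bin_lower and counts must be 1-D arrays of equal length")
        if not (self.bin_width > 0):
            raise FormatError("bin_width must be positive")
        if np.unique(lower).size != lower.size:
            raise FormatError(f"duplicate length bins for year {self.year}")
        if np.any(counts < 0):
            raise FormatError("negative counts are not allowed")
        if not np.allclose(counts, np.round(counts)):
            raise FormatError("counts must be integers")
        order = np.argsort(lower)
        lower, counts = lower[order], np.round(counts[order]).astype(np.int64)
        offsets = (lower - lower[0]) / self.bin_width
        if not np.allclose(offsets, np.round(offsets), atol=1e-9):
            raise FormatError(
                "bin lower edges must lie on a uniform grid of width "
                f"{self.bin_width} mm (year {self.year})"
            )
        # fill interior gaps with empty bins so the grid is contiguous
        idx = np.round(offsets).astype(int)
        full = np.zeros(idx[-1] + 1, dtype=np.int64)
        full[idx] = counts
        self.bin_lower = lower[0] + self.bin_width * np.arange(full.size)
        self.counts = full
        if int((self.counts > 0).sum()) < 2:
            raise FormatError("a length-frequency table needs at least 2 non-empty bins")

    # -- geometry -----------------------------------------------------------
    @property
    def edges_mm(self) -> np.ndarray:
        """Bin edges in mm, length ``n_bins + 1``."""
        return np.append(self.bin_lower, self.bin_lower[-1] + self.bin_width)

    @property
    def edges_cm(self) -> np.ndarray:
        return self.edges_mm / 10.0

    @property
    def mid_mm(self) -> np.ndarray:
        return self.bin_lower + self.bin_width / 2.0

    @property
    def mid_cm(self) -> np.ndarray:
        return self.mid_mm / 10.0

    @property
    def n_fish(self) -> int:
        return int(self.counts.sum())

    def trimmed(self) -> "LengthFrequencyTable":
        """Copy without leading/trailing empty bins."""
        nz = np.nonzero(self.counts)[0]
        sl = slice(nz[0], nz[-1] + 1)
        return LengthFrequencyTable(
            self.year, self.bin_lower[sl].copy(), self.counts[sl].copy(), self.bin_width
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.year,
                "bin_lower_mm": self.bin_lower,
                "count": self.counts,
            }
        )


@dataclass(frozen=True)
class LogbookRecord:
    """One fishing operation from a commercial purse-seine logbook."""

    date: dt.date
    lat: float
    lon: float
    nets: int
    catch_t: float

    def __post_init__(self) -> None:
        if self.nets < 1:
            raise FormatError("nets must be >= 1 (CPUE is undefined otherwise)")
        if self.catch_t < 0:
            raise FormatError("catch must be non-negative")
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise FormatError("latitude/longitude must be finite")


# ---------------------------------------------------------------------------
# length-frequency CSV
# ---------------------------------------------------------------------------

_LF_COLUMNS = ["year", "bin_lower_mm", "count"]


def read_length_frequency(path) -> dict[int, LengthFrequencyTable]:
    """Read a multi-year length-frequency CSV into per-year tables.

    Returns a dict keyed by year. Rows with ``count == 0`` are retained.
    Duplicate (year, bin) rows, negative or non-numeric counts, and bins off
    the uniform grid raise :class:`FormatError`.
    """
    df = pd.read_csv(path)
    if list(df.columns) != _LF_COLUMNS:
        raise FormatError(f"expected columns {_LF_COLUMNS}, got {list(df.columns)}")
    for col in _LF_COLUMNS:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"non-numeric values in column '{col}'")
    if df.duplicated(subset=["year", "bin_lower_mm"]).any():
        raise FormatError("duplicate (year, bin_lower_mm) rows")
    widths = []
    for _, grp in df.groupby("year"):
        lows = np.sort(grp["bin_lower_mm"].to_numpy(dtype=float))
        if lows.size >= 2:
            widths.append(np.min(np.diff(lows)))
    bin_width = float(min(widths)) if widths else 10.0
    tables: dict[int, LengthFrequencyTable] = {}
    for year, grp in df.groupby("year"):
        tables[int(year)] = LengthFrequencyTable(
            int(year),
            grp["bin_lower_mm"].to_numpy(dtype=float),
            grp["count"].to_numpy(),
            bin_width,
        )
    return tables


def write_length_frequency(
    tables: Mapping[int, LengthFrequencyTable] | Iterable[LengthFrequencyTable], path
) -> None:
    if isinstance(tables, Mapping):
        tables = [tables[k] for k in sorted(tables)]
    frame = pd.concat([t.to_frame() for t in tables], ignore_index=True)
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# logbook CSV
# ---------------------------------------------------------------------------

_LOG_COLUMNS = ["date", "lat", "lon", "nets", "catch_t"]


def read_logbook(path) -> list[LogbookRecord]:
    """Read a logbook CSV into records; dates must be ISO-8601."""
    df = pd.read_csv(path)
    if list(df.columns) != _LOG_COLUMNS:
        raise FormatError(f"expected columns {_LOG_COLUMNS}, got {list(df.columns)}")
    for col in ("lat", "lon", "nets", "catch_t"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"non-numeric values in column '{col}'")
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable date: {exc}") from exc
    nets = df["nets"].to_numpy()
    if np.any(nets < 1) or not np.allclose(nets, np.round(nets)):
        raise FormatError("nets must be positive integers (CPUE undefined for nets=0)")
    return [
        LogbookRecord(d.date(), float(la), float(lo), int(n), float(c))
        for d, la, lo, n, c in zip(
            dates, df["lat"], df["lon"], nets, df["catch_t"]
        )
    ]


def write_logbook(records: Iterable[LogbookRecord], path) -> None:
    logbook_frame(records).to_csv(path, index=False)


def logbook_frame(records: Iterable[LogbookRecord]) -> pd.DataFrame:
    """Records as a DataFrame with an added ``year``/``month`` convenience view."""
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=_LOG_COLUMNS)
    if len(df):
        df["date"] = [r["date"].isoformat() for r in rows]
    return df
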