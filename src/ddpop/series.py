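"""Core data containers for colony count time series and conversion factors.

Counts are stored as floats with NaN marking missing years; observed values
are whole numbers.  Series are exchanged on disk as delimited tables with
columns ``colony_id, species, year, count, unit`` (blank count = missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PAIRS = "pairs"
INDIVIDUALS = "individuals"
VALID_UNITS = (PAIRS, INDIVIDUALS)


@dataclass
class CountTimeSeries:
    """One colony's annual counts, possibly with missing years.

    Parameters
    ----------
    colony_id, species:
        Labels used to key the series in reports.
    years:
        Strictly increasing integer years.
    counts:
        Same length as ``years``; non-negative, NaN where no count was made.
    unit:
        ``"pairs"`` or ``"individuals"``.
    """

    colony_id: str
    species: str
    years: np.ndarray
    counts: np.ndarray
    unit: str = PAIRS

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.years.ndim != 1 or self.counts.ndim != 1:
            raise ValueError("years and counts must be 1-D")
        if len(self.years) != len(self.counts):
            raise ValueError("years and counts must have equal length")
        if len(self.years) and np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        obs = self.observed_mask
        if not obs.any():
            raise ValueError("series must contain at least one non-missing count")
        if np.any(self.counts[obs] < 0):
            raise ValueError("counts must be non-negative")

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.counts)

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())

    @property
    def observed_years(self) -> np.ndarray:
        return self.years[self.observed_mask]

    @property
    def observed_counts(self) -> np.ndarray:
        return self.counts[self.observed_mask]

    @property
    def first_observed_count(self) -> float:
        return float(self.observed_counts[0])

    @property
    def max_observed_count(self) -> float:
        return float(self.observed_counts.max())

    def drop_first_observation(self) -> "CountTimeSeries":
        """Return a copy with the first non-missing observation removed."""
        idx = int(np.flatnonzero(self.observed_mask)[0])
        keep = np.ones(len(self.years), dtype=bool)
        keep[: idx + 1] = False
        return replace(self, years=self.years[keep], counts=self.counts[keep])

    def reindexed(self) -> "CountTimeSeries":
        """Return the series on a contiguous annual grid (gaps become NaN)."""
        full = np.arange(self.years[0], self.years[-1] + 1)
        counts = np.full(full.shape, np.nan)
        counts[np.searchsorted(full, self.years)] = self.counts
        return replace(self, years=full, counts=counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "colony_id": self.colony_id,
                "species": self.species,
                "year": self.years,
                "count": self.counts,
                "unit": self.unit,
            }
        )


@dataclass
class ConversionSeries:
    """Smoothed annual individuals-to-pairs conversion factor with SEs."""

    years: np.ndarray
    m_kt: np.ndarray
    s_kt: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.m_kt = np.asarray(self.m_kt, dtype=float)
        self.s_kt = np.asarray(self.s_kt, dtype=float)
        if not (len(self.years) == len(self.m_kt) == len(self.s_kt)):
            raise ValueError("years, m_kt, s_kt must have equal length")
        if np.any(self.m_kt <= 0):
            raise ValueError("m_kt must be positive")
        if np.any(self.s_kt < 0):
            raise ValueError("s_kt must be non-negative")

    def at_years(self, years: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolate (m_kt, s_kt) to ``years``, clamping at the ends."""
        years = np.asarray(years, dtype=float)
        m = np.interp(years, self.years.astype(float), self.m_kt)
        s = np.interp(years, self.years.astype(float), self.s_kt)
        return m, s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "m_kt": self.m_kt, "s_kt": self.s_kt})


def write_counts(collection: Iterable[CountTimeSeries], path: str | Path) -> None:
    """Write a collection of series to one delimited table (blank = missing)."""
    frames = [s.to_frame() for s in collection]
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.10g")


def read_counts(path: str | Path) -> list[CountTimeSeries]:
    """Read a collection of series from a delimited count table."""
    df = pd.read_csv(path)
    required = {"colony_id", "species", "year", "count", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table is missing columns: {sorted(missing)}")
    out: list[CountTimeSeries] = []
    for (cid, sp, unit), grp in df.groupby(["colony_id", "species", "unit"], sort=True):
        grp = grp.sort_values("year")
        out.append(
            CountTimeSeries(
                colony_id=str(cid),
                species=str(sp),
                years=grp["year"].to_numpy(),
                counts=grp["count"].to_numpy(dtype=float),
                unit=str(unit),
            )
        )
    return out


def write_conversion(conv: ConversionSeries, path: str | Path) -> None:
    conv.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_conversion(path: str | Path) -> ConversionSeries:
    df = pd.read_csv(path)
    return ConversionSeries(
        years=df["year"].to_numpy(), m_kt=df["m_kt"].to_numpy(), s_kt=df["s_kt"].to_numpy()
    )
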