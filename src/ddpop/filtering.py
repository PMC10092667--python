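"""Colony-selection rules and conversion-factor smoothing.

The selection pipeline keeps, per species, the series that (1) have enough
observed years, (2) are not unusually small relative to the species' other
colonies (by maximum and by first observed count), and (3) do not start with
a long sporadic gap.  Rules are applied in that order and each rule's drops
are recorded in a :class:`FilterReport`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .series import ConversionSeries, CountTimeSeries

log = logging.getLogger(__name__)


def filter_min_years(
    collection: list[CountTimeSeries], min_years: int = 20
) -> list[CountTimeSeries]:
    """Retain series with at least ``min_years`` non-missing annual counts."""
    if min_years < 1:
        raise ValueError("min_years must be >= 1")
    return [s for s in collection if s.n_observed >= min_years]


def _quantile_filter(
    collection: list[CountTimeSeries], q: float, statistic
) -> list[CountTimeSeries]:
    """Drop series whose per-series statistic falls below the within-species
    q-quantile of that statistic (linear-interpolation / type-7 quantile)."""
    if not 0 <= q <= 1:
        raise ValueError("q must lie in [0, 1]")
    by_species: dict[str, list[CountTimeSeries]] = {}
    for s in collection:
        by_species.setdefault(s.species, []).append(s)
    keep: set[int] = set()
    for members in by_species.values():
        stats = np.array([statistic(s) for s in members])
        threshold = np.quantile(stats, q)  # type-7 linear interpolation
        for s, v in zip(members, stats):
            if v >= threshold:
                keep.add(id(s))
    return [s for s in collection if id(s) in keep]


def filter_low_max_count(
    collection: list[CountTimeSeries], q: float = 0.10
) -> list[CountTimeSeries]:
    """Drop series whose maximum observed count is below the species-level
    ``q``-quantile of per-series maximum counts."""
    return _quantile_filter(collection, q, lambda s: s.max_observed_count)


def filter_low_first_count(
    collection: list[CountTimeSeries], q: float = 0.05
) -> list[CountTimeSeries]:
    """Drop series whose first observed count is below the species-level
    ``q``-quantile of per-series first observed counts."""
    return _quantile_filter(collection, q, lambda s: s.first_observed_count)


def truncate_leading_gap(series: CountTimeSeries, max_gap: int = 5) -> CountTimeSeries:
    """Drop the first observation if the gap to the next one exceeds ``max_gap``.

    Applied once, not iterated: this corrects a single sporadic early count.
    Series with fewer than two observations are returned unchanged.
    """
    obs_years = series.observed_years
    if len(obs_years) < 2:
        return series
    if obs_years[1] - obs_years[0] > max_gap:
        return series.drop_first_observation()
    return series


@dataclass
class FilterReport:
    """Per-rule retention bookkeeping for one filtering pass."""

    n_input: int = 0
    dropped_min_years: int = 0
    dropped_low_max: int = 0
    dropped_low_first: int = 0
    truncated_leading_gap: int = 0
    n_output: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": [
                    "input",
                    "min_years",
                    "low_max_count",
                    "low_first_count",
                    "leading_gap_truncation",
                    "output",
                ],
                "dropped_or_modified": [
                    0,
                    self.dropped_min_years,
                    self.dropped_low_max,
                    self.dropped_low_first,
                    self.truncated_leading_gap,
                    0,
                ],
                "n_series": [
                    self.n_input,
                    self.n_input - self.dropped_min_years,
                    self.n_input - self.dropped_min_years - self.dropped_low_max,
                    self.n_output,
                    self.n_output,
                    self.n_output,
                ],
            }
        )


def apply_filters(
    collection: list[CountTimeSeries],
    min_years: int = 20,
    max_count_q: float = 0.10,
    first_count_q: float = 0.05,
    max_gap: int = 5,
) -> tuple[list[CountTimeSeries], FilterReport]:
    """Apply the four selection rules in order and report per-rule drops.

    Order: min-years -> low-max -> low-first -> leading-gap truncation.
    Retained counts are never modified except by the documented first-year
    truncation.
    """
    report = FilterReport(n_input=len(collection))
    stage1 = filter_min_years(collection, min_years)
    report.dropped_min_years = len(collection) - len(stage1)
    stage2 = filter_low_max_count(stage1, max_count_q)
    report.dropped_low_max = len(stage1) - len(stage2)
    stage3 = filter_low_first_count(stage2, first_count_q)
    report.dropped_low_first = len(stage2) - len(stage3)
    out = []
    for s in stage3:
        truncated = truncate_leading_gap(s, max_gap)
        if truncated is not s:
            report.truncated_leading_gap += 1
        out.append(truncated)
    report.n_output = len(out)
    log.info(
        "filtering: %d -> %d series (min_years -%d, low_max -%d, low_first -%d, "
        "%d leading gaps truncated)",
        report.n_input,
        report.n_output,
        report.dropped_min_years,
        report.dropped_low_max,
        report.dropped_low_first,
        report.truncated_leading_gap,
    )
    return out, report


def _bspline_design(x: np.ndarray, df: int, degree: int = 3) -> tuple[np.ndarray, np.ndarray, int]:
    """Cubic B-spline design matrix with quantile-placed interior knots."""
    n_interior = max(df - degree - 1, 0)
    if n_interior > 0:
        interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
    else:
        interior = np.array([])
    lo, hi = x.min(), x.max()
    pad = max(1e-8, 1e-8 * (hi - lo))
    t = np.concatenate(
        [np.full(degree + 1, lo - pad), interior, np.full(degree + 1, hi + pad)]
    )
    design = BSpline.design_matrix(x, t, degree).toarray()
    return design, t, degree


def smooth_conversion(
    empirical_ratios: list[tuple[int, float]] | np.ndarray,
    df: int | None = None,
) -> ConversionSeries:
    """Smooth empirical individuals-to-pairs ratios into (m_kt, s_kt).

    Uses a least-squares cubic B-spline fit with pointwise standard errors
    from the fit covariance.  With fewer than four points the fit falls back
    to a constant (mean ratio, standard error of the mean).
    """
    arr = np.asarray(empirical_ratios, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("empirical_ratios must be a sequence of (year, ratio) pairs")
    order = np.argsort(arr[:, 0])
    years = arr[order, 0]
    ratios = arr[order, 1]
    n = len(years)
    if n == 0:
        raise ValueError("no ratios supplied")

    if n < 4 or np.ptp(ratios) == 0:
        m = np.full(n, ratios.mean())
        se_val = ratios.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        return ConversionSeries(years=years.astype(int), m_kt=m, s_kt=np.full(n, se_val))

    if df is None:
        df = min(6, n - 1)
    X, _, _ = _bspline_design(years, df)
    coef, *_ = np.linalg.lstsq(X, ratios, rcond=None)
    fitted = X @ coef
    resid = ratios - fitted
    dof = max(n - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, xtx_inv, X) * sigma2, 0.0))
    return ConversionSeries(
        years=years.astype(int), m_kt=np.maximum(fitted, 1e-6), s_kt=se
    )
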