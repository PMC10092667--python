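"""Environmental-variation metrics over foraging buffers around colonies.

Two summary metrics per (colony, variable):

* temporal climate variation — per-pixel SD of breeding-season monthly
  values across years, averaged over pixels within foraging range;
* spatiotemporal resource variation — spatial SD, across those pixels, of
  the per-pixel temporal SDs.

Distances are great-circle (haversine, spherical Earth R = 6371 km); pixel
membership is decided by the pixel centre.  Land/missing pixels (NaN) are
excluded from both the buffer mean and the spatial SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import xarray as xr

EARTH_RADIUS_KM = 6371.0

MetricKind = Literal["temporal_climate", "spatiotemporal_resource"]


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points given in degrees."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class ColonySite:
    colony_id: str
    latitude: float
    longitude: float
    species: str = ""

    def __post_init__(self) -> None:
        if not -90 <= self.latitude <= 90:
            raise ValueError("latitude out of range")
        if not -180 <= self.longitude <= 180:
            raise ValueError("longitude out of range")


@dataclass
class EnvMetric:
    colony_id: str
    variable: str
    metric_kind: MetricKind
    value: float
    n_pixels: int


@dataclass
class EnvGrid:
    """Monthly gridded field: values shaped (time, lat, lon) with per-time
    (year, month) labels and sorted coordinate vectors."""

    variable: str
    values: np.ndarray
    year: np.ndarray
    month: np.ndarray
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.year = np.asarray(self.year, dtype=int)
        self.month = np.asarray(self.month, dtype=int)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if self.values.shape != (len(self.year), len(self.lat), len(self.lon)):
            raise ValueError("values must be shaped (time, lat, lon)")
        if len(self.year) != len(self.month):
            raise ValueError("year and month labels must align")
        if np.any(np.diff(self.lat) <= 0) or np.any(np.diff(self.lon) <= 0):
            raise ValueError("coordinate arrays must be sorted increasing")

    # -- IO -----------------------------------------------------------------

    def to_xarray(self) -> xr.DataArray:
        da = xr.DataArray(
            self.values,
            dims=("time", "lat", "lon"),
            coords={
                "time": np.arange(len(self.year)),
                "lat": self.lat,
                "lon": self.lon,
                "year": ("time", self.year),
                "month": ("time", self.month),
            },
            name=self.variable,
        )
        return da

    def to_netcdf(self, path: str | Path) -> None:
        # scipy engine -> classic NetCDF3, available without extra backends
        self.to_xarray().to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path, variable: str | None = None) -> "EnvGrid":
        ds = xr.open_dataset(path, engine="scipy")
        name = variable or list(ds.data_vars)[0]
        da = ds[name]
        return cls(
            variable=name,
            values=da.values,
            year=ds["year"].values,
            month=ds["month"].values,
            lat=ds["lat"].values,
            lon=ds["lon"].values,
        )


def monthly_aggregate(daily: xr.DataArray, variable: str | None = None) -> EnvGrid:
    """Collapse a daily (time, lat, lon) field to calendar-month means.

    ``daily`` must carry a datetime ``time`` coordinate; months are averaged
    over however many calendar days they contain (leap Februaries included).
    """
    if "time" not in daily.dims:
        raise ValueError("daily field must have a 'time' dimension")
    monthly = daily.resample(time="1MS").mean()
    if monthly.isnull().all():
        raise ValueError("no days available in any month")
    years = monthly["time"].dt.year.values
    months = monthly["time"].dt.month.values
    return EnvGrid(
        variable=variable or (daily.name or "var"),
        values=monthly.values,
        year=years,
        month=months,
        lat=daily["lat"].values,
        lon=daily["lon"].values,
    )


def pixels_in_range(grid: EnvGrid, site: ColonySite, radius_km: float) -> np.ndarray:
    """Boolean (lat, lon) mask of pixels whose centres lie within
    ``radius_km`` great-circle distance of the colony."""
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    lat2, lon2 = np.meshgrid(grid.lat, grid.lon, indexing="ij")
    dist = haversine_km(site.latitude, site.longitude, lat2, lon2)
    mask = dist <= radius_km
    if not mask.any():
        raise ValueError(
            f"no grid pixels within {radius_km} km of colony {site.colony_id!r}"
        )
    return mask


def temporal_sd_per_pixel(
    grid: EnvGrid,
    months: Sequence[int] | None = None,
    year_range: tuple[int, int] | None = None,
) -> np.ndarray:
    """Per-pixel sample SD (ddof=1) over the selected (year, month) slices.

    Pixels with fewer than two non-missing samples come back as NaN.
    """
    sel = np.ones(len(grid.year), dtype=bool)
    if months is not None:
        months = set(int(m) for m in months)
        if not months:
            raise ValueError("months must be non-empty")
        sel &= np.isin(grid.month, sorted(months))
    if year_range is not None:
        sel &= (grid.year >= year_range[0]) & (grid.year <= year_range[1])
    if sel.sum() < 2:
        raise ValueError("need at least two time slices to compute a temporal SD")
    vals = grid.values[sel]
    n_ok = np.sum(~np.isnan(vals), axis=0)
    import warnings

    with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(vals, axis=0, ddof=1)
    sd[n_ok < 2] = np.nan
    return sd


def climate_temporal_variation(
    grid: EnvGrid,
    site: ColonySite,
    radius_km: float,
    months: Sequence[int] | None = (4, 5, 6, 7),
    year_range: tuple[int, int] | None = None,
) -> EnvMetric:
    """Buffer mean of the per-pixel temporal SD field (one value per series)."""
    mask = pixels_in_range(grid, site, radius_km)
    sd = temporal_sd_per_pixel(grid, months, year_range)
    vals = sd[mask]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError(f"no usable (sea) pixels in buffer for colony {site.colony_id!r}")
    return EnvMetric(
        colony_id=site.colony_id,
        variable=grid.variable,
        metric_kind="temporal_climate",
        value=float(vals.mean()),
        n_pixels=int(len(vals)),
    )


def resource_spatiotemporal_variation(
    grid: EnvGrid,
    site: ColonySite,
    radius_km: float,
    months: Sequence[int] | None = (4, 5, 6, 7),
    year_range: tuple[int, int] | None = None,
) -> EnvMetric:
    """Spatial sample SD, across buffer pixels, of per-pixel temporal SDs."""
    mask = pixels_in_range(grid, site, radius_km)
    sd = temporal_sd_per_pixel(grid, months, year_range)
    vals = sd[mask]
    vals = vals[~np.isnan(vals)]
    if len(vals) < 2:
        raise ValueError(
            f"spatial SD undefined: fewer than two usable pixels in the buffer "
            f"for colony {site.colony_id!r}"
        )
    return EnvMetric(
        colony_id=site.colony_id,
        variable=grid.variable,
        metric_kind="spatiotemporal_resource",
        value=float(vals.std(ddof=1)),
        n_pixels=int(len(vals)),
    )


def read_colonies(path: str | Path) -> list[ColonySite]:
    df = pd.read_csv(path)
    return [
        ColonySite(
            colony_id=str(r.colony_id),
            latitude=float(r.lat),
            longitude=float(r.lon),
            species=str(getattr(r, "species", "")),
        )
        for r in df.itertuples()
    ]


def metrics_table(metrics: Sequence[EnvMetric]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "colony_id": [m.colony_id for m in metrics],
            "variable": [m.variable for m in metrics],
            "metric_kind": [m.metric_kind for m in metrics],
            "value": [m.value for m in metrics],
            "n_pixels": [m.n_pixels for m in metrics],
        }
    )
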