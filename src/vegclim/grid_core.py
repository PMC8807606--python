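"""Grid geometry, area weighting, regridding, zonal/zone aggregation and
seasonal alignment shared by every stage of the pipeline.

All gridded data live on regular latitude/longitude grids with cell-center
registration, latitude ascending and longitude in [-180, 180). Missing data
are represented as NaN; masked cells never contribute to any weighted
statistic and are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

EARTH_RADIUS_KM = 6371.0

#: integer codes of the merged climate-zone raster
ZONE_CODES = {
    0: "non-land",
    1: "Equatorial",
    2: "Arid",
    3: "Temperate",
    4: "Boreal",
    5: "Polar",
}
#: zones included in vegetation statistics (Polar and non-land excluded)
VEGETATED_ZONES = (1, 2, 3, 4)


class GridError(ValueError):
    """Invalid geometry or incompatible gridded operands."""


class EmptyDomainError(GridError):
    """A weighted statistic was requested over zero valid cells."""


def _check_regular(centers: np.ndarray, what: str) -> None:
    if centers.ndim != 1 or centers.size < 2:
        raise GridError(f"{what} must be a 1-d array with >= 2 entries")
    steps = np.diff(centers)
    if not np.all(steps > 0):
        raise GridError(f"{what} must be strictly ascending")
    if np.max(np.abs(steps - steps[0])) >= 1e-9:
        raise GridError(f"{what} spacing is not regular")


@dataclass(frozen=True)
class GridGeometry:
    """Cell-center registered regular lat/lon grid."""

    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lat", np.asarray(self.lat, dtype=float))
        object.__setattr__(self, "lon", np.asarray(self.lon, dtype=float))
        _check_regular(self.lat, "lat")
        _check_regular(self.lon, "lon")
        if np.any(np.abs(self.lat) > 90.0):
            raise GridError("latitudes must lie in [-90, 90]")
        if self.lon[0] < -180.0 or self.lon[-1] >= 360.0:
            raise GridError("longitudes must lie in [-180, 360)")

    @property
    def nlat(self) -> int:
        return self.lat.size

    @property
    def nlon(self) -> int:
        return self.lon.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def ncell(self) -> int:
        return self.nlat * self.nlon

    def dlat(self) -> float:
        return float(self.lat[1] - self.lat[0])

    def dlon(self) -> float:
        return float(self.lon[1] - self.lon[0])

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """2-d (lat, lon) coordinate arrays of shape ``self.shape``."""
        return np.meshgrid(self.lat, self.lon, indexing="ij")

    def flat_coords(self) -> tuple[np.ndarray, np.ndarray]:
        la, lo = self.mesh()
        return la.ravel(), lo.ravel()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridGeometry):
            return NotImplemented
        return np.array_equal(self.lat, other.lat) and np.array_equal(
            self.lon, other.lon
        )


@dataclass
class GridField:
    """A physical variable on a grid with a monthly time axis.

    ``time`` is an integer array of shape (nt, 2) holding (year, month)
    stamps; ``values`` has shape (nt, nlat, nlon) with NaN marking missing
    cells.
    """

    geometry: GridGeometry
    time: np.ndarray
    values: np.ndarray
    units: str
    name: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=int)
        self.values = np.asarray(self.values)
        if self.time.ndim != 2 or self.time.shape[1] != 2:
            raise GridError("time must have shape (nt, 2) of (year, month)")
        if self.values.shape != (self.time.shape[0], *self.geometry.shape):
            raise GridError(
                f"values shape {self.values.shape} does not match time/geometry"
            )
        if not self.units:
            raise GridError(f"field {self.name!r} needs non-empty units")
        months = self.time[:, 1]
        if np.any((months < 1) | (months > 12)):
            raise GridError("months must lie in 1..12")

    @property
    def nt(self) -> int:
        return self.time.shape[0]

    def time_index(self, year: int, month: int) -> int:
        hit = np.flatnonzero((self.time[:, 0] == year) & (self.time[:, 1] == month))
        if hit.size != 1:
            raise KeyError(f"no unique time step for {year}-{month:02d}")
        return int(hit[0])

    def sel(self, year: int, month: int) -> np.ndarray:
        """2-d slice for one (year, month)."""
        return self.values[self.time_index(year, month)]

    def years(self) -> np.ndarray:
        return np.unique(self.time[:, 0])


@dataclass(frozen=True)
class AreaWeights:
    """Per-cell weights proportional to cos(latitude); normalization is
    deferred to the consuming statistic."""

    geometry: GridGeometry
    w: np.ndarray


@dataclass(frozen=True)
class ClimateZoneMap:
    """Categorical zone raster (codes per :data:`ZONE_CODES`), constant in
    time even when aggregating future periods."""

    geometry: GridGeometry
    zone: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "zone", np.asarray(self.zone, dtype=int))
        if self.zone.shape != self.geometry.shape:
            raise GridError("zone raster shape does not match geometry")
        bad = set(np.unique(self.zone)) - set(ZONE_CODES)
        if bad:
            raise GridError(f"unknown zone codes {sorted(bad)}")

    def mask(self, code: int) -> np.ndarray:
        return self.zone == code


# ---------------------------------------------------------------------------
# operations


def cell_area_weights(geometry: GridGeometry) -> AreaWeights:
    """Relative cell areas on a regular grid: w(lat) = cos(lat)."""
    if np.any(np.abs(geometry.lat) > 90.0):
        raise GridError("invalid geometry: |lat| > 90")
    w1d = np.cos(np.deg2rad(geometry.lat))
    w1d = np.clip(w1d, 0.0, None)  # cos(90) may round slightly negative
    w = np.broadcast_to(w1d[:, None], geometry.shape).copy()
    return AreaWeights(geometry=geometry, w=w)


def area_weighted_mean(
    values: np.ndarray, weights: AreaWeights, mask: np.ndarray | None = None
) -> float:
    """Area-weighted mean of one 2-d slice over valid (and masked-in) cells."""
    values = np.asarray(values, dtype=float)
    if values.shape != weights.geometry.shape:
        raise GridError("field slice and weights are not co-registered")
    valid = np.isfinite(values)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    wsum = float(np.sum(weights.w[valid]))
    if not np.any(valid) or wsum <= 0.0:
        raise EmptyDomainError("no valid cells under the requested mask")
    return float(np.sum(values[valid] * weights.w[valid]) / wsum)


def zonal_mean(values: np.ndarray, weights: AreaWeights) -> np.ndarray:
    """Per-latitude-row weighted mean of a 2-d slice; empty rows are NaN."""
    values = np.asarray(values, dtype=float)
    if values.shape != weights.geometry.shape:
        raise GridError("field slice and weights are not co-registered")
    valid = np.isfinite(values)
    w = np.where(valid, weights.w, 0.0)
    num = np.sum(np.where(valid, values, 0.0) * w, axis=1)
    den = np.sum(w, axis=1)
    out = np.full(weights.geometry.nlat, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def regrid_bilinear(fld: GridField, target: GridGeometry) -> GridField:
    """Bilinear interpolation of every time slice onto ``target`` centers.

    Target points outside the source hull come back missing; fully disjoint
    domains raise. NaN sources propagate to any target cell whose bilinear
    stencil touches them.
    """
    src = fld.geometry
    if (
        target.lat[0] > src.lat[-1]
        or target.lat[-1] < src.lat[0]
        or target.lon[0] > src.lon[-1]
        or target.lon[-1] < src.lon[0]
    ):
        raise GridError("target domain is disjoint from source domain")
    tl, tn = np.meshgrid(target.lat, target.lon, indexing="ij")
    pts = np.column_stack([tl.ravel(), tn.ravel()])
    out = np.empty((fld.nt, *target.shape))
    for it in range(fld.nt):
        interp = RegularGridInterpolator(
            (src.lat, src.lon),
            np.asarray(fld.values[it], dtype=float),
            method="linear",
            bounds_error=False,
            fill_value=np.nan,
        )
        out[it] = interp(pts).reshape(target.shape)
    return GridField(
        geometry=target, time=fld.time.copy(), values=out, units=fld.units,
        name=fld.name,
    )


def hemisphere_align_seasons(cycle, latitude_sign: str) -> np.ndarray:
    """Rotate a southern-hemisphere 12-month cycle by 6 months so its
    seasonality matches the northern solar cycle; north is the identity."""
    cycle = np.asarray(cycle, dtype=float)
    if cycle.shape != (12,):
        raise ValueError("monthly cycle must have exactly 12 entries")
    if latitude_sign == "north":
        return cycle.copy()
    if latitude_sign == "south":
        return np.roll(cycle, 6)
    raise ValueError(f"latitude_sign must be 'north' or 'south', got {latitude_sign!r}")


def great_circle_distance_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Haversine distance on a 6371 km sphere; accepts scalars or arrays."""
    la1, lo1, la2, lo2 = (np.deg2rad(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = la2 - la1
    dlon = lo2 - lo1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


# ---------------------------------------------------------------------------
# NetCDF I/O (scipy / NetCDF3 backend so no binary deps are required)


def _to_datetimes(time: np.ndarray) -> pd.DatetimeIndex:
    return pd.to_datetime(
        [f"{y:04d}-{m:02d}-15" for y, m in np.asarray(time, dtype=int)]
    )


def write_fields(path, fields: dict[str, GridField]) -> None:
    """Write co-registered fields to one NetCDF file (classic format)."""
    first = next(iter(fields.values()))
    geo = first.geometry
    data_vars = {}
    for key, f in fields.items():
        if f.geometry != geo or not np.array_equal(f.time, first.time):
            raise GridError("all fields in one file must share geometry and time")
        data_vars[key] = xr.DataArray(
            np.asarray(f.values, dtype="float64"),
            dims=("time", "lat", "lon"),
            attrs={"units": f.units, "long_name": f.name or key},
        )
    ds = xr.Dataset(
        data_vars,
        coords={
            "time": _to_datetimes(first.time),
            "lat": ("lat", geo.lat, {"units": "degrees_north"}),
            "lon": ("lon", geo.lon, {"units": "degrees_east"}),
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_fields(path) -> dict[str, GridField]:
    """Read every (time, lat, lon) variable of a NetCDF file as GridFields.

    Latitude is sorted ascending and longitude normalized to [-180, 180) on
    ingest.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    if ds["lat"].values[0] > ds["lat"].values[-1]:
        ds = ds.isel(lat=slice(None, None, -1))
    lon = ds["lon"].values
    if lon.max() >= 180.0:
        ds = ds.assign_coords(lon=(((lon + 180.0) % 360.0) - 180.0)).sortby("lon")
    geo = GridGeometry(lat=ds["lat"].values, lon=ds["lon"].values)
    t = pd.DatetimeIndex(ds["time"].values)
    time = np.column_stack([t.year, t.month])
    out = {}
    for key, da in ds.data_vars.items():
        if da.dims != ("time", "lat", "lon"):
            continue
        out[key] = GridField(
            geometry=geo,
            time=time,
            values=np.asarray(da.values, dtype=float),
            units=str(da.attrs.get("units", "")) or "1",
            name=str(da.attrs.get("long_name", key)),
        )
    return out


def write_zone_map(path, zones: ClimateZoneMap) -> None:
    ds = xr.Dataset(
        {
            "zone": xr.DataArray(
                zones.zone.astype("int32"),
                dims=("lat", "lon"),
                attrs={
                    "units": "1",
                    "long_name": "climate zone code",
                    "zone_codes": ";".join(f"{k}={v}" for k, v in ZONE_CODES.items()),
                },
            )
        },
        coords={
            "lat": ("lat", zones.geometry.lat, {"units": "degrees_north"}),
            "lon": ("lon", zones.geometry.lon, {"units": "degrees_east"}),
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_zone_map(path) -> ClimateZoneMap:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    geo = GridGeometry(lat=ds["lat"].values, lon=ds["lon"].values)
    return ClimateZoneMap(geometry=geo, zone=np.asarray(ds["zone"].values, dtype=int))
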