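"""Global 1°×1° grid handling for monthly ocean climatologies.

The whole pipeline operates on a fixed cell-centre-registered 1°×1°
latitude/longitude grid (180×360 cells, latitudes −89.5…89.5°N, longitudes
−179.5…179.5°E) with twelve climatological calendar months.  Native-resolution
inputs (e.g. 2.5° reanalysis winds) are refined to this grid by bilinear
interpolation.  Missing data (land, unobserved cells) are carried as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import xarray as xr

EARTH_RADIUS_M = 6.371e6  # spherical Earth, standard climatological value

N_MONTHS = 12
MONTH_NAMES = (
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
)


class CoordinateOrderError(ValueError):
    """Source grid coordinates are not strictly monotone."""


class EmptyRegionError(ValueError):
    """A region/month selection contains no valid ocean cells."""


class RegistrationError(ValueError):
    """Fields that must share a grid have mismatching shapes or axes."""


def _as_lon180(lon: np.ndarray) -> np.ndarray:
    """Map longitudes to the (−180, 180] convention."""
    lon = np.asarray(lon, dtype=float)
    return np.where(lon > 180.0, lon - 360.0, lon)


@dataclass(frozen=True)
class GlobalGrid:
    """Cell-centre-registered global 1°×1° grid with ocean mask.

    Attributes
    ----------
    lat_centers, lon_centers:
        Cell-centre coordinates in degrees north / degrees east.
    ocean_mask:
        Boolean (lat, lon) array, True over ocean.
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    ocean_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.ocean_mask.shape != (self.lat_centers.size, self.lon_centers.size):
            raise RegistrationError(
                f"ocean_mask shape {self.ocean_mask.shape} does not match "
                f"({self.lat_centers.size}, {self.lon_centers.size}) coordinates"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat_centers.size, self.lon_centers.size)

    @property
    def cell_area(self) -> np.ndarray:
        """Per-cell area in m², broadcast to the full (lat, lon) shape."""
        return cell_areas(self)

    def ocean_area(self) -> float:
        """Total ocean surface area in m²."""
        return float(self.cell_area[self.ocean_mask].sum())


def default_grid(ocean_mask: np.ndarray | None = None) -> GlobalGrid:
    """The standard 1°×1° grid; all-ocean if no mask is supplied."""
    lat = np.arange(-89.5, 90.0, 1.0)
    lon = np.arange(-179.5, 180.0, 1.0)
    if ocean_mask is None:
        ocean_mask = np.ones((lat.size, lon.size), dtype=bool)
    return GlobalGrid(lat, lon, np.asarray(ocean_mask, dtype=bool))


def cell_areas(grid: GlobalGrid) -> np.ndarray:
    """Cell areas A(lat) = R²·Δφ·Δλ·cos(lat) in m² on the 1°×1° grid."""
    dphi = np.deg2rad(1.0)
    area_lat = EARTH_RADIUS_M**2 * dphi * dphi * np.cos(np.deg2rad(grid.lat_centers))
    return np.broadcast_to(area_lat[:, None], grid.shape).copy()


@dataclass
class MonthlyField:
    """A named monthly gridded quantity with units.

    ``values`` has shape (12, nlat, nlon); missing cells are NaN.  The field
    carries its own coordinate axes so it can live on a native resolution
    before regridding.
    """

    name: str
    units: str
    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if not self.units:
            raise ValueError("MonthlyField.units must be a non-empty string")
        if self.values.ndim != 3 or self.values.shape[0] != N_MONTHS:
            raise ValueError(
                f"values must be (12, nlat, nlon), got {self.values.shape}"
            )
        if self.values.shape[1:] != (self.lat.size, self.lon.size):
            raise RegistrationError(
                f"values shape {self.values.shape[1:]} does not match coordinate "
                f"sizes ({self.lat.size}, {self.lon.size})"
            )

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def on_grid(self, grid: GlobalGrid) -> bool:
        return (
            self.values.shape[1:] == grid.shape
            and np.allclose(self.lat, grid.lat_centers)
            and np.allclose(self.lon, grid.lon_centers)
        )

    def with_values(self, values: np.ndarray, name: str | None = None,
                    units: str | None = None) -> "MonthlyField":
        return replace(
            self,
            values=values,
            name=self.name if name is None else name,
            units=self.units if units is None else units,
        )

    def to_dataarray(self) -> xr.DataArray:
        return xr.DataArray(
            self.values,
            dims=("month", "lat", "lon"),
            coords={
                "month": np.arange(1, N_MONTHS + 1),
                "lat": self.lat,
                "lon": self.lon,
            },
            name=self.name,
            attrs={"units": self.units},
        )

    @classmethod
    def from_dataarray(cls, da: xr.DataArray, units: str | None = None) -> "MonthlyField":
        units = units or str(da.attrs.get("units", ""))
        return cls(
            name=str(da.name or "field"),
            units=units,
            values=np.asarray(da.values, dtype=float),
            lat=np.asarray(da["lat"].values, dtype=float),
            lon=np.asarray(da["lon"].values, dtype=float),
        )


def field_on_grid(name: str, units: str, values: np.ndarray, grid: GlobalGrid) -> MonthlyField:
    return MonthlyField(name, units, values, grid.lat_centers, grid.lon_centers)


def _check_monotone(coord: np.ndarray, label: str) -> int:
    """Return +1 for ascending, −1 for descending, raise otherwise."""
    d = np.diff(coord)
    if np.all(d > 0):
        return 1
    if np.all(d < 0):
        return -1
    raise CoordinateOrderError(f"{label} coordinate is not strictly monotone")


def _interp_weights(src: np.ndarray, tgt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices i and weights w for 1-D linear interpolation: f(tgt) ≈
    (1−w)·f[i] + w·f[i+1], with edge clamping (constant extrapolation)."""
    i = np.searchsorted(src, tgt) - 1
    i = np.clip(i, 0, src.size - 2)
    w = (tgt - src[i]) / (src[i + 1] - src[i])
    return i, np.clip(w, 0.0, 1.0)


def regrid_linear(field: MonthlyField, target: GlobalGrid) -> MonthlyField:
    """Bilinear regrid of a native-resolution field onto the target grid.

    Missing cells get any-valid-neighbour weighting: the bilinear weights are
    renormalised over the valid stencil corners, so coastal cells survive as
    long as at least one corner carries data.  Cells whose whole stencil is
    missing stay missing.  Raises :class:`CoordinateOrderError` for
    non-monotone source axes.
    """
    lat_dir = _check_monotone(field.lat, "latitude")
    lon_src = _as_lon180(field.lon)
    vals = field.values
    if lat_dir < 0:
        vals = vals[:, ::-1, :]
    lat_src = field.lat[::lat_dir]
    # rotate longitudes into ascending −180…180 order
    lon_order = np.argsort(lon_src)
    lon_src = lon_src[lon_order]
    _check_monotone(lon_src, "longitude")
    vals = vals[:, :, lon_order]

    ilat, wlat = _interp_weights(lat_src, target.lat_centers)
    ilon, wlon = _interp_weights(lon_src, target.lon_centers)

    valid = np.isfinite(vals)
    filled = np.where(valid, vals, 0.0)

    def corner(dy: int, dx: int) -> tuple[np.ndarray, np.ndarray]:
        v = filled[:, ilat + dy][:, :, ilon + dx]
        m = valid[:, ilat + dy][:, :, ilon + dx]
        return v, m

    wy = [(1.0 - wlat), wlat]
    wx = [(1.0 - wlon), wlon]
    num = np.zeros((N_MONTHS, target.shape[0], target.shape[1]))
    den = np.zeros_like(num)
    for dy in (0, 1):
        for dx in (0, 1):
            w = wy[dy][None, :, None] * wx[dx][None, None, :]
            v, m = corner(dy, dx)
            num += w * m * v
            den += w * m
    out = np.full_like(num, np.nan)
    np.divide(num, den, out=out, where=den > 0)
    return MonthlyField(field.name, field.units, out, target.lat_centers,
                        target.lon_centers)


def _month_index(months: Sequence[int] | None) -> np.ndarray:
    if months is None:
        return np.arange(N_MONTHS)
    idx = np.asarray(sorted(set(int(m) for m in months))) - 1
    if idx.size == 0 or idx.min() < 0 or idx.max() >= N_MONTHS:
        raise ValueError(f"months must be within 1–12, got {months}")
    return idx


def extract_region(
    field: MonthlyField,
    grid: GlobalGrid,
    lat_range: tuple[float, float],
    lon_range: tuple[float, float],
    months: Sequence[int] | None = None,
    area_weighted: bool = True,
) -> float:
    """Mean of a field over a lat/lon box, selected months and ocean cells.

    Area weighting (cos-latitude) is the default; pass
    ``area_weighted=False`` for a plain cell average.  Raises
    :class:`EmptyRegionError` if no valid cell falls in the selection.
    """
    if not field.on_grid(grid):
        raise RegistrationError("field is not registered on the supplied grid")
    la0, la1 = sorted(lat_range)
    lo0, lo1 = sorted(lon_range)
    lat_sel = (grid.lat_centers >= la0) & (grid.lat_centers <= la1)
    lon_sel = (grid.lon_centers >= lo0) & (grid.lon_centers <= lo1)
    midx = _month_index(months)

    box = np.outer(lat_sel, lon_sel) & grid.ocean_mask
    vals = field.values[midx][:, box]
    good = np.isfinite(vals)
    if not good.any():
        raise EmptyRegionError(
            f"no valid ocean cells in lat {lat_range}, lon {lon_range}, "
            f"months {list(midx + 1)}"
        )
    if area_weighted:
        w = np.broadcast_to(grid.cell_area[box], vals.shape)
        w = np.where(good, w, 0.0)
        return float((vals * w)[good].sum() / w.sum())
    return float(vals[good].mean())


def write_netcdf(field: MonthlyField, path) -> None:
    """Write a MonthlyField as a CF-style NetCDF file (classic format)."""
    ds = field.to_dataarray().to_dataset()
    ds["lat"].attrs["units"] = "degrees_north"
    ds["lon"].attrs["units"] = "degrees_east"
    ds.to_netcdf(path, engine="scipy")


def read_netcdf(path, varname: str) -> MonthlyField:
    """Read a MonthlyField written by :func:`write_netcdf` (or compatible)."""
    with xr.open_dataset(path, engine="scipy") as ds:
        if varname not in ds:
            raise KeyError(
                f"variable {varname!r} not found in {path}; "
                f"available: {list(ds.data_vars)}"
            )
        da = ds[varname].load()
    return MonthlyField.from_dataarray(da)
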