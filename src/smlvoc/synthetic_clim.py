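"""Seeded synthetic monthly climatologies for the full pipeline.

Physically plausible stand-ins for the gridded inputs (UV irradiance, 10-m
wind, net primary production, MBL height, POA background) so every stage
runs without downloads.  The generators emulate the gross structure of the
real fields — zonal gradients, seasonal cycles phase-shifted between
hemispheres, storm belts crossing the SML wind limits, trophic area
fractions — not their detailed statistics.  All generators are pure
functions of the configuration (including its seed): identical inputs give
bit-identical fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import (
    GlobalGrid,
    MonthlyField,
    default_grid,
    field_on_grid,
    read_netcdf,
    regrid_linear,
    write_netcdf,
)
from .photo_potential import day_length

#: accepted unit spellings per canonical unit string
_UNIT_ALIASES = {
    "mW cm-2": {"mw cm-2", "mw/cm2", "mw cm^-2"},
    "m s-1": {"m s-1", "m/s", "m s^-1"},
    "g C m-2 day-1": {"g c m-2 day-1", "g c/m2/day", "g c m^-2 day^-1"},
}


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults sketch a realistic modern-ocean state."""

    seed: int = 0
    uv_peak: float = 4.5                 # mW cm⁻², equatorial monthly mean
    wind_belt_amplitude: float = 15.0    # m s⁻¹, peak of the westerly belts
    npp_coastal_boost: float = 1.5       # g C m⁻² day⁻¹ added near coasts
    trophic_fractions: tuple = (0.6, 0.3, 0.1)   # oligo / meso / eutrophic
    mbl_height_mean: float = 800.0       # m
    poa_background: float = 0.4          # µg m⁻³, remote marine air

    def __post_init__(self) -> None:
        if abs(sum(self.trophic_fractions) - 1.0) > 1.0e-9:
            raise ValueError("trophic_fractions must sum to 1")
        if any(f < 0 for f in self.trophic_fractions):
            raise ValueError("trophic_fractions must be non-negative")


def _rng_named(cfg: SynthConfig, offset: int) -> np.random.Generator:
    # one documented RNG per generated field: seed sequence (seed, offset)
    return np.random.default_rng([int(cfg.seed), offset])


def make_ocean_mask(grid_shape: tuple[int, int] = (180, 360)) -> np.ndarray:
    """Latitude-banded pseudo-continents giving ≈70% ocean.

    Deterministic rectangles loosely mimicking the real land distribution;
    no shoreline realism intended, just non-trivial masking.
    """
    lat = np.arange(-89.5, 90.0, 1.0)
    lon = np.arange(-179.5, 180.0, 1.0)
    LO, LA = np.meshgrid(lon, lat)
    land = np.zeros(grid_shape, dtype=bool)
    boxes = [
        (-120, -65, 20, 68),     # north-america-like
        (-78, -40, -52, 8),      # south-america-like
        (-12, 45, -32, 33),      # africa-like
        (5, 130, 42, 70),        # eurasia-like
        (68, 115, 10, 35),       # south-asia-like
        (114, 152, -36, -14),    # australia-like
        (-50, -25, 62, 80),      # greenland-like
    ]
    for lo0, lo1, la0, la1 in boxes:
        land |= (LO >= lo0) & (LO <= lo1) & (LA >= la0) & (LA <= la1)
    land |= LA <= -71.0          # antarctica-like cap
    return ~land


def make_grid() -> GlobalGrid:
    """The standard 1°×1° grid with the synthetic ocean mask."""
    return default_grid(make_ocean_mask())


def _seasonal_phase(month_idx: np.ndarray) -> np.ndarray:
    """cos term peaking at the June solstice (month index 5.5 of 0–11)."""
    return np.cos(2.0 * np.pi * (month_idx - 5.5) / 12.0)


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma_cells: int = 6) -> np.ndarray:
    """Zonally periodic smoothed white noise in [−1, 1]-ish range."""
    from scipy.ndimage import gaussian_filter

    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, sigma=sigma_cells, mode=("nearest", "wrap"))
    return sm / max(np.abs(sm).max(), 1.0e-12)


def make_uv(cfg: SynthConfig, grid: GlobalGrid | None = None) -> MonthlyField:
    """Monthly-mean surface UV-a+UV-b irradiance (mW cm⁻²).

    Zonally smooth, peaking under the seasonally migrating sub-solar
    latitude, and exactly zero in polar-night cells.
    """
    grid = grid or make_grid()
    lat = grid.lat_centers
    months = np.arange(12)
    decl = 23.44 * np.sin(2.0 * np.pi * (284 + np.asarray(
        [15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])) / 365.0)
    vals = np.empty((12,) + grid.shape)
    rng = _rng_named(cfg, 1)
    noise = 0.05 * _smooth_noise(rng, grid.shape)
    for m in months:
        # irradiance falls off with the cosine of the sub-solar zenith angle
        mu = np.cos(np.deg2rad(lat - decl[m]))
        prof = cfg.uv_peak * np.clip(mu, 0.0, None) ** 1.5
        tsun = day_length(lat, int(m) + 1)
        prof = np.where(tsun > 0.0, prof, 0.0)
        vals[m] = np.clip(prof[:, None] * (1.0 + noise), 0.0, None)
    vals[:, ~grid.ocean_mask] = np.nan
    return field_on_grid("uv_ab", "mW cm-2", vals, grid)


def make_wind(cfg: SynthConfig, grid: GlobalGrid | None = None) -> MonthlyField:
    """Monthly-mean 10-m wind speed (m s⁻¹).

    Westerly storm belts near ±50° reach ``wind_belt_amplitude`` (above the
    13 m s⁻¹ SML limit so all three masks differ), trades near ±15°,
    doldrums at the equator; winter hemisphere belts are stronger.
    """
    grid = grid or make_grid()
    lat = grid.lat_centers
    vals = np.empty((12,) + grid.shape)
    rng = _rng_named(cfg, 2)
    noise = 1.0 * _smooth_noise(rng, grid.shape)
    for m in range(12):
        phase = _seasonal_phase(np.asarray(float(m)))
        belts = cfg.wind_belt_amplitude * (
            np.exp(-((lat - 50.0) / 12.0) ** 2) * (1.0 - 0.25 * phase * np.sign(lat - 0))
            + np.exp(-((lat + 50.0) / 12.0) ** 2) * (1.0 + 0.25 * phase)
        )
        trades = 6.5 * (np.exp(-((lat - 15.0) / 10.0) ** 2)
                        + np.exp(-((lat + 15.0) / 10.0) ** 2))
        doldrums = 2.0 * np.exp(-((lat / 6.0) ** 2))
        prof = np.maximum.reduce([belts, trades, doldrums, np.full_like(lat, 3.0)])
        vals[m] = np.clip(prof[:, None] + noise, 0.0, None)
    vals[:, ~grid.ocean_mask] = np.nan
    return field_on_grid("u10", "m s-1", vals, grid)


def _weighted_quantile_thresholds(
    latent: np.ndarray, weights: np.ndarray, fractions: tuple
) -> tuple[float, float]:
    """Latent-value cuts putting the target area fractions below them."""
    order = np.argsort(latent)
    cw = np.cumsum(weights[order])
    cw /= cw[-1]
    f_oligo, f_meso, _ = fractions
    def cut(f: float) -> float:
        if f <= 0.0:
            return -np.inf
        if f >= 1.0:
            return np.inf
        i = int(np.searchsorted(cw, f))
        return float(latent[order][min(i, latent.size - 1)])
    return cut(f_oligo), cut(f_oligo + f_meso)


def make_npp(cfg: SynthConfig, grid: GlobalGrid | None = None) -> MonthlyField:
    """Monthly NPP (g C m⁻² day⁻¹) with calibrated trophic area fractions.

    A smooth latent productivity field (higher near coasts and high
    latitudes, plus seeded noise) is cut at area-weighted quantiles so the
    classified oligo/meso/eutrophic fractions match
    ``cfg.trophic_fractions``; cells then get NPP values inside their
    class's range.  Checked to within 5 percentage points by construction.
    """
    grid = grid or make_grid()
    rng = _rng_named(cfg, 3)
    lat = grid.lat_centers

    # coast proximity: cells within a few cells of land are more productive
    from scipy.ndimage import binary_dilation

    land = ~grid.ocean_mask
    near_coast = binary_dilation(land, iterations=4) & grid.ocean_mask
    vals = np.empty((12,) + grid.shape)
    area = grid.cell_area
    noise = _smooth_noise(rng, grid.shape, sigma_cells=8)
    for m in range(12):
        bloom = 0.6 * _seasonal_phase(np.asarray(float(m))) * np.sign(lat + 1e-9)
        latent = (
            0.8 * np.abs(lat[:, None]) / 90.0
            + bloom[:, None]
            + 1.2 * near_coast.astype(float) * (cfg.npp_coastal_boost / 1.5)
            + 1.5 * noise
        )
        ocean_latent = latent[grid.ocean_mask]
        t1, t2 = _weighted_quantile_thresholds(
            ocean_latent, area[grid.ocean_mask], cfg.trophic_fractions
        )
        npp = np.full(grid.shape, np.nan)
        oligo = grid.ocean_mask & (latent < t1)
        eu = grid.ocean_mask & (latent >= t2)
        meso = grid.ocean_mask & ~oligo & ~eu
        u = rng.random(grid.shape)
        npp[oligo] = 0.05 + 0.34 * u[oligo]           # < 0.4
        npp[meso] = 0.41 + 0.78 * u[meso]             # 0.4–1.2
        npp[eu] = 1.21 + 1.8 * u[eu]                  # > 1.2
        vals[m] = npp
    return field_on_grid("npp", "g C m-2 day-1", vals, grid)


def make_mbl_height(cfg: SynthConfig, grid: GlobalGrid | None = None) -> MonthlyField:
    """Monthly MBL height (m): deeper in the trades, shallower poleward."""
    grid = grid or make_grid()
    lat = grid.lat_centers
    rng = _rng_named(cfg, 4)
    noise = 60.0 * _smooth_noise(rng, grid.shape)
    prof = cfg.mbl_height_mean * (0.75 + 0.5 * np.exp(-((np.abs(lat) - 20.0) / 25.0) ** 2))
    vals = np.repeat((prof[:, None] + noise)[None], 12, axis=0)
    vals = np.clip(vals, 200.0, None)
    vals[:, ~grid.ocean_mask] = np.nan
    return field_on_grid("mbl_height", "m", vals, grid)


def make_poa(cfg: SynthConfig, grid: GlobalGrid | None = None) -> MonthlyField:
    """Constant remote-marine POA background (µg m⁻³) over ocean."""
    grid = grid or make_grid()
    vals = np.full((12,) + grid.shape, float(cfg.poa_background))
    vals[:, ~grid.ocean_mask] = np.nan
    return field_on_grid("poa", "ug m-3", vals, grid)


def read_monthly_netcdf(
    path,
    varname: str,
    units_expected: str,
    grid: GlobalGrid | None = None,
) -> MonthlyField:
    """Read a monthly field from NetCDF, check units, regrid to 1°×1°.

    The variable's ``units`` attribute must match ``units_expected`` up to
    case/spelling aliases; a mismatch raises ``ValueError`` rather than
    silently mis-scaling.  Fields on coarser rectilinear grids are refined
    by bilinear interpolation.
    """
    field = read_netcdf(path, varname)
    want = units_expected.strip()
    got = field.units.strip()
    aliases = _UNIT_ALIASES.get(want, set()) | {want.lower()}
    if got.lower() not in aliases:
        raise ValueError(
            f"{path}:{varname} has units {got!r}, expected {want!r}"
        )
    grid = grid or make_grid()
    if field.on_grid(grid):
        return field
    out = regrid_linear(field, grid)
    out.values[:, ~grid.ocean_mask] = np.nan
    return out


def write_fixture_set(cfg: SynthConfig, outdir) -> dict[str, str]:
    """Generate and write the complete synthetic input set as NetCDF."""
    import os

    grid = make_grid()
    fields = {
        "uv": make_uv(cfg, grid),
        "wind": make_wind(cfg, grid),
        "npp": make_npp(cfg, grid),
        "mbl_height": make_mbl_height(cfg, grid),
        "poa": make_poa(cfg, grid),
    }
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for key, f in fields.items():
        p = os.path.join(outdir, f"{key}.nc")
        write_netcdf(f, p)
        paths[key] = p
    return paths
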