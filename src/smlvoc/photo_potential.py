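"""Daily photochemical VOC emission potential of the ocean surface.

The potential µ_photo (mW s cm⁻² day⁻¹) for each cell and calendar month is
the product of four factors:

    µ_photo = t_sun · UV_ab · F_surfactant · k_g

* ``t_sun`` — day length in seconds from standard solar-declination
  geometry at mid-month;
* ``UV_ab`` — surface UV-a + UV-b irradiance (280–400 nm, mW cm⁻²);
* ``F_surfactant = ln(c)/ln(c_max)`` — logarithmic scaling of photochemical
  production with surfactant concentration, normalised to the highest
  (eutrophic) concentration so it lies in (0, 1];
* ``k_g = (8.2 + 0.014·U₁₀³)/(8.2 + 0.014·U_lab³)`` — a cubic wind-speed
  parameterisation of air–sea gas transfer, normalised to the laboratory
  flow speed, predicting non-zero transfer at zero wind.

Cells whose wind exceeds the SML limit carry no microlayer and contribute
exactly zero.  The multiplication by t_sun can be switched off when the UV
input is already a daily dose, to avoid double counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import MonthlyField, RegistrationError
from .sml_coverage import (
    classify_trophic,
    sml_mask,
    surfactant_concentration,
)

#: mid-month day-of-year per calendar month (365-day climatological calendar)
MID_MONTH_DOY = (15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349)

#: season labels and their month numbers used for seasonal aggregation
SEASONS = {
    "Jan-Mar": (1, 2, 3),
    "Apr-Jun": (4, 5, 6),
    "Jul-Sep": (7, 8, 9),
    "Oct-Dec": (10, 11, 12),
}


@dataclass(frozen=True)
class PhotochemConfig:
    """Constants of the emission-potential model.

    ``u_lab`` is the laboratory sample flow speed (200 mL min⁻¹ scaled to
    10 m height assuming a log wind profile).  ``a_kg``/``b_kg`` are the
    coefficients of the cubic gas-transfer parameterisation.
    """

    wind_limit: float = 13.0            # m s⁻¹, SML formation limit
    c_max_surfactant: float = 663.0     # µg Teq L⁻¹, eutrophic mean
    u_lab: float = 5.31e-2              # m s⁻¹
    a_kg: float = 8.2
    b_kg: float = 0.014
    multiply_t_sun: bool = True

    def __post_init__(self) -> None:
        if self.c_max_surfactant <= 1:
            raise ValueError("c_max_surfactant must exceed 1 µg Teq L⁻¹")
        if self.u_lab <= 0:
            raise ValueError("u_lab must be positive")


@dataclass
class PotentialField:
    """µ_photo (mW s cm⁻² day⁻¹) per month/cell, with the config that made it."""

    values: np.ndarray                  # (12, nlat, nlon); NaN over land
    lat: np.ndarray
    lon: np.ndarray
    config: PhotochemConfig

    def as_field(self) -> MonthlyField:
        return MonthlyField("mu_photo", "mW s cm-2 day-1", self.values,
                            self.lat, self.lon)


def f_surfactant(c, c_max: float = 663.0):
    """Surfactant scaling factor ln(c)/ln(c_max) ∈ (0, 1].

    Valid for 1 < c ≤ c_max; values outside raise a domain error (the
    logarithmic fit is only anchored within the observed concentration
    range).  NaN inputs propagate (missing cells).
    """
    c = np.asarray(c, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (c <= 1.0) | (c > c_max)
    if bool(np.any(bad & np.isfinite(c))):
        raise ValueError(
            f"surfactant concentration outside (1, {c_max}] µg Teq L⁻¹"
        )
    out = np.log(c) / np.log(c_max)
    return float(out) if out.ndim == 0 else out


def k_g(u10, cfg: PhotochemConfig = PhotochemConfig()):
    """Wind-speed gas-transfer factor, normalised to laboratory conditions."""
    u10 = np.asarray(u10, dtype=float)
    if np.nanmin(u10) < 0:
        raise ValueError("wind speed must be non-negative")
    out = (cfg.a_kg + cfg.b_kg * u10**3) / (cfg.a_kg + cfg.b_kg * cfg.u_lab**3)
    return float(out) if out.ndim == 0 else out


def day_length(lat, month: int) -> np.ndarray | float:
    """Daylight duration in seconds at mid-month.

    Solar declination δ = 23.44°·sin(2π(284+n)/365) with n the mid-month
    day of year; the sunset hour angle cos ω₀ = −tan φ · tan δ is clamped
    to [−1, 1] for polar day (86400 s) and polar night (0 s).
    """
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month must be 1–12, got {month}")
    lat = np.asarray(lat, dtype=float)
    n = MID_MONTH_DOY[int(month) - 1]
    decl = np.deg2rad(23.44) * np.sin(2.0 * np.pi * (284 + n) / 365.0)
    cos_w0 = -np.tan(np.deg2rad(lat)) * np.tan(decl)
    w0 = np.arccos(np.clip(cos_w0, -1.0, 1.0))
    out = 86400.0 * w0 / np.pi
    return float(out) if out.ndim == 0 else out


def mu_photo(t_sun, uv, f_surf, kg, covered):
    """Combine the four factors; exactly zero where the surface is uncovered."""
    t_sun, uv, f_surf, kg = (np.asarray(a, dtype=float) for a in (t_sun, uv, f_surf, kg))
    prod = t_sun * uv * f_surf * kg
    out = np.where(np.asarray(covered, dtype=bool), prod, 0.0)
    return float(out) if out.ndim == 0 else out


def potential_field(
    uv: MonthlyField,
    wind: MonthlyField,
    npp: MonthlyField,
    cfg: PhotochemConfig = PhotochemConfig(),
) -> PotentialField:
    """Compose the full µ_photo field from UV, wind and NPP climatologies.

    All three fields must be co-registered on the same grid.  Cells where
    any input is missing stay NaN; uncovered (high-wind) ocean cells are 0.
    """
    for f in (wind, npp):
        if f.values.shape != uv.values.shape or not (
            np.allclose(f.lat, uv.lat) and np.allclose(f.lon, uv.lon)
        ):
            raise RegistrationError("uv, wind and npp must share one grid")

    trophic = classify_trophic(npp)
    surf = surfactant_concentration(trophic)
    fsurf = np.full(surf.values.shape, np.nan)
    good = np.isfinite(surf.values)
    fsurf[good] = np.log(surf.values[good]) / np.log(cfg.c_max_surfactant)

    covered = sml_mask(wind, cfg.wind_limit)
    kg = np.full(wind.values.shape, np.nan)
    wgood = np.isfinite(wind.values)
    kg[wgood] = (cfg.a_kg + cfg.b_kg * wind.values[wgood] ** 3) / (
        cfg.a_kg + cfg.b_kg * cfg.u_lab**3
    )

    if cfg.multiply_t_sun:
        tsun = np.stack(
            [np.broadcast_to(day_length(uv.lat, m)[:, None], uv.values.shape[1:])
             for m in range(1, 13)]
        )
    else:
        tsun = np.ones_like(uv.values)

    vals = tsun * uv.values * fsurf * kg
    # uncovered cells with valid wind and UV are exactly 0; cells missing an
    # input (land, no data) stay NaN
    vals[~covered] = np.where(
        np.isfinite(uv.values[~covered])
        & np.isfinite(wind.values[~covered]),
        0.0,
        np.nan,
    )
    return PotentialField(vals, uv.lat.copy(), uv.lon.copy(), cfg)


def seasonal_mean(potential: PotentialField) -> dict[str, np.ndarray]:
    """Mean µ_photo per meteorological quarter, keyed by season label."""
    import warnings

    out = {}
    for label, months in SEASONS.items():
        idx = [m - 1 for m in months]
        with warnings.catch_warnings():
            # all-NaN land columns are expected and stay NaN
            warnings.simplefilter("ignore", category=RuntimeWarning)
            out[label] = np.nanmean(potential.values[idx], axis=0)
    return out
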