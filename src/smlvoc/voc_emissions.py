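"""Species-resolved VOC emission fluxes from the photochemical potential.

Multiplying the emission potential µ_photo (mW s cm⁻² day⁻¹) by a
laboratory photochemical production rate VOC_lab (molecules mW⁻¹ s⁻¹)
yields an ambient emission flux in molecules cm⁻² day⁻¹:

    VOC_ambient = VOC_lab · µ_photo

Laboratory rates carry a low–high range, so fluxes and totals are reported
as ranges.  Global annual totals integrate the flux over ocean area and a
365-day no-leap climatological calendar.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .grids import GlobalGrid, MonthlyField, extract_region, field_on_grid
from .photo_potential import PotentialField

AVOGADRO = 6.02214076e23
DAYS_IN_MONTH = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)  # no-leap


@dataclass(frozen=True)
class Species:
    """A VOC with its laboratory photochemical production-rate range.

    ``voc_lab_low``/``voc_lab_high`` are in molecules mW⁻¹ s⁻¹;
    ``carbon_fraction`` is the carbon mass fraction of the molecule.
    """

    name: str
    voc_lab_low: float
    voc_lab_high: float
    molar_mass: float               # g mol⁻¹
    k_oh: float | None = None       # cm³ molecule⁻¹ s⁻¹
    unsaturated: bool = False
    carbon_fraction: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.voc_lab_low <= self.voc_lab_high:
            raise ValueError(
                f"{self.name}: need 0 < voc_lab_low <= voc_lab_high, got "
                f"({self.voc_lab_low}, {self.voc_lab_high})"
            )


# Registry.  Isoprene rates are laboratory measurements on authentic
# microlayer and biofilm samples.  The acetone and acetaldehyde rates are
# BACK-DERIVED PLACEHOLDERS: only their ambient flux ranges (0.58–1.1e14 and
# 0.20–0.60e14 molecules cm⁻² day⁻¹) are on record, so the rates below are
# those ranges divided by a nominal tropical potential of 1e5 mW s cm⁻²
# day⁻¹.  Replace them with measured values before quantitative use.
SPECIES_REGISTRY: dict[str, Species] = {
    "isoprene": Species(
        "isoprene", 3.71e7, 6.19e7, molar_mass=68.12,
        k_oh=1.0e-10, unsaturated=True, carbon_fraction=60.055 / 68.12,
    ),
    "acetone": Species(
        "acetone", 5.8e8, 1.1e9, molar_mass=58.08,
        k_oh=1.8e-13, unsaturated=False, carbon_fraction=36.033 / 58.08,
    ),
    "acetaldehyde": Species(
        "acetaldehyde", 2.0e8, 6.0e8, molar_mass=44.05,
        k_oh=1.5e-11, unsaturated=False, carbon_fraction=24.022 / 44.05,
    ),
}


def voc_flux(mu, voc_lab: float):
    """Ambient emission flux (molecules cm⁻² day⁻¹) = VOC_lab · µ_photo."""
    mu = np.asarray(mu, dtype=float)
    if voc_lab < 0 or np.nanmin(mu) < 0:
        raise ValueError("voc_lab and µ_photo must be non-negative")
    out = voc_lab * mu
    return float(out) if out.ndim == 0 else out


def flux_field(potential: PotentialField, species: Species,
               which: str = "low") -> MonthlyField:
    """Flux map for one end of the laboratory range (``which`` ∈ {low, high})."""
    rate = {"low": species.voc_lab_low, "high": species.voc_lab_high}[which]
    return MonthlyField(
        f"flux_{species.name}_{which}",
        "molecules cm-2 day-1",
        voc_flux(potential.values, rate),
        potential.lat,
        potential.lon,
    )


def regional_flux_range(
    potential: PotentialField,
    species: Species,
    grid: GlobalGrid,
    lat_range: tuple[float, float],
    lon_range: tuple[float, float],
    months: Sequence[int] | None = None,
    area_weighted: bool = True,
) -> tuple[float, float]:
    """(low, high) mean flux over a region/period, molecules cm⁻² day⁻¹."""
    mu_mean = extract_region(
        potential.as_field(), grid, lat_range, lon_range, months, area_weighted
    )
    return (species.voc_lab_low * mu_mean, species.voc_lab_high * mu_mean)


def global_annual_total(flux: MonthlyField, grid: GlobalGrid,
                        molar_mass: float) -> float:
    """Global annual emission in Tg yr⁻¹ from a monthly flux map.

    Σ over ocean cells and months of flux · cell area · days-in-month,
    converted from molecules to mass with the species molar mass.
    """
    if flux.values.shape[1:] != grid.shape:
        raise ValueError("flux field is not on the supplied grid")
    area_cm2 = grid.cell_area * 1.0e4            # m² → cm²
    vals = np.where(np.isfinite(flux.values), flux.values, 0.0)
    vals = np.where(grid.ocean_mask[None, :, :], vals, 0.0)
    days = np.asarray(DAYS_IN_MONTH, dtype=float)[:, None, None]
    molecules = float((vals * area_cm2[None, :, :] * days).sum())
    grams = molecules / AVOGADRO * molar_mass
    return grams / 1.0e12                        # g → Tg


def annual_total_range(potential: PotentialField, species: Species,
                       grid: GlobalGrid) -> tuple[float, float]:
    """(low, high) global annual total for one species, Tg yr⁻¹."""
    return tuple(
        global_annual_total(flux_field(potential, species, w), grid,
                            species.molar_mass)
        for w in ("low", "high")
    )


def total_carbon_emissions(
    potential: PotentialField,
    species_list: Iterable[Species],
    grid: GlobalGrid,
) -> tuple[float, float]:
    """(low, high) summed carbon-mass emissions over species, Tg C yr⁻¹.

    Each species total is weighted by its carbon mass fraction; species
    without a recorded carbon fraction are rejected.
    """
    low = high = 0.0
    for sp in species_list:
        if sp.carbon_fraction is None:
            raise ValueError(f"{sp.name}: carbon_fraction required")
        lo, hi = annual_total_range(potential, sp, grid)
        low += lo * sp.carbon_fraction
        high += hi * sp.carbon_fraction
    return (low, high)


def write_species_csv(path, species: Iterable[Species]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "voc_lab_low", "voc_lab_high", "molar_mass",
                    "k_oh", "unsaturated", "carbon_fraction"])
        for sp in species:
            w.writerow([sp.name, sp.voc_lab_low, sp.voc_lab_high,
                        sp.molar_mass, sp.k_oh if sp.k_oh is not None else "",
                        int(sp.unsaturated),
                        sp.carbon_fraction if sp.carbon_fraction is not None else ""])


def read_species_csv(path) -> dict[str, Species]:
    out: dict[str, Species] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["name"]] = Species(
                name=row["name"],
                voc_lab_low=float(row["voc_lab_low"]),
                voc_lab_high=float(row["voc_lab_high"]),
                molar_mass=float(row["molar_mass"]),
                k_oh=float(row["k_oh"]) if row.get("k_oh") else None,
                unsaturated=bool(int(row["unsaturated"])),
                carbon_fraction=(
                    float(row["carbon_fraction"])
                    if row.get("carbon_fraction") else None
                ),
            )
    return out


def regional_table_csv(
    path,
    potential: PotentialField,
    species: Species,
    grid: GlobalGrid,
    rows: Iterable[dict],
) -> None:
    """Write a regional-comparison CSV (one row per study region).

    Each input row needs keys: location, lat (tuple), lon (tuple),
    months (list).  Fluxes are written in 10¹² molecules cm⁻² day⁻¹.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["location", "lat", "lon", "period",
                    "flux_low_1e12", "flux_high_1e12"])
        for r in rows:
            lo, hi = regional_flux_range(
                potential, species, grid, r["lat"], r["lon"], r.get("months")
            )
            w.writerow([
                r["location"], r["lat"], r["lon"], r.get("months", "annual"),
                f"{lo / 1e12:.3f}", f"{hi / 1e12:.3f}",
            ])
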