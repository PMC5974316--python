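"""Sea-surface microlayer (SML) coverage from productivity and wind.

Surfactant-enriched microlayers form over biologically productive water and
are disrupted by wind-driven wave breaking.  The mapping implemented here:

1. classify each ocean cell/month by trophic state from net primary
   production (NPP, g C m⁻² day⁻¹): oligotrophic below 0.4, mesotrophic
   between 0.4 and 1.2 (boundaries inclusive), eutrophic above 1.2;
2. assign each trophic state the mean field-observed surfactant
   concentration in Triton-X equivalents (320 / 502 / 663 µg Teq L⁻¹);
3. declare cells free of an SML wherever the monthly-mean 10-m wind speed
   strictly exceeds a chosen limit (8, 10 or 13 m s⁻¹).

Boundary conventions (NPP exactly at a threshold → mesotrophic; wind exactly
at the limit → covered) follow the strict inequalities of the source
classification and are fixed here so results are reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grids import GlobalGrid, MonthlyField, RegistrationError, _month_index

# trophic category codes
UNDEFINED = -1
OLIGOTROPHIC = 0
MESOTROPHIC = 1
EUTROPHIC = 2

CATEGORY_NAMES = {
    UNDEFINED: "undefined",
    OLIGOTROPHIC: "oligotrophic",
    MESOTROPHIC: "mesotrophic",
    EUTROPHIC: "eutrophic",
}

#: NPP thresholds separating trophic states, g C m⁻² day⁻¹
NPP_OLIGO_MAX = 0.4
NPP_EUTROPHIC_MIN = 1.2

#: Mean surfactant concentration per trophic state, µg Teq L⁻¹
SURFACTANT_UG_TEQ_L = {
    OLIGOTROPHIC: 320.0,
    MESOTROPHIC: 502.0,
    EUTROPHIC: 663.0,
}

#: Wind-speed limits (m s⁻¹) above which the sea surface is SML-free
WIND_LIMITS = (8.0, 10.0, 13.0)


@dataclass
class TrophicMap:
    """Per-cell/month trophic category codes (−1/0/1/2), shape (12, nlat, nlon)."""

    codes: np.ndarray
    lat: np.ndarray
    lon: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return self.codes != UNDEFINED


def classify_trophic(npp: MonthlyField) -> TrophicMap:
    """Classify NPP (g C m⁻² day⁻¹) into trophic states.

    Missing NPP (land or no data) maps to the ``undefined`` category.
    Negative NPP anywhere is a validation error.
    """
    vals = npp.values
    if np.nanmin(vals) < 0:
        raise ValueError("NPP must be non-negative where defined")
    codes = np.full(vals.shape, UNDEFINED, dtype=np.int8)
    good = np.isfinite(vals)
    codes[good & (vals < NPP_OLIGO_MAX)] = OLIGOTROPHIC
    codes[good & (vals >= NPP_OLIGO_MAX) & (vals <= NPP_EUTROPHIC_MIN)] = MESOTROPHIC
    codes[good & (vals > NPP_EUTROPHIC_MIN)] = EUTROPHIC
    return TrophicMap(codes, npp.lat.copy(), npp.lon.copy())


def surfactant_concentration(trophic: TrophicMap) -> MonthlyField:
    """Surfactant concentration (µg Teq L⁻¹) from trophic state; NaN where undefined."""
    out = np.full(trophic.codes.shape, np.nan)
    for code, conc in SURFACTANT_UG_TEQ_L.items():
        out[trophic.codes == code] = conc
    return MonthlyField("c_surfactant", "ug Teq L-1", out, trophic.lat, trophic.lon)


def sml_mask(wind: MonthlyField, limit: float) -> np.ndarray:
    """Boolean SML coverage mask: covered ⇔ U₁₀ ≤ limit.

    Cells strictly exceeding the limit, and land/missing cells, are
    uncovered ("photochemically not active").
    """
    if not np.isfinite(limit) or limit <= 0:
        raise ValueError(f"wind-speed limit must be positive, got {limit!r}")
    vals = wind.values
    if np.nanmin(vals) < 0:
        raise ValueError("wind speed must be non-negative where defined")
    return np.isfinite(vals) & (vals <= limit)


def coverage_fraction(
    mask: np.ndarray,
    grid: GlobalGrid,
    months: Sequence[int] | None = None,
) -> float:
    """Area-weighted fraction of ocean surface covered by an SML.

    Averaged over the selected months (all twelve by default).
    """
    if mask.shape[1:] != grid.shape:
        raise RegistrationError("mask does not match grid shape")
    midx = _month_index(months)
    w = grid.cell_area[grid.ocean_mask]
    total = w.sum() * midx.size
    covered = sum(w[mask[m][grid.ocean_mask]].sum() for m in midx)
    return float(covered / total)


def monthly_coverage_csv(
    path,
    wind: MonthlyField,
    grid: GlobalGrid,
    limits: Sequence[float] = WIND_LIMITS,
) -> None:
    """Write per-month ocean coverage fractions for each wind limit as CSV."""
    masks = {lim: sml_mask(wind, lim) for lim in limits}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["month"] + [f"coverage_limit_{lim:g}" for lim in limits])
        for m in range(1, 13):
            writer.writerow(
                [m] + [f"{coverage_fraction(masks[lim], grid, [m]):.6f}" for lim in limits]
            )


def trophic_field(trophic: TrophicMap) -> MonthlyField:
    """Trophic codes as a MonthlyField (floats, NaN where undefined) for NetCDF export."""
    vals = trophic.codes.astype(float)
    vals[trophic.codes == UNDEFINED] = np.nan
    f = MonthlyField("trophic_state", "category", vals, trophic.lat, trophic.lon)
    return f
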