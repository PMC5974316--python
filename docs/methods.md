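# Methods

This note documents the model assumptions, parameter choices, numerical
decisions and known limitations of `smlvoc`.

## Emission-potential model

The daily photochemical VOC emission potential per ocean cell and calendar
month is the product µ_photo = t_sun · UV_ab · F_surfactant · k_g, kept in
the bookkeeping unit mW s cm⁻² day⁻¹ so that multiplication by a laboratory
production rate (molecules mW⁻¹ s⁻¹) yields a daily flux directly.  The
unit string mixes a rate and a dose; we retain it for that conversion
convenience and document the inputs as *mean daytime irradiance* in
mW cm⁻².

Assumptions inherited from the underlying laboratory work: production is
linear in UV irradiance (280–400 nm treated as one scalar band), decays
logarithmically with surfactant concentration, and occurs only where a
microlayer exists.  The ocean surface is treated as flat; wave-driven area
enhancement is instead folded into the gas-transfer factor.

Parameters (all overridable via `PhotochemConfig`):

| parameter | default | meaning |
|---|---|---|
| `wind_limit` | 13 m s⁻¹ | wind above which no SML persists (8/10/13 supported) |
| `c_max_surfactant` | 663 µg Teq L⁻¹ | eutrophic mean, normalisation of F_surfactant |
| `u_lab` | 5.31×10⁻² m s⁻¹ | laboratory flow speed (200 mL min⁻¹ scaled to 10 m by a log wind profile) |
| `a_kg`, `b_kg` | 8.2, 0.014 | cubic gas-transfer coefficients |
| `multiply_t_sun` | on | whether to multiply the day length |

**Day length.**  t_sun is computed from solar geometry at mid-month
(declination δ = 23.44°·sin(2π(284+n)/365), sunset hour angle
cos ω₀ = −tan φ tan δ clamped for polar day/night) rather than taken from a
UV dataset.  Monthly UV climatologies often already integrate day length
into a daily dose; the `multiply_t_sun` switch exists so users with
dose-type inputs can avoid double counting.  The default multiplies,
matching the four-factor definition literally.

**Boundary conventions.**  NPP exactly at 0.4 or 1.2 g C m⁻² day⁻¹ is
mesotrophic (the outer classes are defined by strict inequalities); wind
exactly at the limit keeps its SML ("exceeding" removes it).  These
conventions are fixed here because the classification source leaves them
open; they move individual boundary cells only.

**Regional means** are area-weighted (cos-latitude) by default with a flag
for plain averaging; whether published regional means were area-weighted is
not documented, so both are available.

## Regridding

Native-resolution inputs are refined to the 1°×1° cell-centre grid by
per-month bilinear interpolation with any-valid-neighbour weighting: the
four stencil weights are renormalised over non-missing corners, so coastal
cells survive partial stencils, and a fully missing stencil stays missing.
Interpolation is exact on affine fields and never overshoots the source
range.  Longitudes are normalised to −180…180 on read.  Conservative
(flux-preserving) regridding is out of scope.  The Earth is a sphere of
radius 6371 km; cell areas are R²·Δφ·Δλ·cos(lat).

## Flux integration

Global totals use a 365-day no-leap calendar (climatological monthly
means), summing flux · cell area · days-in-month over ocean cells and
converting molecules to mass by molar mass.  The species registry ships
isoprene (VOC_lab = 3.71–6.19×10⁷ molecules mW⁻¹ s⁻¹, M = 68.12 g mol⁻¹,
unsaturated) plus acetone and acetaldehyde entries whose production rates
are **back-derived placeholders**: only their ambient flux ranges are on
record (0.58–1.1×10¹⁴ and 0.20–0.60×10¹⁴ molecules cm⁻² day⁻¹), so the
registry divides those by a nominal tropical potential of 1×10⁵ mW s cm⁻²
day⁻¹.  Compound-mass and carbon-mass totals are reported separately
(`annual_total_range` vs `total_carbon_emissions`); carbon totals weight
each species by its carbon mass fraction.

## SOA box model

A well-mixed MBL column of height h receives a constant precursor flux E;
the precursor concentration follows dC/dt = E/h − k·C with
k = k_OH·c_OH, giving the analytic steady state C_ss = E/(h·k).  The
published mean OH rate constant for the unsaturated VOC mixture is printed
with a positive exponent (10¹²); we implement 1.0976×10⁻¹⁰ cm³ molecule⁻¹
s⁻¹, the only reading consistent with the published steady state of
4×10⁸ molecules cm⁻³.  Each Euler step (default dt = 60 s, guarded by
dt·k < 0.1; halving dt changes 12-h outputs by < 0.5%) converts the
oxidised mass to µg m⁻³ via the precursor molar mass (default 68 g mol⁻¹,
isoprene-like mix), distributes it over the volatility bins by the mass
yields α, and re-equilibrates all bins — partitioning is treated as
instantaneous relative to the chemistry.

**Partitioning solver.**  The absorptive equilibrium
C_abs = seed + Σᵢ totalsᵢ·(1 + C*ᵢ/C_abs)⁻¹ is solved by bracketed root
search (Brent) on [seed, seed + Σ totals] to ~10⁻¹² relative tolerance; the
bracket guarantees the unique non-negative solution.  With zero seed and a
sub-saturated mixture (Σ totalsᵢ/C*ᵢ ≤ 1) the only fixed point is all-gas,
handled analytically.  Per-bin totals are conserved exactly; a single
supersaturated bin reproduces the closed form C_OA = total − C*.

**Volatility calibration.**  The published configuration pairs the low-NOx
alkene yields α = {0.023, 0.044, 0.129, 0.375} with the log₁₀ C* = 0…3
bins of the 10-bin set.  Read literally, that configuration cannot
reproduce the published single-cell example: the condensable totals after
12 h (≈0.16 µg m⁻³) sit far below those saturation concentrations, and the
equilibrium aerosol yield is ≈0.003 µg m⁻³ — thirty times below the
published 0.088 µg m⁻³.  The example *is* reproduced, in all three of its
features (≈2 h onset delay, 0.085 µg m⁻³ ≈ +21% after 12 h, 16 ppt_V
plateau), when the same yields occupy the four lowest bins
(log₁₀ C* = −3…0, numerically equivalent to reading the printed C* values
in 10⁻³ µg m⁻³ units) and the non-volatile background aerosol acts as
absorbing seed.  `smlvoc` therefore defaults to that calibrated
configuration and treats it as the effective product-volatility
distribution of the original model;
`VBSConfig.with_literature_yields()` restores the literal alignment for
sensitivity studies.  "Non-volatile background" retains its meaning in both
settings: the background never evaporates or re-partitions, it only
provides absorbing mass (switchable via `poa_in_absorbing_mass`; with it
off, a 10⁻⁶ µg m⁻³ bootstrap seed floats the fixed point).

**Temperature dependence of C*.**  A Clausius–Clapeyron shift
C*(T) = C*(300 K)·(300/T)·exp[(ΔH/R)(1/300 − 1/T)] with ΔH = 30 kJ mol⁻¹
is implemented but **off by default**: the published example at 20 °C is
matched best using the 300 K values directly (0.0846 vs 0.088 µg m⁻³;
with the shift on, 0.0928), indicating the original model applied no
shift.  Enable it with `apply_cstar_shift=True` for physically
temperature-consistent runs.

Default aging conditions: 12 h of active oxidation per day at 15 °C,
c_OH = 1.5×10⁶ cm⁻³.  Ozone-initiated oxidation, multigenerational aging
and aerosol microphysics are out of scope; the SOA numbers are lower
limits also because emissions are instantaneously diluted into the whole
MBL column.

**Gridded SOA maps.**  `soa_contribution_map` accepts an arbitrary
background-aerosol field (default constant 0.4 µg m⁻³, typical remote
marine air) and an MBL-height field; a mechanistic primary-aerosol emission
scheme is deliberately not included.  Per cell it evaluates the closed-form
end state of the box scenario (the precursor ODE integrates exactly and
equilibrium partitioning is memoryless, so the 12-h aerosol mass depends
only on the cumulative oxidised mass) — verified in the tests to match the
time-stepped model within Euler error.  The per-cell emission rate spreads
the daily flux VOC_lab·µ_photo over the `aging_hours` window.

## Synthetic climatologies

The generators emulate the gross structure of the real inputs so the whole
pipeline is testable offline; they do not emulate their detailed
statistics, so passing tests demonstrate correct mechanics, units and
monotonicities — not agreement with real-world global numbers, which
require the external UV/wind/NPP climatologies.

* **Ocean mask** — deterministic rectangular pseudo-continents giving
  69.9% ocean (3.57×10¹⁴ m², within 5% of the real ocean area).
* **UV** (peak 4.5 mW cm⁻² at the equator) — cosine-of-zenith profile
  following the seasonally migrating sub-solar latitude, zero in polar
  night, ±5% smooth noise.
* **Wind** — westerly belts near ±50° peaking at 15 m s⁻¹ (so the 8, 10
  and 13 m s⁻¹ masks all differ), trades near ±15°, equatorial doldrums,
  winter-hemisphere amplification.
* **NPP** — a smooth latent productivity field (coastal and high-latitude
  enhancement plus seeded noise) cut at area-weighted quantiles so the
  classified trophic area fractions hit the configured targets
  (default 60/30/10% oligo/meso/eutrophic) by construction.
* **MBL height** (mean 800 m, deeper in the trades) and a constant
  0.4 µg m⁻³ aerosol background.

All generators are pure functions of `(SynthConfig, seed)` using
`numpy.random.default_rng` with per-field seed sequences; identical
configurations give bit-identical fields.

## File formats

NetCDF I/O uses the classic (NetCDF-3 64-bit) format via xarray's scipy
backend, with CF-style month/lat/lon dimensions and units attributes.
Coverage summaries, species tables and box-model time series are plain CSV.

## Known limitations

* The surfactant ladder (320/502/663 µg Teq L⁻¹) is a three-level
  climatological proxy; real microlayers are chemically diverse and
  dynamic, and the logarithmic irradiance–production law comes from
  single-surfactant laboratory systems.
* Gas-transfer velocities carry at least a factor-two uncertainty.
* The volatility calibration above reproduces the published example but
  inherits its conventions; treat absolute SOA masses as
  scenario-consistent estimates, not predictions.
* Monthly climatological forcing cannot resolve bloom decay, storms or
  diurnal cycles; µ_photo is a monthly-mean potential, not an hourly flux.
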