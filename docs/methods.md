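# Methods

## The model

`watneeds` solves a daily, single-layer (bucket) water balance of the crop
root zone, independently for every grid cell, crop and water regime. The
state is the depth-averaged root-zone storage `S` (mm), bounded by the
total available water `TAW = theta_diff * zr` (soil storage capacity,
mm/m, times rooting depth, m) and its readily available share
`RAW = p * TAW`, where `p` is the crop's critical depletion factor.

Each day the engine evaluates, in this order:

1. `Peff = (1 - fr) * P` with surface-runoff fraction `fr` (default 5%);
2. potential crop ET `ETpot = kc * ET0`;
3. stress coefficient `ks` on the **previous day's** storage: `S/RAW`
   below RAW, 1 at or above (forced to 1 for an unstressed run);
4. actual ET `ETa = ks * ETpot`;
5. deep percolation `D` on the previous day's storage: 0 below RAW,
   rising linearly to the soil's maximum infiltration rate `Fmax` at TAW;
6. tentative storage `S' = S + Peff - ETa - D`;
7. if `S' < 0`, `ETa` and `D` are multiplied by the common factor
   `lambda = (S + Peff)/(ETa + D)` so the balance closes at `S' = 0`
   (their ratio is preserved; `lambda = 0` if both sinks are zero);
8. if `S' > TAW`, the excess leaves as sub-surface runoff `R` and the
   storage is capped at TAW.

The scheme is fully explicit: evaluating both `ks` and `D` on the
carried-over state avoids any implicit circularity, and percolation's
stated validity condition refers to the previous day's storage. The daily
identity `S_t - S_{t-1} = Peff - ETa - D - R` holds to machine precision
and is asserted over the whole trace of every simulation (tolerance
1e-9 mm). The time step is fixed at one day.

**Green and blue water.** Green water is the stressed actual ET — demand
met from precipitation-derived soil moisture. Blue water is the
irrigation requirement `ETpot - ETa`, counted on irrigated land only. The
unstressed ("irrigated") actual ET is taken to be `ETpot` identically:
irrigation is by definition whatever closes the gap, so no irrigation
term is simulated in the balance and only the stressed trace is run. A
consequence asserted in the tests: for irrigated land, green + blue
equals the in-season sum of `kc * ET0` exactly.

**Aggregation.** Daily green/blue values are summed over each calendar
month of a crop's growing season. Off-season days (simulated with
`kc = 0.5`) move soil moisture between seasons but never contribute to
the reported requirement. Seasons that wrap the year boundary book each
day in its actual calendar month, so a crop planted in October
contributes to both the late and the early months of adjacent years.
Where a crop has two growing periods in a cell, each period is simulated
independently (its own kc curve and spin-up) and the monthly fields are
summed — summation conserves total seasonal demand, which is why it was
preferred over averaging the two periods. Multi-year products are
element-wise means of yearly simulations.

## Phenology

Stage lengths are the FAO-56 fractions of the growing period (initial,
development, mid, late), scaled to regional planting/harvest dates.
Boundaries use cumulative rounding, `b_k = round(L * sum(f_1..f_k))`, so
the four intervals always tile the season exactly and no drift
accumulates from per-stage rounding. Within the season, kc is constant at
`kc_ini`, ramps linearly to `kc_mid` over development (reaching `kc_mid`
on the first mid-season day), stays at `kc_mid`, then ramps to `kc_end`
on the harvest day. The interpolation shape is the de-facto FAO-56
convention.

Calendars are climatological: a season recurs every year of the
simulation span, defined by day-of-year on a nominal 365-day year.
Day-of-year 366 maps to day 365 in common years; a season spanning a leap
day keeps its nominal length, so its harvest date shifts by one calendar
day in leap years. Regions reporting more than two growing periods per
crop-regime are consolidated to the two with the largest harvested area
(ties broken by earliest planting day); discarded areas are added to the
nearest retained period by circular planting-day distance, conserving the
total. An external-calendar fallback for all-equal-area ties is out of
scope — the deterministic earliest-planting tie-break replaces it.

## Initial conditions and spin-up

Every simulation starts at `S = 50%` of TAW and runs a three-year spin-up
before the production period, using forcing years drawn once from a
seeded generator and reused for every crop, regime and cell of a run (so
perturbation experiments differ only in the perturbed parameter). The
spin-up is what makes the initial fraction irrelevant: the
initial-condition sweep (0% vs 100% of TAW) on the seasonal synthetic
scenario changes domain-total annual green+blue water by ~1e-13% —
effectively zero, because the bucket saturates (or empties) at least once
during spin-up, which erases its memory completely. Without spin-up the
change is bounded by TAW relative to seasonal demand, a bound the tests
check on an arid scenario.

## Forcing

ET0 arrives as monthly totals and is disaggregated uniformly within each
month (`mm/month / days_in_month`); uniform splitting was chosen over
mid-month interpolation because it conserves the monthly totals exactly.
Precipitation is daily. Both must cover the same days; grids are
validated cell-for-cell against the run's `GridSpec`, with errors naming
the offending layer and both shapes.

## Grids and files

Grids are regular WGS84 lat/lon with cell-centre coordinates, row 0
northernmost, longitudes −180→180. The global product grid is 2160 × 4320
at 1/12° (5 arcmin). Cells whose region has no calendar entry for a
crop-regime carry NaN (written with `_FillValue`), never 0. Outputs are
NetCDF-4: annual files `BW_irrig_<YEAR>`, `GW_irrig_<YEAR>`,
`GW_rainf_<YEAR>` with a crop dimension ordered by the 26 crop codes
(1 = wheat … 26 = others annual), and monthly per-crop files
`BW_<crop>_irr_<YEAR>` / `GW_<crop>_irr_<YEAR>` / `GW_<crop>_rfc_<YEAR>`
with a 12-month dimension; units are mm throughout. The variable naming
inside the files (`cwr`, plus `crop_name` labels) is this package's own
frozen schema. Inputs are NetCDF (plus CSV for crop and calendar tables);
only nearest-neighbour regridding between WGS84 grids is provided.

The daily loop is vectorised with numpy across the cells of a calendar
region. The scalar and vectorised paths share one elementwise step
function, so a grid run is bit-identical to looping the point engine over
cells — asserted in the tests, along with agreement of the step against
an independent literal transcription of the stress/percolation/closure
rules on 10^4 random states.

## Synthetic forcing

The generator emulates the statistical envelope of the real inputs:
precipitation as independent Bernoulli wet-day occurrence times
exponential depths per cell-day; ET0 as a sinusoid
`mean + amplitude * cos(2*pi*(doy - phase)/365)` (clipped at zero,
spatially uniform, delivered as monthly sums); soil storage capacity
uniform in [100, 250] mm/m and maximum infiltration in [5, 50] mm/day;
calendars covering single-season, two-season, more-than-two-season and
year-wrapping cases. Defaults for the `seasonal` scenario — 30% wet days
of mean 8 mm (≈880 mm/yr), ET0 between 1 and 6 mm/day peaking at
day-of-year 196 — describe a mixed climate where soil moisture passes
through both stressed and saturated phases each year.

Two presets are analytic limiting cases used as end-to-end checks. The
`humid` preset rains a **constant** 80 mm every day (the one departure
from the exponential-depth contract, needed so daily supply provably
exceeds demand plus percolation): the bucket stays at TAW, so blue water
is exactly 0 and green water equals the in-season sum of `kc * ET0`. The
`arid` preset has no rain: started empty, green water is exactly 0 and
irrigated blue water equals the potential demand.

What the generator does **not** emulate: spatial autocorrelation, storm
structure, orographic or latitudinal gradients, ET0–precipitation
correlation. Passing tests therefore demonstrate the correctness of the
numerics and bookkeeping under realistic magnitudes, not skill against
observed climate or the published global totals (which require the real
CRU/CHIRPS/CPC/MIRCA inputs).

## Sensitivity and comparison harnesses

`sensitivity_initial_condition` and `sensitivity_offseason_kc` re-run the
full gridded model with one engine parameter swept, all seeds fixed. The
off-season-kc sweep reports a per-crop and total green/blue table, one
column pair per kc value. `compare_fields` computes the area-weighted
fraction of cells whose relative difference `|a - b| / b` from a
reference field `b` stays within a threshold; cells where both fields are
zero agree, cells where only the reference is zero disagree, and the
mean relative difference is taken over cells with `b > 0` (the statistic
is deliberately one-sided in `b`, and is scale-invariant). Weights
default to uniform when no harvested-area grid is supplied.

## Problem sizes and numerical choices

Default experiment sizes (10 × 10 cells, 3 crops, 2 regimes, 5 forcing
years, 1 production year, 3 spin-up years) run in seconds and already
average ~100 heterogeneous soil columns, which is ample to measure the
domain-level statistics the harnesses report. Key tolerances: balance
residual 1e-9 mm/day; stage fractions must sum to 1 within 1e-9; annual
vs monthly consistency 1e-6 mm; analytic-limit agreement 1e-6 mm.
Degenerate inputs are rejected up front (negative forcing, non-finite
values, `p` outside (0,1), RAW ≥ TAW, zero-length seasons); a zero-length
stage simply receives no days.

## Known limitations

Single soil layer; no capillary rise, groundwater coupling, snow,
interception or deficit-irrigation scheduling. The surface-runoff share
is a fixed fraction, not intensity-dependent. ET0 is an input — the model
does not compute Penman–Monteith from raw meteorology. Irrigated and
rain-fed runs share the precipitation forcing; paddy-specific processes
(standing water for rice) are not represented beyond the crop's shallow
rooting depth and low depletion factor. GeoTIFF static layers are not
read — inputs are NetCDF/CSV only.
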