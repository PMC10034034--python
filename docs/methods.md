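# Methods

This note records the models the package implements, the defaults it
ships, the numerical choices made where the design was genuinely open,
and what the synthetic field simulator does and does not emulate.

## Stress limits and the minute CWSI

The crop water stress index normalizes the canopy-minus-air
temperature differential between two theoretical limits evaluated
from weather alone, using the one-layer energy-balance form:

    dT_ul = r_a (R_n − G) / ρc_p
    γ*    = γ (1 + r_c,p / r_a)
    dT_ll = dT_ul · γ*/(Δ + γ*) − VPD/(Δ + γ*)

Saturation vapor pressure follows the Tetens form
e_s = 0.6108·exp(17.27 T/(T+237.3)) kPa, and Δ is its analytic
derivative at air temperature — no tabulated slopes.  Defaults:
aerodynamic resistance r_a = 10 s m⁻¹, canopy resistance at potential
transpiration r_c,p = 50 s m⁻¹, psychrometric constant γ = 0.066 kPa
K⁻¹, ρc_p = 1200 J m⁻³ K⁻¹.  These are plausible mid-day values for a
ventilated short crop; they are site parameters and are exposed in
configuration precisely because calibrating them is a field exercise,
not a package default one can trust blindly.  R_n − G may be supplied
as a constant or derived per minute from solar irradiance as
0.65 × S (the 0.65 coefficient is configurable); under zero radiative
load and saturated air both limits collapse to zero and the index is
undefined, which the minute pipeline records as a missing minute.

Minute CWSI values are clamped to [0, 1] before integration.  The
tier thresholds (150/250/325 on a 600-minute window) presuppose a
bounded index; unclamped advective excursions would make the daily
dose unbounded and the tiers meaningless.

## Reference curve, scaling, and the daily dose

Stationary infrared thermometers over fully irrigated plots provide
whole-day canopy curves; their pointwise arithmetic mean is the
reference.  Gaps up to 10 minutes are linearly interpolated; longer
gaps fail loudly naming the gap, since silently bridging a cloud-band
or radio outage would bias the daily dose.

A moving sensor sees each zone once.  The single observation is
scaled through the reference with anchored-ratio scaling,

    T_s(t) = a + (ref(t) − a) · (T_obs − a) / (ref(t_obs) − a),

with the anchor a set to the day's pre-dawn minimum air temperature.
This family preserves the diurnal shape, is exact at the observation
minute (enforced explicitly, so the guarantee is independent of
floating-point rounding), and degrades gracefully: an unstressed zone
reproduces the reference identically.  The denominator vanishing
(reference equal to the anchor at the observation minute) is an error,
not a fallback.

The daily dose integrates one-minute CWSI over 09:00–19:00 as a
left-Riemann sum at one-minute steps — 600 terms for a complete
window, so the dose lives on a 0–600 scale and the tier cut points
read directly as "minutes of full stress equivalent".  Up to 5 % of
minutes may be missing (linearly interpolated, logged); more is an
error.  The window bounds are half-open, [09:00, 19:00).

## Soil water depletion

The sensed profile places TDRs at 10/20/30/50 cm and partitions the
top 60 cm at sensor midpoints: layers 0–15, 15–25, 25–40 and 40–60 cm.
Field capacity defaults to 0.35/0.34/0.33/0.33 m³ m⁻³ per layer with a
common wilting point of 0.18 m³ m⁻³ (a clay loam with a calcic hard
pan at depth); all are configurable.  Depletion is reported as the
thickness-weighted mean fraction of plant-available water consumed,
Σ l_i f_i / Σ l_i ∈ [0, 1].  The un-normalized sum Σ l_i f_i has
units of length and could not be compared against the 0.10/0.65
scheduling gates, which are fractions of the management-allowed-
depletion kind; normalization is therefore part of the definition
here, with per-layer fractions clamped to [0, 1].

The manual method's replenishment amount is the deficit to 96 % of
field capacity summed over layers within the root zone (default
1.5 m, pro-rating a layer straddling the boundary), in millimetres;
layers wetter than their target contribute nothing rather than a
negative credit.  The seasonal water balance uses
ET_c = I + P + F − ΔS − R with ΔS = end-minus-start storage, boundary
flux F and runoff R defaulting to zero; a season that draws the
profile down therefore adds to ET_c, as it must.

## The decision engine

Tier bounds are half-open and lower-inclusive: a dose of exactly 150
is tier I, exactly 325 tier III.  The hybrid gates act inclusively at
both ends (≤ 0.10 withholds, ≥ 0.65 applies the level's maximum
depth), and a missing soil reading — distinct from a reading of any
value — falls back to the tier logic, so a dead station degrades the
hybrid method to plant feedback rather than stalling the pivot.
Emitted depths are rounded to 0.1 mm; the default tier depths are
exact at that precision.  A prescription map covers every configured
zone exactly once; zone geometry (annular sector under the pivot) is
carried as metadata only, because decisions are keyed by zone and the
sprinkler-bank mechanics live in hardware.  Replicate pooling —
several zones sharing one soil station and a pooled mean stress dose
— is expressed in configuration, not hard-coded.

Open points resolved as package choices: a tier-triggered depth is
never capped by the remaining profile deficit (no cap is defined for
the tier table, and capping would silently couple the two sensing
streams); rain days are not special-cased by the engine — a wet
profile expresses itself through the SWD gate or a low stress dose.

## The synthetic field

The simulator exists to exercise the scheduler end to end, not to
predict agronomy.  Per day and zone it runs a bucket profile:
infiltration fills layers to field capacity top-down with the excess
leaving the bottom as drainage; extraction removes the day's
evaporative demand weighted by a fixed root profile
(0.40/0.25/0.20/0.15 over the four layers), floored at the wilting
point.  Demand is a Priestley–Taylor-style proxy,
α·Δ/(Δ+γ)·(R_n−G)/λ with α = 1.26 and a crop coefficient of 1.0,
reduced linearly once depletion exceeds 0.65 (an FAO-style stress
coefficient) — this reduction is what lets severely deficit
treatments reach a drier equilibrium instead of all treatments
converging on the same long-run application rate.  The daily balance
closes exactly (asserted at 10⁻⁹ mm) and the season ledger sets
F = −drainage so ET_c equals the water actually extracted.

Weather emulates a dry-year semi-arid High Plains season: daily
extremes drawn around 34/19 °C (σ = 2 °C), a minute-level sinusoid
with the minimum at 03:00 and maximum at 15:00, relative humidity
mirroring temperature between 80 % (pre-dawn) and 25 % (afternoon),
clear-sky noon irradiance of 950 W m⁻² with a daily cloudiness
factor, and sparse convective rain (5 % daily probability,
exponential depths with a 7 mm mean).  Canopy temperature responds to
soil state through a monotone gain curve g(d) = d^gain (linear by
default) interpolating between the stress limits, so a fully depleted
zone sits at the non-transpiring limit.  One-time-of-day observations
(13:00, offset one minute per zone to mimic the moving lateral) carry
0.2 °C Gaussian noise and pass through the real reference-curve /
scaling / integration pipeline; soil stations can be failed per scan
with a configurable probability to exercise the hybrid fallback.

Scans run every 3 days starting day 1; prescriptions apply the
following day.  Reference-plot deficit readings for the manual method
are refreshed on the same schedule, so the manual benchmark responds
on the same cadence as the sensor methods (a deliberate
simplification of weekly probe readings: it keeps the fully irrigated
zones near their refill target, which is what the manual amounts are
defined against).  All stochastic draws come from one generator
seeded from the run seed, giving bitwise-reproducible runs.

What the simulator does not emulate — and what passing tests
therefore do not show about real fields: crop growth and yield (no
yield model is invented; the metrics take measured yields as inputs),
spatial soil heterogeneity beyond per-zone profiles, advection events
that push the canopy outside the theoretical limits, sensor drift and
body-temperature error, and the hydraulics of a pivot that cannot
always apply a prescription the next day.  Test problem sizes — 60-day
seasons, eleven zones, 600-minute windows — were chosen so a full
closed-loop season runs in well under a second while still containing
multiple refill cycles at every level.

## Tolerances and degenerate inputs

Validation raises a single `ValidationError` type with messages that
name the offending zone, station, key or line.  Water-balance
assertions use 10⁻⁹ mm; scaling exactness at the observation minute
is exact equality; everything else compares at the precision the
quantity is reported with (0.1 mm depths, 0.01 kg m⁻³ productivity,
integer percent savings).  Degenerate cases defined above: zero
radiative load collapses the stress limits; a reference equal to the
anchor at the observation minute, inverted temperature extremes,
humidity outside [0, 100] %, non-contiguous soil layers and water
contents above a 0.60 porosity bound are all rejected rather than
repaired.
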