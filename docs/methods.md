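# Methods

This note documents the models, conventions, and numerical choices behind
`eutroscen`, and what the synthetic fixtures do and do not establish.

## Effluent mass balance

Each outfall is a well-mixed source with flow `Q` (m³/d, scalar or monthly
series) and constituent concentrations (mg/L; alkalinity meq/L, iron µg/L).
Potable recycling diverts a fraction `r` of the flow through reverse osmosis;
a fraction `ρ` of the diverted volume (default 0.8) is recovered as potable
water and leaves the system, the remainder returns as concentrate. "Removal"
efficiencies are interpreted as membrane **rejection into the concentrate**:
a constituent with rejection `η` keeps `η` of its diverted mass in the return
stream and loses `1 − η` to the permeate. This is the only reading under
which nitrogen loading stays roughly constant across recycling levels at
η ≈ 0.95–1.0, which is the premise of the scenario design. Closure holds
exactly by construction and is asserted to machine precision in the tests:
discharged + recovered volume = original; undiverted + concentrate +
permeate mass = original.

DIN management is applied **before** recycling and caps each nitrogen species
independently at its tier target (`min(current, target)`); outfalls already
below a target are held constant. The per-species min rule is a design
choice: targets are stated per species, and capping (rather than setting)
preserves plants that already treat beyond the tier. A consequence is that an
outfall whose NO3+NO2 sits below target keeps its speciation instead of
converting ammonium to nitrate; suite-level DIN totals are unaffected by this
distinction within each tier's recycling ratios.

Scenario suite: CTRL (all outfall loads zeroed, flows kept), ANTH (identity),
and the 2 × 3 grid of DIN tier {7, 13} / {1, 4} mg/L × recycle fraction
{0, 0.5, 0.9}. Monthly flow series are balanced month-by-month and
summarized by time-averaging afterwards. Effluent density is reported from a
linear ρ(S, T) approximation but **not** propagated to plume geometry: plume
placement is held fixed across scenarios so that scenario differences isolate
the load forcing rather than confounded plume dynamics.

## Carbonate system

`solve_carbonate` solves `TA(pH; DIC, totals) = TA_input` for pH on the total
scale, bracket [2, 12], by Newton iteration with bisection safeguard
(forward-difference derivative, convergence at |ΔTA| ≤ 1e-8 of input TA,
far tighter than any diagnostic threshold). The alkalinity decomposition
carries carbonate, borate, water, phosphate (3 K's), and silicate terms minus
free H⁺, HSO4⁻ and HF.

Constant dialect (recorded in `CarbonateParams`): K1/K2 Lueker et al. (2000),
HSO4⁻ Dickson (1990a), HF Dickson & Riley (1979), total boron Uppström
(1974), KW/KP/KSi Millero (1995), K0 Weiss (1974), aragonite Ksp Mucci
(1983) with [Ca²⁺] ∝ S/1.80655. Constants are assembled on the seawater
scale, pressure-corrected with the Millero (1995) molal-volume /
compressibility forms (aragonite ΔV = calcite + 2.8 cm³/mol), then converted
to the total scale using the pressure-corrected HSO4⁻/HF constants — the
same order of operations as the classic CO2SYS code. In-situ pressure is
depth(m)/10 ≈ depth dbar. Grid inputs in mmol/m³ (TA meq/m³) are converted
to µmol/kg with a fixed reference density of 1025 kg/m³ (configurable);
the same density is used for the reverse conversion everywhere, so the
round trip is exact.

Verification is two-route: an **independently coded** scalar evaluator
(`scripts/make_carbonate_reference.py`, plain `math` + 200-step interval
bisection, constants typed in separately from the same primary literature)
froze a 5 × 5 × 5 (T, S, DIC) lattice plus a pressure block into
`tests/data/carbonate_reference.csv`; the vectorized package solver must
reproduce it within 0.005 pH and 0.02 Ω_Ar (observed agreement ≈ 5e-7 pH).
Cross-version differences between published carbonate constant sets are
~0.01 pH, below every diagnostic threshold used here.

## Habitat-capacity metrics

pO2 is computed from O2 concentration as
`pO2 = x_O2 · 101.325 kPa · [O2]/O2_sat(T, S)` with the Garcia & Gordon
(1992) Benson–Krause solubility fit, so air-saturated water maps to the
atmospheric O2 partial pressure (~21.2 kPa). The small water-vapour and
hydrostatic-pressure corrections are neglected — they are far below the
sensitivity of a thickness criterion evaluated over 0–200 m.

The Metabolic Index is `Φ = A0 · pO2 · exp[(E0/k_B)(1/T − 1/T_ref)]`
(supply/resting-demand ratio; body-mass scaling absorbed into A0 for
single-species use). Aerobic habitat requires Φ/Φ_crit ≥ 1, so only the
ratio A0/Φ_crit matters — asserted exactly by a rescaling-invariance test.
**The shipped traits are labelled synthetic placeholders** (A0 = 1 kPa⁻¹,
E0 = 0.4 eV, T_ref = 288.15 K, Φ_crit = 8, chosen so the viability horizon
sits mid-window in the synthetic background): real species traits (e.g.
northern anchovy) are not printed in this codebase and must be supplied from
the trait literature in the same kPa convention.

Calcifier habitat requires Ω_Ar ≥ θ with θ = 1.4 by default (sublethal
stress threshold for calcifying zooplankton); recomputation at θ ∈
{1.1, ..., 1.4} is supported for threshold-sensitivity checks.

Habitat thickness per column is the measure of the set within the 0–200 m
window where the criterion quantity meets its threshold, with the quantity
piecewise **linear between layer centers**, constant above the first center
and below the last wet center (to min(bathymetry, 200 m)). Disjoint
intervals are **summed** — contiguity from the surface is not required; a
criterion evaluated on subsurface O2 minima naturally produces split habitat,
and summing is the measure-theoretic reading of "thickness of optimal
conditions". A dense-sampling brute-force oracle checks the closed-form
interval arithmetic on random columns.

Change reports average thickness over the August–October months of each
simulated year (the late-summer habitat minimum), then form
`100·(scenario − reference)/reference` with two masks: columns with
bathymetry < 200 m (to highlight pelagic environments) and reference
thickness < 1 m (denominator floor; % change of a near-empty habitat is
meaningless). Areal-extent histograms use 5% bins of cell area (km²), with
±10% and ±20% exceedance areas reported.

## Change assessment

* Vertical integrals weight by layer-window overlap; columns shallower than
  the window integrate to the bathymetry. Respiration maps are emitted both
  as 0–200 m integrals (mmol m⁻² d⁻¹, the contour unit) and as
  thickness-weighted averages; both are labelled.
* Normalized Bightwide change: per year,
  `100 · (S − ANTH)/(ANTH − CTRL)`; mean and SEM = sd/√n across years.
  The sign convention makes DIN-reduction scenarios negative. Years follow
  Nov–Oct boundaries (labelled by the ending year) to match the simulation
  averaging windows; denominators below 1e-12 are masked.
* Bightwide means are area-weighted (plain-mean toggle provided); the choice
  matters little on a quasi-uniform grid but is recorded in the API.
* "Considerable value" areas use strict inequalities beyond ±10 mmol m⁻² d⁻¹,
  split at the 15-km inshore band by great-circle distance to coast.
* Inshore decline statistics: area-weighted mean of −Δ (signed) and the 95th
  percentile of positive declines, using a weighted empirical quantile that
  reduces exactly to the standard (n−1)-spacing linear quantile for equal
  cell areas.
* Cross sections bin columns by distance to coast (default 5-km bins,
  0–150 km) and average per depth layer over 0–200 m; a Bightwide mean
  vertical profile accompanies each section.

## Cross-isobath transport

The 200-m isobath section is the staircase of cell faces separating
ocean columns with bathymetry < 200 m from columns ≥ 200 m; each face's
normal points to the deep side, so positive flux is shelf → offshore.
Per face and layer, flux = (normal velocity) × NH4 × face length × layer
thickness, with velocity and concentration interpolated to the face as the
arithmetic mean of the two adjacent cell centers, evaluated on monthly mean
fields (the mean/eddy decomposition of the flux is deliberately out of
scope; the headline number uses monthly means only). Profiles are reported
as alongshore sums (mol/s per layer) and per-unit-section-area rates
(mmol m⁻² s⁻¹); a section-volume-normalized rate (mmol m⁻³ d⁻¹) is available
because transport is sometimes quoted in concentration-tendency units, which
are not dimensionally a transport — both labelled forms avoid the ambiguity.

## Synthetic-ocean generator

The generator produces the statistical structure the diagnostics assume, not
ocean dynamics. Defaults (the study conditions for all tests and the
acceptance script): 120 × 90 cells at 3 km, 30 layers over 0–600 m (10-m
resolution through 0–200 m), 24 monthly states spanning two Nov–Oct years,
straight eastern coastline, exponential shelf/slope bathymetry (e-folding
20 km, max 620 m) crossing the 200-m isobath ~8 km offshore. The 3-km
spacing (vs the 300-m resolution of the real coupled model) is a desk-scale
choice: every diagnostic is resolution-agnostic.

Backgrounds are analytic profiles with a seasonal cycle whose subsurface
O2/DIC anomaly peaks in September, producing the late-summer O2 and Ω_Ar
minima that drive the Aug–Oct habitat aggregation. The aragonite background
crosses Ω = 1.4 near 110 m and the synthetic aerobic viability horizon sits
at ~150–180 m, so both habitat criteria have active thresholds inside the
evaluation window.

Plume anomalies are exactly linear in each outfall's DIN load `L` (kg/d):

* NH4: `3e-4 · L` (mmol m⁻³ at kernel peak) on a Gaussian vertical kernel at
  the discharge depth (σ = 10 m) and an alongshore-stretched exponential
  horizontal kernel (e-folding 5 km, stretch 2.5);
* NPP: `1e-4 · L` confined to the euphotic band (0–50 m);
* respiration: 50% of the plume NPP gain, on a vertical Gaussian centered at
  100 m (σ = 35 m) — the 50–150 m respiration band — displaced 8 km
  downstream of the source by the mean alongshore current;
* O2 and DIC follow respiration with fixed stoichiometry (O2:C = 150:106,
  C:N = 106:16) accumulated over a 30-day response timescale.

Circulation is a mean poleward alongshore current (0.15 m/s) with a weak
offshore drift (0.03 m/s) plus a seeded solenoidal eddy field (rms 0.05 m/s)
from a smoothed random streamfunction, divergence-free by construction and
tapered with depth. The eddy realization depends only on the seed, never on
the scenario, so scenario differences isolate the forcing exactly: CTRL
anomalies are identically zero, anomalies superpose linearly across
outfalls, and Bightwide NPP, offshore NH4 export, and aerobic habitat change
are strictly ordered by total DIN load. Concentrations are floored at zero;
the default amplitudes keep the floor inactive, which is what makes the
linearity exact rather than approximate.

The five built-in outfalls (4.0, 3.2, 3.0, 1.6, 0.4 × 10⁵ m³/d; secondary
effluent ~37–39 mg/L NH4 except one small plant already at 2/3 mg/L)
exercise the held-constant rule and give a ~49 t/d total DIN load.

**What passing tests do and do not show.** The generator has no momentum
equations, upwelling, El Niño variability, or plume rise physics; its
absolute NPP magnitudes are not calibrated to the real Bight (a
`productivity_multiplier` knob exists but is uncalibrated, so there is no
synthetic analogue of high- vs low-productivity years). Tests therefore
establish the *correctness of the arithmetic and the structural response*
(signs, orderings, closures, oracle equalities), not quantitative magnitudes
of real-ocean change, which require the full coupled model.

## Numerical details and degenerate inputs

* Missing value is NaN throughout; any arithmetic propagates it, and the
  missingness pattern is shared across fields (land/below-bottom).
* µmol/kg ↔ mmol/m³ conversions use the single reference density
  1025 kg/m³, recorded in file metadata.
* Flows accepted in m³/d or MGD (1 MGD = 3785.411784 m³/d), converted at
  read time.
* `ρ·r = 1` with a nonzero load is rejected (no discharge volume); empty
  outfall lists, degenerate all-land/all-ocean grids, windows below the
  deepest layer, flat bathymetry at the isobath target, and missing velocity
  on wet section faces all raise typed errors.
* Deterministic: identical (config, scenario, seed) inputs give identical
  outputs; the pipeline summary JSON contains no wall-clock information so
  repeat runs are byte-identical.

## Known limitations

* The per-species min rule under-counts nitrate in scenarios where real
  plants would nitrify (convert NH4 to NO3) to meet a tier; tier totals and
  recycling ratios are unaffected.
* Carbonate output omits the fugacity correction on pCO2 (< 0.5%) and NH3/HS
  alkalinity terms; the solver is not valid for freshwater (S < 0.5).
* Habitat metrics are single-stressor; no population dynamics, multi-stressor
  synergy, or food-availability modulation.
* The transport diagnostic reports fluxes on the staircase approximation to
  the isobath; no sigma-coordinate or curvilinear-grid support.
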