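# Methods

## The model

`colonsim` simulates carbohydrate fermentation in the human colon as a
one-dimensional advection–reaction system

∂t **c** + ∂x F(**c**) = R(**c**) + E(**c**)

for a concentration vector **c** (g/L) over two biochemical environments at
every axial position: the flowing **lumen** and a stationary, wall-bound
**mucus** layer fixed at 10% of total colon volume.  The three operators are

- **F — transport.**  Lumen material advects proximally→distally at constant
  velocity v = L/MTT (colon length over mean transit time); mucus material
  does not move.  Dietary fiber enters at the proximal boundary as meal
  pulses (default 30 g/day in three 15-minute meals at simulation-day hours
  0, 4 and 10).  The upper GIT is a mass-preserving black box: by default the
  pulse passes through unchanged; optionally it is smoothed through k
  first-order dilution tanks (an Erlang-shaped, still mass-preserving
  response).
- **R — digestion.**  A five-step anaerobic pathway: fiber is hydrolyzed to
  monomer sugar; sugar is fermented by sugar degraders (SD) to lactate,
  acetate, propionate, butyrate, H2, CO2 and water; lactate degraders (LD)
  ferment lactate further; hydrogenotrophic acetogens (HDA) and methanogens
  (HDM) respire dissolved H2 (consuming CO2) to acetate and methane.  Each
  of the four biomass functional groups (BFGs) also decays at a first-order
  rate, returning its mass to the particulate fiber pool.  Every process
  column of the stoichiometry matrix sums to zero on a mass basis (water and
  CO2 close the balances), so R conserves total mass identically.
- **E — exchange.**  First-order (linear) fluxes between compartments:
  biomass attaches (lumen→mucus) and detaches (mucus→lumen); sugar and the
  solutes (SCFAs, dissolved gases, fermentation water) diffuse toward equal
  concentrations; mucus fiber sloughs into the lumen; an endogenous mucin
  source produces fiber in the mucus at a constant rate; and the host absorbs
  SCFAs and dissolved gases from the lumen.  All transfers are
  volume-corrected so that transferred mass is conserved exactly; absorption
  and mucin production are the only system boundaries besides the two ends of
  the tube, and both are tracked in accumulators.

Each BFG can be expanded into *n* anonymous strains: kinetic variants whose
uptake rate k_m, half-saturation K_S, yield Y and decay rate k_dec carry
independent multipliers drawn from Uniform(1−δ, 1+δ) for a configured
biochemical deviation δ.  Stoichiometric product fractions are never
perturbed, preserving mass closure.  With δ = 0 an n-strain community
reproduces the single-strain group trajectories exactly (split invariance),
which is enforced by starting every group at the same total inoculum split
over its strains.

### State layout

The dissolved catalog has 14 components (fiber, sugar, lactate, acetate,
propionate, butyrate, dissolved H2/CH4/CO2, water, and one slot per BFG);
the gas-inclusive catalog adds H2/CH4/CO2 gas for 17.  Water counts only
fermentation-generated water; inflow water is not tracked.  Gas-phase
components are carried for state-count parity with the classical three-stage
formulation but have no sources (gas transfer kinetics are out of scope).
With two environments this gives 28 dissolved-only dependent variables per
location (34 gas-inclusive; 3 stages × 34 = 102 ODEs), indexed
environment-major in catalog order with strains ascending.

### Rate laws

- Hydrolysis (default): ρ = k_hyd·Z, first-order in fiber Z — the classical
  anaerobic-digestion default.  A biomass-limited Contois-type law
  ρ = k_hyd·Z·X_SD/(K_Z + Z + ε·X_SD) is config-selectable.  The first-order
  default is a deliberate choice: with biomass-limited hydrolysis the sugar
  supply scales with the local SD population, which gives the wall community
  a colonization threshold (an Allee effect); at fine spatial resolution the
  thin proximal mucus then cannot establish because its sugar leaks to the
  fast-flowing lumen faster than a small population can produce it.
- Uptake: Monod, ρ_j = k_m,j · S/(K_S,j + S) · X_j.  The hydrogenotrophic
  pathways carry an additional CO2 saturation factor CO2/(K_CO2 + CO2)
  (K_CO2 = 1e-4 g/L) because their catabolism co-consumes CO2; without it the
  co-consumed pool could be driven negative.
- Decay: ρ_j = k_dec,j · X_j.
- Negative concentrations are clamped to zero for rate evaluation only; an
  optional static acidity profile I(x) ∈ (0,1] multiplies hydrolysis and
  uptake rates.

## Parameters

All numeric values are data, shipped in
`src/colonsim/data/default_parameters.yaml` and overridable from config;
the engine hard-codes none of them.  The defaults that matter most:

| parameter | default | units | rationale |
|---|---|---|---|
| colon length / volume | 1.5 m / 1.67 L | — | standard human figures |
| mucus volume fraction | 0.10 | — | fixed-volume mucus layer |
| mean transit time | 24 | h | healthy colon (scenarios sweep 6–96 h) |
| k_hyd | 0.25 | 1/h | fiber half-life ~3 h against 24 h transit |
| k_m (SD/LD/HDA/HDM) | 2.5/2.0/1.5/2.0 | g/g/h | anaerobic-digestion order of magnitude |
| K_S (SD/LD) | 0.5/0.3 | g/L | Monod half-saturations |
| K_S (HDA/HDM) | 1e-4/5e-5 | g/L | dissolved H2 is scavenged to trace levels |
| Y (SD/LD/HDA/HDM) | 0.25/0.15/0.10/0.10 | g/g | gut-flora yields; a self-sustaining community needs growth ≥ loss at colonic transit |
| k_dec | 8.3e-4 | 1/h | 0.02/day, the classical decay rate |
| attach / detach | 0.05 / 0.2 | 1/h | detachment-dominated wall cycling keeps colon-average biomass at few-g/L digesta densities |
| sugar/solute diffusion | 0.5 | 1/h | lumen↔mucus equilibration within ~2 h |
| absorption (SCFA / gases) | 0.3 / 0.1 | 1/h | host uptake from the lumen |
| mucus production / slough | 0.05 g/L/h / 0.02 1/h | — | constant endogenous mucin source |
| initial biomass | 1.0 g/L per group | — | an established, colonized colon |

Yields and turnover were fixed by steady-state viability analysis, not by
fitting: the community must satisfy per-biomass growth ≥ per-biomass loss at
colonic dilution rates (washout otherwise), and the expressed fitness
difference between strains that differ by δ in their kinetics scales with
the community turnover rate — a maximally retentive biofilm would mute the
strain-level dynamics the multi-strain extension exists to study.

## Numerics

Both representations share one semi-discretization: first-order upwind
finite volumes on n cells are *identical* to an n-stage chain of stirred
tanks with stage dilution rate n/MTT.  `simulate_pfr` (n ≥ 51, the coarsest
supported grid) and `simulate_cstr_chain` (n = 1 or 3 classically) therefore
differ only in n and reporting, and a 3-cell grid must match the 3-stage
chain to solver tolerance — used as a cross-verification oracle in the test
suite.  Upwind was chosen over a higher-order central scheme deliberately:
it is positivity-preserving and makes the grid/stage identity exact.

The default integrator is a monolithic stiff method of lines: one BDF solve
over all cells with an analytic sparse Jacobian (dense within-cell reaction
blocks, a constant exchange operator recovered by probing the linear flux
function, constant upwind couplings).  Integration is segmented at boundary
discontinuities (meal edges, perturbation windows); within a segment the
square-pulse forcing is constant.  Tolerances default to rtol 1e-6 /
atol 1e-9 g/L.  A Strang operator-splitting mode (implicit reaction/exchange
halves around explicit upwind advection at CFL 0.9) is retained as
`method="split"`; it smears the meal spike over one advection step but
agrees with the monolithic solution in integral quantities and smooth
fields.

Boundary inflow, outflow, host absorption and mucin production are
integrated as quadrature states alongside the model, making the global mass
audit (inflow − outflow − absorbed + produced = Δ stored) a *linear
invariant* of the ODE system.  Linear multistep methods preserve linear
invariants exactly, so the audit closes to machine precision on every run —
a much stronger statement than an error-tolerance check, and any future
stoichiometry mistake would break it loudly at build time (columns are
checked to sum to zero).

Negative states are clipped to zero and logged; a run aborts if the clipped
mass exceeds 1e-6 of throughput.  Tightening rtol/atol tenfold moves the
day-56 outflow biomass share by far less than 0.1 percentage points.

## Scenario presets and statistics

- **Flow × fiber grid:** 15 scenarios, MTT ∈ {6,12,24,48,96} h × fiber ∈
  {15,30,45} g/day, 56 days, single strains.
- **Diet dropout:** a 10-week run at 30 g/day with zero-fiber periods
  (day pattern `14on,7off,14on,7off,14on,7off,7on` — the published pattern is
  figure-only, so the preset approximates it and is config-replaceable),
  with 1, 2, 5 or 10 SD strains at δ = 10%.
- **Community perturbation:** after a 56-day burn-in, the decay rate of the
  *dominant* SD strain (resolved at window start, volume-weighted over both
  environments, ties to the lowest strain id) is multiplied by 10 (the
  documented default factor; the source experiments never quantify the
  boost) for 0–10 days; the run continues 56 days past the window.  5 SD
  strains at δ = 1%.  The sweep runner shares the burn-in across window
  lengths — the forcing is 24 h-periodic, so branching from the stored state
  is exact.

Statistics: coarse composition classifies mass as fiber / biomass / sugar /
SCFA (lactate counted with the SCFAs by default; switchable) / others
(dissolved gases, water, gas phase).  %Biomass = biomass / total mass,
volume-weighted over both environments (lumen-only available).  %Deviation
between representations is (%B_D − %B_C)/%B_D with the stage solution
extrapolated piecewise-constant over equal blocks of the colon length;
positive values mean the stage model over-predicts.  Periodicity onset
compares consecutive whole-period windows in the sup norm relative to the
earlier window's sup norm (default tolerance 1%); recovery time is the first
lag after a perturbation window at which the outflow biomass share stays
within 5% (relative) of the pre-perturbation two-period-average orbit for a
full period.  Both tolerances are implementation choices, exposed in the
API.

## Problem sizes used in the shipped experiments

The periodic-regime measurement runs the continuous representation at grid
51 for 8 simulated weeks.  The perturbation sweep runs the 3-stage
representation (the study's discrete mode; both targets are desk-scale) for
a 52-day shared burn-in plus 11 branches of 4 + w + 56 days.  The
representation-comparison checks run 10-day windows of the 51-cell
continuous model against the 3-stage chain.  These sizes are the package's
own choices for routine verification; all horizons and grids are plain
arguments.

## What the defaults do and do not emulate

The synthetic community is an *established* colon ecosystem under a
controlled fiber-only diet: realistic in its transit times, meal forcing,
compartment volumes, digestion pathway and community-scale turnover, but
not calibrated to any measured subject.  Protein/lipid digestion, pH and
redox dynamics, gas-phase transfer, viscosity and peristalsis detail, host
immune coupling, and taxonomic identity are all out of scope; strains are
anonymous kinetic variants.  Consequently, passing tests demonstrate the
internal consistency of the model and the reproducibility of its emergent
community phenomena — not quantitative agreement with clinical
measurements.

## Known limitations

- First-order hydrolysis removes the enzyme-capacity memory that a
  biomass-limited (Contois) law would give; experiments that hinge on
  famine-recovery capacity are sensitive to this choice (the law is
  config-selectable per run).  In the diet-dropout experiment the
  single-strain outcome additionally depends on the strain's drawn
  parameter set: a marginally viable draw erodes across successive
  zero-fiber periods, a robust draw recovers fully each cycle.
- Dominance among strains at δ = 1% is decided by small expressed fitness
  gaps; which strain is dominant at day 56, and whether it returns after a
  knockdown, varies with the sampling seed.  The dominance-loss threshold is
  therefore reported per seed rather than as a universal constant (measured
  thresholds across seeds span "never regained" to 10 days).
- Under the default parameterization the 3-stage representation mostly
  *under*-predicts the volume-weighted biomass share relative to the
  continuous model once the regime has settled; the location of the largest
  discrepancy (distal third at fast transit, proximal third at standard
  transit) is the robust feature, the sign is parameterization-dependent.
- The upwind scheme is first-order accurate in space; sharp meal fronts are
  numerically diffused at coarse grids (quantified by the convergence test).
- The mucus layer has fixed volume; mucin production/sloughing do not feed
  back on geometry.
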