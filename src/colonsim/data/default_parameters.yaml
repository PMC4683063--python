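# Default parameter set for colonsim.
#
# These values are data, not code: the simulation engine reads whatever this
# file (or a user override) provides.  Physical defaults follow standard
# human-colon figures (length ~1.5 m, working volume ~1.7 L, mucus layer held
# at 10% of total volume, mean transit time 24 h).  Kinetic and
# stoichiometric values are plausible anaerobic-digestion figures in the
# classical tradition (uptake rates of a few g substrate per g biomass per
# hour, first-order decay of 0.02 per day), with yields and exchange
# turnover adapted to gut residence times so that an established community
# is self-sustaining (see docs/methods.md).  They are engineering defaults,
# intended to be replaced whenever calibrated values for a specific system
# are available.
# Units: concentrations g/L, time h, length m, volume L.

physical:
  colon_length: 1.5          # m
  total_volume: 1.67         # L, lumen + mucus
  mucus_volume_fraction: 0.10
  mean_transit_time: 24.0    # h; velocity = length / MTT

hydrolysis:
  # First-order fiber hydrolysis (the classical anaerobic-digestion default;
  # extracellular enzymes are plentiful in an established community) with a
  # half-life of ~3 h against a 24 h transit.  A biomass-limited Contois-type
  # law (rate = k_hyd * Z * X_SD / (K_Z + Z + eps_X * X_SD)) is selectable.
  k_hyd: 0.25                # 1/h
  K_Z: 0.5                   # g/L, fiber half-saturation (contois law only)
  eps_X: 0.5                 # biomass crowding weight (contois law only)
  law: first_order

groups:
  # k_m: g substrate / g biomass / h;  K_S: g/L;  Y: g biomass / g substrate;
  # k_dec: 1/h (0.02 per day, the classical anaerobic-digestion decay rate).
  # Yields sit at the gut-flora end of anaerobic figures: colonic communities
  # convert roughly a quarter of fermented carbohydrate into cell mass, and a
  # self-sustaining community requires per-biomass growth to exceed the
  # per-biomass loss rates at colonic transit times.
  SD:  {k_m: 2.5, K_S: 5.0e-1, Y: 0.25, k_dec: 8.3e-4}
  LD:  {k_m: 2.0, K_S: 3.0e-1, Y: 0.15, k_dec: 8.3e-4}
  HDA: {k_m: 1.5, K_S: 1.0e-4, Y: 0.10, k_dec: 8.3e-4}
  HDM: {k_m: 2.0, K_S: 5.0e-5, Y: 0.10, k_dec: 8.3e-4}

stoichiometry:
  # Mass fractions of catabolized substrate (the 1 - Y share) routed to each
  # product; each block sums to 1, water closing the balance.  Mixed-acid
  # splits typical of colonic fermentation.
  sd_products:
    lactate: 0.15
    acetate: 0.30
    propionate: 0.10
    butyrate: 0.15
    h2_dissolved: 0.03
    co2_dissolved: 0.22
    water: 0.05
  ld_products:
    acetate: 0.35
    propionate: 0.25
    butyrate: 0.15
    h2_dissolved: 0.02
    co2_dissolved: 0.18
    water: 0.05
  # Hydrogenotrophic catabolism, g per g of dissolved H2 consumed; negative
  # CO2 is co-consumed.  From 4 H2 + 2 CO2 -> CH3COOH + 2 H2O and
  # 4 H2 + CO2 -> CH4 + 2 H2O on a mass basis; net sums are 1 so that
  # stoichiometry columns sum to zero.
  hda_coeffs:
    co2_dissolved: -11.0
    acetate: 7.5
    water: 4.5
  hdm_coeffs:
    co2_dissolved: -5.5
    ch4_dissolved: 2.0
    water: 4.5

exchange:
  # First-order rates, 1/h, except mucus_production (g/L/h in the mucus).
  absorb:                    # lumen -> host removal
    scfa: 0.3
    solute_gas: 0.1
    sugar: 0.0
    water: 0.0
  # Attachment/detachment set the wall-residence of biomass and hence the
  # community turnover; detachment-dominated cycling keeps colon-average
  # biomass at the few-g/L densities seen in digesta rather than letting a
  # static biofilm accumulate.
  attach: 0.05               # biomass lumen -> mucus
  detach: 0.2                # biomass mucus -> lumen
  sugar_diffusion: 0.5       # sugar lumen <-> mucus
  solute_diffusion: 0.5      # SCFA / dissolved gas / water lumen <-> mucus
  mucus_production: 0.05     # endogenous mucin fiber source in mucus
  slough: 0.02               # mucus fiber -> lumen

numerics:
  grid_n: 51                 # coarsest spatial discretization
  rtol: 1.0e-6
  atol: 1.0e-9
  output_every: 1.0          # h
  cfl: 0.9
  clip_threshold: 1.0e-12
  max_clipped_fraction: 1.0e-6

initial:
  biomass_seed: 1.0          # g/L per strain, both environments: an
                             # established, densely colonized colon rather
                             # than a near-sterile inoculum

# Secondary CO2 half-saturation (g/L) limiting the hydrogenotrophic pathways
# so that co-consumed CO2 cannot be driven negative.
co2_limit_K: 1.0e-4

# Optional static acidity/inhibition profile I(x) in (0, 1], one value per
# grid cell (proximal first), multiplying hydrolysis and uptake rates.
inhibition_profile: null
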