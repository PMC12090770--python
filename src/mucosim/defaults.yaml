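# Scenario-file schema and defaults for mucosim.
#
# A scenario file is a single YAML document with the keys below.  Every key
# is optional except `species` and `metabolites`.  Defaults here mirror
# SimulationConfig (a unit test keeps the two in sync).
#
# Units: lengths um, time h, concentrations mM, fluxes mmol/gDW/h, mass pg.

name: scenario          # label used in logs and the run manifest
seed: 0                 # master RNG seed
nx: 20                  # lattice cells in x (domain width = nx * cell_size)
ny: 8                   # lattice cells in y
cell_size: 10.0         # um; lattice cells are cell_size x cell_size
max_biofilm_height: 60.0  # um; biomass whose sphere bottom exceeds this sloughs
slab_depth: 10.0        # um; third dimension of a cell, makes mM meaningful
rho_cell: 1.0           # pg/um^3; wet cell mass density (radius from mass)
dry_mass_fraction: 0.3  # gDW per g wet mass, converts agent mass to gDW
dt: 0.1                 # h per timestep
max_steps: 200          # hard step limit
steady_tol: 1.0e-3      # relative fluctuation tolerance for steady state
steady_window: 20       # sliding-window length (steps) for the steady test
step_length: 5.0        # um; planktonic move per step
rotation_sd: 30.0       # degrees; sd of the random heading rotation
shove_max_iter: 10      # cap on shoving sweeps per collision resolution
shove_tol: 1.0e-3       # um; overlap below this counts as mechanically resolved
planktonic_fba: true    # planktonic agents also feed from their local cell
fixed_point_coupling: false  # iterate fluxes <-> fields within a step
fixed_point_tol: 1.0e-3
fixed_point_max: 5
field_relaxation: 1.0  # <1 blends each step's fields with the previous step's
output_interval: 10     # steps between snapshot writes

# species: list of
#   species_id: producer            # unique id
#   gem:                            # one of:
#     builtin: producer             #   fixture builder (producer, consumer,
#     params: {}                    #   slowgrower, aerotolerant, toy_chain)
#     # path: model.xml             #   or an SBML / toy-JSON file
#     # inline: {...}               #   or an embedded toy-JSON model document
#   kinetics:                       # Michaelis-Menten uptake per metabolite
#     glucose: [10.0, 0.5]          #   [v_max mmol/gDW/h, K_m mM]
#   initial_count: 10
#   initial_mass: 4.0               # pg
#   division_radius: 2.0            # um; division above this radius
#   # division_mass: null           # pg; overrides the radius rule if set
species: []

# metabolites: list of
#   metabolite: glucose
#   D_bulk: 3.6e4                   # um^2/h bulk diffusivity
#   biofilm_factor: 0.6             # diffusivity multiplier inside biofilm
#   boundary:
#     top: [dirichlet, 10.0]        # dirichlet <mM> | neumann
#     bottom: [neumann, 0.0]        # neumann | dirichlet <mM> | robin <k_abs um/h>
metabolites: []
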