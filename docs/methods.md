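# Methods

`mucosim` simulates a mucosal microbial community as three coupled layers: a
2D agent layer of spherical bacteria, a finite-volume environment layer of
metabolite concentration fields, and a per-agent constraint-based metabolic
layer. This note records the model, its assumptions, the parameters that
matter, the numerical choices, and what the synthetic scenarios do and do
not demonstrate.

## Model overview

The domain is a vertical strip of the mucosal boundary layer: an impermeable
host surface at the bottom (y = 0), the lumen at the top, and periodic side
boundaries (the strip is a small window of a laterally extended layer).
Space is discretized into square lattice cells (10 um default) for the
metabolite fields; bacteria are off-lattice spheres.

Each timestep (default dt = 0.1 h) runs three phases in fixed order:

1. **Movement.** Unattached (planktonic) cells advance 5 um along their
   heading; the heading is then rotated by a normally distributed angle
   (default sd 30 degrees). A cell attaches on first contact with the bottom
   wall or with any attached cell; attached cells move only by mechanical
   pushing. Overlaps are relaxed by shoving (below).
2. **Solute equilibrium.** Agent biomass is rasterized to the lattice (each
   agent's mass to the cell containing its center). Every agent's uptake
   bounds are set from its own cell's concentrations by Michaelis–Menten
   kinetics, a parsimonious FBA is solved per agent, the resulting exchange
   fluxes become per-cell volumetric sources, and each metabolite field is
   re-solved to diffusive steady state.
3. **Growth and division.** Each agent grows exponentially at its own pFBA
   growth rate (m <- m e^{mu dt}), cells above the division size split into
   two equal offspring placed one child-radius from the parent center along
   a random direction, overlaps are relaxed again, and any cell whose sphere
   bottom exceeds the maximum biofilm height is sloughed (removed — shear
   loss to the lumen).

A run stops at a step limit or when every species' total biomass and every
metabolite's domain-mean concentration fluctuate by less than a relative
tolerance over a sliding window (defaults 1e-3 over 20 steps; the bundled
scenarios use 2%, the scale of single division/slough events at their
population sizes).

## Agent layer

Cells are spheres of wet density rho = 1 pg/um^3 (approximately water), so
radius follows mass: r = (3m / 4 pi rho)^(1/3). Division triggers on radius
(default threshold 2 um), configurable as a mass threshold instead; the size
threshold is deliberately length-typed since radius is the geometrically
meaningful size here.

**Shoving.** For every intersecting pair the displacement distance is
(r_a + r_b) − ||p_a − p_b|| (minimum image across the periodic sides).
Each member of the pair receives a push of half that distance along the
center line, pointing away from its neighbor; pushes from all neighbors
accumulate. Candidate positions are computed from the pre-sweep positions
for all agents at once (a Jacobi-style sweep, which makes the iteration
independent of agent order), then each agent moves from its old toward its
candidate position, stopping where it would cross the bottom wall. Sweeps
repeat until no overlap exceeds a tolerance or an iteration cap (default 10)
is reached; non-convergence is reported, not raised. Neighbor search uses a
KD-tree with ghost images across the periodic seam — an optimization with
output identical to the all-pairs computation. Coincident centers are
separated along a deterministic pseudo-random direction seeded by the agent
id pair.

**Two tolerances.** `resolve_collisions` defaults to a strict 1e-6 um
tolerance: when it reports convergence, effectively no overlap remains.
The simulation loop instead uses a *mechanical* tolerance of 1e-3 um
(config `shove_tol`): overlaps below ~0.1% of a cell radius (~1 nm) have no
mechanical meaning, and demanding their removal makes dense-bed relaxation
arbitrarily slow, because collective expansion propagates roughly one agent
layer per sweep. At the mechanical tolerance, a dense ~500-agent bed whose
nutrient-exposed surface layer has just grown (pair overlaps up to ~10% of
a radius) relaxes in a median of ~7 sweeps — the regime the iteration cap
of 10 is sized for. Deep insertions (a fresh division inside a
tangent-packed interior, overlap ~0.7 r) relax much more slowly under any
tolerance; in the coupled model they are rare because nutrient limitation
confines most growth and division to the biofilm surface, where free space
is adjacent.

## Environment layer

Each tracked metabolite i obeys the steady-state reaction–diffusion balance
div(D_i grad S_i) + R_i = 0, on the assumption that solutes relax much
faster than bacteria grow; no transient solve is performed. Discretization
is a conservative 5-point finite-volume stencil, periodic in x, with
harmonic-mean face diffusivities. Diffusivity is reduced to 0.6x bulk inside
the biofilm mask (cells holding any attached biomass). Boundary conditions
per metabolite:

* top — Dirichlet: a fixed lumen concentration for nutrients, zero for
  products diffusing away;
* bottom — zero-flux Neumann (default), Dirichlet (oxygen supplied by the
  vascularized submucosa; mm Hg converted at 1.3e-3 mM/mmHg, configurable),
  or a Robin absorptive sink with outflux k_abs * S (host uptake of SCFAs);
* sides — periodic.

The linear system is solved directly (sparse LU); with both boundaries
Neumann the system is singular and an error naming the metabolite is
raised. Verified properties: second-order convergence against the
closed-form quadratic profile for a uniform sink (error falls 4.0x per mesh
halving) and discrete flux-balance closure to machine precision.

**Over-consumption.** Uptake bounds are set from concentrations one
half-step stale, so the prescribed consumption can exceed what diffusion
supplies, which would drive the steady solution negative. Negative sources
in offending cells are damped by half and the system re-solved (up to 5
times), then any residual negative values are clamped to zero; clamp events
are counted and logged. This implements "consumption capped by local
supply" in steady-state form, where no per-step mass inventory exists.

**Units.** Concentrations mM, lengths um, time h, fluxes mmol/gDW/h. A 2D
cell is given a configurable slab depth (default 10 um, making cells
10x10x10 um^3 = 1 pL) so that source terms convert naturally:
R [mM/h] = flux x agent dry mass / cell volume. Agent wet mass (pg)
converts to dry weight by a configurable fraction (default 0.3).

## Metabolic layer

Each species carries a stoichiometric model with flux bounds and a biomass
objective (whatever reaction the input model designates). Per agent and per
step:

* **Uptake coupling.** For each exchange reaction whose environment
  metabolite has Michaelis–Menten parameters, the lower (uptake) bound is
  set to −v_max S / (K_m + S) at the agent's local concentration; secretion
  bounds are untouched; metabolites without kinetics keep the model's own
  bounds. Sign convention: exchange flux < 0 is uptake.
* **pFBA.** FBA maximizes the objective subject to S v = 0 and bounds; pFBA
  then minimizes total absolute flux at that optimum via the standard split
  into irreversible forward/backward pairs. LPs are assembled directly and
  solved with HiGHS (via `scipy.optimize.linprog`) with fixed options and
  variable ordering, so identical inputs give identical solutions. A full
  lexicographic tie-break among degenerate pFBA optima was considered and
  rejected: it costs O(n) extra LPs per agent per step; deterministic
  solver behavior already provides run-to-run reproducibility.
* **FVA.** Per-reaction minimum and maximum flux with the objective
  constrained to a fraction of its optimum (default 0.9, following common
  suboptimal-FVA practice).
* An infeasible per-agent LP (e.g., no usable substrate locally) yields
  zero growth and zero exchange for that agent in that step; the agent
  persists.

Agents of one species whose constraint vectors agree after rounding far
below solver tolerance (1e-9 relative) share a single LP solve — a pure
cache that leaves results unchanged while collapsing the saturated and
depleted regions onto a handful of solves.

## Coupling stability

The explicit scheme (fluxes from last step's fields, then one field solve)
develops a two-cycle when consumption rivals diffusive supply and local
concentrations sit on the Michaelis–Menten knee: high S -> large uptake
bound -> depleted solution -> small bound -> recovered S. Two damping
mechanisms are available:

* `fixed_point_coupling` — an in-step damped Picard loop (re-solve agent
  LPs on the updated fields, blend successive field iterates 50/50, up to
  `fixed_point_max` rounds). Effective but multiplies LP cost.
* `field_relaxation` (alpha < 1) — blend each step's solved fields with the
  previous step's, S <- alpha S_new + (1−alpha) S_old, at no extra LP cost.
  At a population plateau the blend converges to the same self-consistent
  field; during transients it introduces a lag of order (1−alpha) dt, far
  below the growth timescale. The bundled scenarios use alpha = 0.5.

## Synthetic scenarios (what they do and do not show)

The toy metabolic models have closed-form optima (growth = uptake x yield),
so every layer is testable against arithmetic. Scenario conditions were
chosen once, on physical grounds:

* Domain 160 x 80 um (16 x 8 cells), maximum biofilm height 40 um,
  30 cells per species seeded at 20 pg (r ~ 1.7 um), division at r = 2 um.
* Scenario growth yields give specific growth rates of ~0.2–0.5 1/h
  (doubling times 1.5–3.5 h, gut-bacterium scale) so that shoving and
  sloughing keep pace with division. The builder defaults keep the faster
  textbook yields (mu* = 5 at yield 0.5) for the LP oracle examples.
* The effective diffusivity (3.6e4 um^2/h) is scaled down with the domain:
  a microns-deep strip then develops the millimolar gradients a
  millimeters-deep mucosal layer would at molecular diffusivities. Uptake
  kinetics: v_max = 10 mmol/gDW/h, K_m = 0.5 mM for sugars/acids; oxygen
  K_m = 0.01 mM.
* `pair_crossfeed`: a glucose fermenter secreting acetate plus an acetate
  specialist that converts acetate to butyrate and grows only slowly on
  glucose. The butyrate producer's fate is thereby tied to cross-feeding —
  the defining feature of the biology this fixture mirrors — and its
  steady-state biomass exceeds a producer-free control by an order of
  magnitude.
* `two_region_oxygen`: the fermenter plus a facultative species whose
  respiration outyields fermentation, run under bottom-boundary oxygen of
  59 mm Hg (proximal small intestine analogue) versus 10 mm Hg (cecum
  analogue). Only the direction of the abundance contrast is meaningful.
* `triple_with_slow_grower` adds an acetate-consuming methanogen analogue
  with a very low biomass yield; it disperses rather than clustering.

These scenarios demonstrate the mechanisms (emergent cross-feeding, oxygen
niche separation, spatial flux heterogeneity), not gut physiology: real
communities have genome-scale models with thousands of reactions, tens of
tracked metabolites, mm-scale geometry, and measured kinetic parameters.
Passing tests show the machinery is correct and the qualitative contrasts
emerge from the coupled layers; they do not calibrate any quantity to in
vivo data.

## Analyses

* **Cross-feeding graph.** Mean exchange flux per (species, metabolite)
  across that species' agents; producers (mean > 0) route flux to consumers
  (mean < 0) proportionally; surplus flows to an explicit `environment`
  node and deficit flows from it, so per-metabolite bookkeeping closes
  exactly. Metabolites below a concentration threshold (default 0.1 mM) or
  on an exclusion list are omitted.
* **KDE maps.** Gaussian kernel density of agent positions, periodic in x
  (kernel images at +/- one domain width), Scott's-rule bandwidth by
  default, numerically normalized to integrate to 1 over the domain.
* **Per-agent suboptimal FVA and range shifts.** Each agent's last local
  constraints are re-applied and FVA run at 90% of its optimum. For each
  reaction, shift = max(spread of interval lower ends, spread of upper
  ends) across agents — zero iff all agents agree, and it reproduces the
  companion min-lower-bound / max-upper-bound summary. Reactions at or
  above the 95th percentile of shifts are flagged; an interval-width-spread
  alternative is available behind a flag is deliberately not the default.
* **Wilcoxon signed-rank.** Two-sided, zero differences removed, mid-ranks
  for ties; exact null distribution by dynamic programming over all 2^n
  sign assignments (ranks doubled to integers, so ties stay exact) for
  n <= 25, tie-corrected normal approximation with continuity correction
  beyond. The intended pairing for region comparisons is per-reaction
  summaries between two named runs; other pairings are the caller's choice.

## Known limitations

* 2D geometry with a slab-depth convention; no advection or shear flow, no
  pH, no EPS mechanics, no host immune feedback.
* The shoving cap of 10 sweeps leaves residual overlap in steps with heavy
  division; it is bounded (the same debt is re-attacked next step) but
  positions within a dense biofilm are approximate at the ~0.1 um scale.
* The explicit flux–field coupling is first-order in dt; `field_relaxation`
  trades a small transient lag for stability.
* Sloughing removes agents individually by height; detached-but-connected
  clusters are not tracked.
* GEM quality is the caller's responsibility: models are inputs, and no
  reconstruction, gap-filling, or biomass re-derivation is performed.
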