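"""Simulation time loop.

Each timestep runs three phases in fixed order:

1. **movement** — planktonic agents take a 5 um step with a randomly rotated
   heading, attach on contact with the wall or the biofilm, and overlaps are
   relaxed by shoving (at most 10 sweeps);
2. **solute equilibrium** — agent biomass is rasterized to the lattice, each
   agent's uptake bounds are set from its cell's metabolite concentrations
   (Michaelis–Menten), a parsimonious FBA is solved per agent (cached per
   species and identical constraint vector), exchange fluxes are accumulated
   into per-cell sources, and every metabolite field is re-solved to steady
   state;
3. **growth and division** — agents grow exponentially at their own pFBA
   growth rate, divide above the division size, overlaps are relaxed again,
   and biomass above the maximum biofilm height is sloughed.

A run ends at the step limit or when every species' total biomass and every
metabolite's domain-mean concentration fluctuate by less than a relative
tolerance over a sliding window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import agents as ag
from . import environment as env
from .agents import BacterialAgent, SpeciesSpec
from .environment import BoundarySpec, LatticeGrid, MetaboliteField  # noqa: F401 (re-exported)
from .gem_core import FluxResult, constrain_uptake, pfba

logger = logging.getLogger(__name__)


@dataclass
class MetaboliteSpec:
    """Scenario-level description of one tracked metabolite."""

    metabolite: str
    D_bulk: float                       # um^2/h
    boundary: BoundarySpec
    biofilm_factor: float = 0.6


@dataclass
class SimulationConfig:
    """Full scenario description."""

    species: List[SpeciesSpec]
    metabolites: List[MetaboliteSpec]
    nx: int = 20
    ny: int = 8
    cell_size: float = 10.0             # um
    max_biofilm_height: float = 60.0    # um
    slab_depth: float = 10.0            # um (third dimension of a cell)
    rho_cell: float = 1.0               # pg/um^3
    dry_mass_fraction: float = 0.3
    dt: float = 0.1                     # h
    max_steps: int = 200
    steady_tol: float = 1e-3
    steady_window: int = 20
    seed: int = 0
    step_length: float = 5.0            # um, planktonic move
    rotation_sd: float = 30.0           # degrees
    shove_max_iter: int = 10
    shove_tol: float = 1e-3             # um; mechanical overlap resolution
    planktonic_fba: bool = True         # planktonic agents also feed
    fixed_point_coupling: bool = False  # iterate fluxes<->fields in-step
    fixed_point_tol: float = 1e-3
    fixed_point_max: int = 5
    field_relaxation: float = 1.0       # <1: blend new fields with previous
                                        # step's (damps flux<->field cycling)
    output_interval: int = 10
    name: str = "scenario"

    def validate(self) -> None:
        errors = []
        if self.dt <= 0:
            errors.append("dt must be positive")
        if not self.species:
            errors.append("at least one species is required")
        if self.nx <= 0 or self.ny <= 0:
            errors.append("nx and ny must be positive")
        if self.max_biofilm_height <= 0:
            errors.append("max_biofilm_height must be positive")
        if self.max_biofilm_height > self.ny * self.cell_size:
            errors.append("max_biofilm_height exceeds the domain height")
        seen = set()
        for sp in self.species:
            if sp.species_id in seen:
                errors.append(f"duplicate species '{sp.species_id}'")
            seen.add(sp.species_id)
        for ms in self.metabolites:
            if ms.boundary is None:
                errors.append(
                    f"metabolite '{ms.metabolite}' has no boundary spec")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    @property
    def width(self) -> float:
        return self.nx * self.cell_size

    def species_by_id(self) -> Dict[str, SpeciesSpec]:
        return {sp.species_id: sp for sp in self.species}


@dataclass
class StepDiagnostics:
    """Bookkeeping recorded by each step."""

    phases: List[str] = field(default_factory=list)
    shove_iterations: Tuple[int, int] = (0, 0)
    growth_added_pg: float = 0.0
    sloughed_pg: float = 0.0
    lp_solves: int = 0
    lp_cache_hits: int = 0
    infeasible_agents: int = 0
    clamped_cells: int = 0


@dataclass
class SimulationState:
    """Full mutable world at one timestep."""

    timestep: int
    agents: List[BacterialAgent]
    grid: LatticeGrid
    fields: Dict[str, MetaboliteField]
    rng: np.random.Generator
    next_agent_id: int
    biomass_series: Dict[str, List[float]] = field(default_factory=dict)
    conc_series: Dict[str, List[float]] = field(default_factory=dict)
    last_fluxes: Dict[int, FluxResult] = field(default_factory=dict)
    last_growth: Dict[int, float] = field(default_factory=dict)
    diagnostics: StepDiagnostics = field(default_factory=StepDiagnostics)

    def total_biomass(self, species_id: Optional[str] = None) -> float:
        return ag.total_biomass(self.agents, species_id)

    def local_concentrations(self, agent: BacterialAgent
                             ) -> Dict[str, float]:
        ix, iy = self.grid.cell_of(agent.position)
        return {met: float(f.S[iy, ix]) for met, f in self.fields.items()}


def _append_series(state: SimulationState, config: SimulationConfig) -> None:
    for sp in config.species:
        state.biomass_series.setdefault(sp.species_id, []).append(
            state.total_biomass(sp.species_id))
    for met, f in state.fields.items():
        state.conc_series.setdefault(met, []).append(f.mean_concentration())


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def seed_initial(config: SimulationConfig,
                 rng: Optional[np.random.Generator] = None
                 ) -> SimulationState:
    """Place the configured number of agents per species uniformly at random
    (planktonic), relax overlaps once, and solve all fields with R = 0."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    grid = LatticeGrid(config.nx, config.ny, config.cell_size)
    width, height = grid.width, grid.height

    # close-packing sanity check (area fraction ~0.9 is already impossible)
    area = sum(math.pi * ag.radius_from_mass(sp.initial_mass,
                                             config.rho_cell) ** 2
               * sp.initial_count for sp in config.species)
    if area > 0.9 * width * height:
        raise ValueError(
            f"requested seeding density (area fraction "
            f"{area / (width * height):.2f}) exceeds close packing")

    agents: List[BacterialAgent] = []
    next_id = 0
    for sp in config.species:
        r0 = ag.radius_from_mass(sp.initial_mass, config.rho_cell)
        for _ in range(sp.initial_count):
            x = rng.uniform(0.0, width)
            y = rng.uniform(r0, height)
            theta = rng.uniform(0.0, 2.0 * math.pi)
            agents.append(BacterialAgent(
                id=next_id, species_id=sp.species_id,
                position=np.array([x, y]), mass=sp.initial_mass,
                rho_cell=config.rho_cell,
                direction=np.array([math.cos(theta), math.sin(theta)]),
                attached=False))
            next_id += 1
    ag.resolve_collisions(agents, width, config.shove_max_iter,
                          tol=config.shove_tol)

    fields: Dict[str, MetaboliteField] = {}
    for ms in config.metabolites:
        f = MetaboliteField(ms.metabolite, grid, ms.D_bulk, ms.boundary,
                            ms.biofilm_factor)
        D = env.diffusion_map(grid, ms.D_bulk, ms.biofilm_factor)
        env.solve_steady_state(f, D)
        fields[ms.metabolite] = f

    state = SimulationState(
        timestep=0, agents=agents, grid=grid, fields=fields, rng=rng,
        next_agent_id=next_id)
    _append_series(state, config)
    return state


# ---------------------------------------------------------------------------
# the three phases
# ---------------------------------------------------------------------------


def _movement_phase(state: SimulationState, config: SimulationConfig) -> None:
    planktonic = [a for a in state.agents if not a.attached]
    height = config.ny * config.cell_size
    for a in planktonic:
        ag.planktonic_move(a, state.rng, config.width,
                           config.step_length, config.rotation_sd,
                           domain_height=height)
    ag.attach_by_contact(state.agents, config.width)
    _, n_iter, _ = ag.resolve_collisions(
        state.agents, config.width, config.shove_max_iter,
        tol=config.shove_tol)
    ag.attach_by_contact(state.agents, config.width)
    state.diagnostics.shove_iterations = (
        n_iter, state.diagnostics.shove_iterations[1])


def _quantize_bounds(model) -> tuple:
    """Cache key from exchange lower bounds, rounded far below solver
    tolerance so physically identical constraint sets share one LP solve."""
    key = []
    for ex_id in sorted(model.exchange_map):
        lb = model.reaction(ex_id).lower_bound
        q = round(lb, 9) if abs(lb) < 1.0 else round(lb, 6)
        key.append((ex_id, q))
    return tuple(key)


def _solve_agent_fluxes(state: SimulationState, config: SimulationConfig
                        ) -> Tuple[List[FluxResult], Dict[int, float]]:
    """Per-agent pFBA under local Michaelis–Menten uptake bounds, with a
    per-(species, constraint-vector) cache."""
    specs = config.species_by_id()
    cache: Dict[tuple, FluxResult] = {}
    results: List[FluxResult] = []
    growth: Dict[int, float] = {}
    diag = state.diagnostics
    for a in state.agents:
        sp = specs[a.species_id]
        if not a.attached and not config.planktonic_fba:
            res = FluxResult({r.id: 0.0 for r in sp.gem.reactions},
                             0.0, "optimal")
            results.append(res)
            growth[a.id] = 0.0
            continue
        concs = state.local_concentrations(a)
        model = constrain_uptake(sp.gem, concs, sp.kinetics)
        key = (a.species_id, _quantize_bounds(model))
        if key in cache:
            res = cache[key]
            diag.lp_cache_hits += 1
        else:
            res = pfba(model)
            diag.lp_solves += 1
            if not res.optimal:
                # agent persists with zero growth and zero exchange
                diag.infeasible_agents += 1
                res = FluxResult({r.id: 0.0 for r in model.reactions},
                                 0.0, "infeasible")
            cache[key] = res
        results.append(res)
        growth[a.id] = max(res.growth_rate, 0.0)
    return results, growth


def _solute_phase(state: SimulationState, config: SimulationConfig) -> None:
    specs = config.species_by_id()
    models = {sid: sp.gem for sid, sp in specs.items()}
    env.rasterize(state.agents, state.grid, config.dry_mass_fraction)

    step_prev_S = {met: f.S.copy() for met, f in state.fields.items()}
    n_outer = config.fixed_point_max if config.fixed_point_coupling else 1
    prev_S = None
    for outer in range(n_outer):
        results, growth = _solve_agent_fluxes(state, config)
        sources = env.accumulate_sources(
            state.agents, results, models, state.grid,
            config.dry_mass_fraction, config.slab_depth)
        clamped = 0
        for met, f in state.fields.items():
            f.R = sources.get(met, np.zeros((state.grid.ny, state.grid.nx)))
            D = env.diffusion_map(state.grid, f.D_bulk, f.biofilm_factor)
            env.solve_steady_state(f, D)
            clamped += getattr(f, "_last_clamped", 0)
        state.diagnostics.clamped_cells = clamped
        if prev_S is not None:
            # damped Picard: plain iteration two-cycles when uptake sits on
            # the Michaelis-Menten knee, under-relaxation contracts it
            delta = 0.0
            for met, f in state.fields.items():
                blended = 0.5 * (prev_S[met] + f.S)
                scale = max(float(np.abs(blended).max()), 1e-12)
                delta = max(delta,
                            float(np.abs(blended - prev_S[met]).max())
                            / scale)
                f.S = blended
            if delta < config.fixed_point_tol:
                break
        prev_S = {met: f.S.copy() for met, f in state.fields.items()}
    alpha = config.field_relaxation
    if alpha < 1.0:
        # cross-step under-relaxation: damps the explicit-coupling
        # two-cycle at no extra LP cost; converges to the same
        # self-consistent field once the community stops changing
        for met, f in state.fields.items():
            f.S = alpha * f.S + (1.0 - alpha) * step_prev_S[met]
    state.last_fluxes = {a.id: r for a, r in zip(state.agents, results)}
    state.last_growth = growth


def _growth_phase(state: SimulationState, config: SimulationConfig) -> None:
    specs = config.species_by_id()
    added = 0.0
    for a in state.agents:
        mu = state.last_growth.get(a.id, 0.0)
        before = a.mass
        ag.grow(a, mu, config.dt)
        added += a.mass - before
    new_agents: List[BacterialAgent] = []
    for a in state.agents:
        sp = specs[a.species_id]
        offspring = ag.divide(a, state.rng, sp, state.next_agent_id,
                              config.width)
        if offspring is None:
            new_agents.append(a)
        else:
            state.next_agent_id += 2
            new_agents.extend(offspring)
    state.agents = new_agents
    _, n_iter, _ = ag.resolve_collisions(
        state.agents, config.width, config.shove_max_iter,
        tol=config.shove_tol)
    state.diagnostics.shove_iterations = (
        state.diagnostics.shove_iterations[0], n_iter)
    before_slough = ag.total_biomass(state.agents)
    state.agents, removed = ag.slough(state.agents,
                                      config.max_biofilm_height)
    if removed:
        logger.debug("step %d: sloughed %s", state.timestep, removed)
    state.diagnostics.growth_added_pg = added
    state.diagnostics.sloughed_pg = before_slough - ag.total_biomass(
        state.agents)


def step(state: SimulationState, config: SimulationConfig
         ) -> SimulationState:
    """Advance one timestep: movement -> solute equilibrium -> growth and
    division.  Errors are re-raised tagged with the failing phase."""
    state.diagnostics = StepDiagnostics()
    phases = (("movement", _movement_phase),
              ("solute", _solute_phase),
              ("growth_division", _growth_phase))
    for name, fn in phases:
        try:
            fn(state, config)
            state.diagnostics.phases.append(name)
        except Exception as exc:
            raise RuntimeError(
                f"step {state.timestep}, phase '{name}': {exc}") from exc
    state.timestep += 1
    _append_series(state, config)
    return state


# ---------------------------------------------------------------------------
# run loop
# ---------------------------------------------------------------------------


def _window_stable(series: Sequence[float], window: int, tol: float) -> bool:
    if len(series) < window + 1:
        return False
    tail = np.asarray(series[-(window + 1):])
    span = float(tail.max() - tail.min())
    scale = float(np.abs(tail).max())
    if scale == 0.0:
        return True
    return span / scale < tol


def is_steady(state: SimulationState, config: SimulationConfig) -> bool:
    """No significant fluctuation of any species' total biomass or any
    metabolite's domain-mean concentration over the sliding window."""
    for series in state.biomass_series.values():
        if not _window_stable(series, config.steady_window,
                              config.steady_tol):
            return False
    for series in state.conc_series.values():
        if not _window_stable(series, config.steady_window,
                              config.steady_tol):
            return False
    return True


@dataclass
class RunReport:
    steps: int
    steady: bool
    final_biomass: Dict[str, float]
    final_mean_conc: Dict[str, float]


def run(config: SimulationConfig,
        callback=None) -> Tuple[SimulationState, RunReport]:
    """Iterate :func:`step` until steady state or the step limit."""
    state = seed_initial(config)
    steady = False
    while state.timestep < config.max_steps:
        step(state, config)
        if callback is not None:
            callback(state)
        if is_steady(state, config):
            steady = True
            break
    report = RunReport(
        steps=state.timestep,
        steady=steady,
        final_biomass={sid: series[-1]
                       for sid, series in state.biomass_series.items()},
        final_mean_conc={met: series[-1]
                         for met, series in state.conc_series.items()},
    )
    logger.info("run '%s': %d steps, steady=%s", config.name,
                report.steps, steady)
    return state, report
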