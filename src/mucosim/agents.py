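"""Agent-based layer: spherical bacterial cells on a 2D domain.

Agents carry mass (pg), a radius derived from mass assuming constant cell
density, a position in um, and a planktonic heading.  The domain is periodic
in x, has an impermeable bottom wall at y = 0 (the epithelial/mucus surface),
and is open at the top (the lumen); biomass pushed above a configured maximum
biofilm height is sloughed away.

Overlaps created by growth, division, or movement are relaxed with an
iterative shoving scheme: every intersecting pair pushes each member half the
overlap apart along the center line, candidate positions are computed from
the old positions for all agents at once (Jacobi-style, order-independent),
and moves stop at the bottom wall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

#: default wet cell mass density, pg per um^3 (approximately water)
CELL_DENSITY = 1.0

#: overlap below which a configuration counts as resolved, um
SHOVE_TOL = 1e-6


def radius_from_mass(mass: float, rho_cell: float = CELL_DENSITY) -> float:
    """Sphere radius (um) from mass (pg) at cell density rho (pg/um^3)."""
    return (3.0 * mass / (4.0 * math.pi * rho_cell)) ** (1.0 / 3.0)


@dataclass
class BacterialAgent:
    """One spherical microbe."""

    id: int
    species_id: str
    position: np.ndarray          # (x, y) um
    mass: float                   # pg
    rho_cell: float = CELL_DENSITY
    direction: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0]))
    attached: bool = False
    radius: float = field(init=False)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.mass <= 0:
            raise ValueError(f"agent {self.id}: mass must be positive")
        self.radius = radius_from_mass(self.mass, self.rho_cell)

    def set_mass(self, mass: float) -> None:
        self.mass = mass
        self.radius = radius_from_mass(mass, self.rho_cell)


@dataclass
class SpeciesSpec:
    """Per-species parameter bundle used by the orchestrator."""

    species_id: str
    gem: object                        # GEMModel
    kinetics: object                   # UptakeKinetics
    initial_count: int = 10
    initial_mass: float = 4.0          # pg
    division_radius: float = 2.0       # um; division when radius exceeds this
    division_mass: Optional[float] = None  # pg; overrides radius if set
    label: str = ""

    def __post_init__(self) -> None:
        if self.division_mass is None:
            init_radius = radius_from_mass(self.initial_mass)
            if self.division_radius <= init_radius:
                raise ValueError(
                    f"{self.species_id}: division radius "
                    f"{self.division_radius} must exceed initial radius "
                    f"{init_radius:.3f}")
        elif self.division_mass <= self.initial_mass:
            raise ValueError(
                f"{self.species_id}: division mass must exceed initial mass")


# ---------------------------------------------------------------------------
# movement
# ---------------------------------------------------------------------------


def planktonic_move(agent: BacterialAgent, rng: np.random.Generator,
                    domain_width: float, step_length: float = 5.0,
                    rotation_sd: float = 30.0,
                    domain_height: Optional[float] = None
                    ) -> BacterialAgent:
    """Move an unattached agent one step: advance ``step_length`` um along
    its heading (x wrapped periodically, y stopped at the bottom wall), then
    rotate the heading by N(0, rotation_sd^2) degrees.  Touching the bottom
    wall attaches the agent.  When ``domain_height`` is given the move also
    stops at the domain ceiling (the modeled strip ends there; biomass above
    the biofilm height limit is removed by sloughing anyway)."""
    if agent.attached:
        raise ValueError(f"agent {agent.id} is attached; planktonic only")
    p = agent.position + step_length * agent.direction
    if p[1] < agent.radius:           # bottom wall contact -> attach
        p[1] = agent.radius
        agent.attached = True
    if domain_height is not None and p[1] > domain_height - agent.radius:
        p[1] = domain_height - agent.radius
    p[0] %= domain_width
    agent.position = p
    theta = math.radians(rng.normal(0.0, rotation_sd)) if rotation_sd > 0 \
        else 0.0
    c, s = math.cos(theta), math.sin(theta)
    dx, dy = agent.direction
    agent.direction = np.array([c * dx - s * dy, s * dx + c * dy])
    return agent


def _min_image_delta(pa: np.ndarray, pb: np.ndarray,
                     width: float) -> np.ndarray:
    """Displacement a - b under the minimum-image convention in x."""
    d = pa - pb
    d[0] -= width * round(d[0] / width)
    return d


def displacement_distance(a: BacterialAgent, b: BacterialAgent,
                          width: float) -> float:
    """(r_a + r_b) - center distance, minimum image in x.
    Positive iff the spheres intersect; coincident centers give r_a + r_b."""
    d = _min_image_delta(a.position.copy(), b.position, width)
    return a.radius + b.radius - float(np.hypot(d[0], d[1]))


# ---------------------------------------------------------------------------
# shoving
# ---------------------------------------------------------------------------


def _overlap_pairs(pos: np.ndarray, rad: np.ndarray, width: float,
                   tol: float = SHOVE_TOL) -> np.ndarray:
    """Index pairs (i, j) with positive overlap, periodic in x.

    Built with a KD-tree over the agents plus ghost images of agents near the
    periodic sides (spatial binning optimization; identical to all-pairs)."""
    n = len(pos)
    if n < 2:
        return np.empty((0, 2), dtype=int)
    rmax = float(rad.max())
    cut = 2.0 * rmax
    # ghost images across the periodic sides
    left = np.where(pos[:, 0] < cut)[0]
    right = np.where(pos[:, 0] > width - cut)[0]
    ghosts = np.concatenate([left, right])
    gpos = np.vstack([pos,
                      pos[left] + [width, 0.0],
                      pos[right] - [width, 0.0]]) if len(ghosts) else pos
    owner = np.concatenate([np.arange(n), ghosts]) if len(ghosts) \
        else np.arange(n)
    tree = cKDTree(gpos)
    raw = tree.query_pairs(cut, output_type="ndarray")
    if len(raw) == 0:
        return np.empty((0, 2), dtype=int)
    i, j = owner[raw[:, 0]], owner[raw[:, 1]]
    keep = i != j
    i, j = i[keep], j[keep]
    # dedupe (each ghost pair appears once per image)
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    pairs = np.unique(np.stack([lo, hi], axis=1), axis=0)
    d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
    d[:, 0] -= width * np.round(d[:, 0] / width)
    dist = np.hypot(d[:, 0], d[:, 1])
    overlap = rad[pairs[:, 0]] + rad[pairs[:, 1]] - dist
    return pairs[overlap > tol]


def _tiebreak_unit(id_a: int, id_b: int) -> np.ndarray:
    """Deterministic pseudo-random unit vector for coincident centers,
    seeded by the (unordered) agent-id pair."""
    seed = (min(id_a, id_b) * 1_000_003 + max(id_a, id_b)) % (2**31)
    ang = np.random.default_rng(seed).uniform(0.0, 2.0 * math.pi)
    return np.array([math.cos(ang), math.sin(ang)])


def shove_iteration(agents: Sequence[BacterialAgent], width: float,
                    tol: float = SHOVE_TOL) -> np.ndarray:
    """One Jacobi-style shoving sweep; returns the new position array.

    For every intersecting pair, each member receives a push of half the
    displacement distance along the center line, pointing away from the
    neighbor; agents then move from their old toward their candidate
    position, stopping where they would cross the bottom wall."""
    pos = np.array([a.position for a in agents], dtype=float)
    rad = np.array([a.radius for a in agents], dtype=float)
    n = len(agents)
    if n == 0:
        return pos
    push = np.zeros_like(pos)
    pairs = _overlap_pairs(pos, rad, width, tol)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        d = pos[i] - pos[j]
        d[:, 0] -= width * np.round(d[:, 0] / width)
        dist = np.hypot(d[:, 0], d[:, 1])
        coincident = dist < 1e-12
        overlap = rad[i] + rad[j] - dist
        unit = np.zeros_like(d)
        ok = ~coincident
        unit[ok] = d[ok] / dist[ok, None]
        for k in np.where(coincident)[0]:
            unit[k] = _tiebreak_unit(agents[i[k]].id, agents[j[k]].id)
            overlap[k] = rad[i[k]] + rad[j[k]]
        vec = 0.5 * overlap[:, None] * unit
        np.add.at(push, i, vec)
        np.add.at(push, j, -vec)
    cand = pos + push
    # wall stop: walk from old to candidate position, halt at y = radius
    new = cand.copy()
    for k in range(n):
        if cand[k, 1] < rad[k]:
            oy, cy = pos[k, 1], cand[k, 1]
            if oy > rad[k] and oy != cy:
                t = (oy - rad[k]) / (oy - cy)
                new[k] = pos[k] + t * (cand[k] - pos[k])
            new[k, 1] = rad[k]
    new[:, 0] %= width
    return new


def resolve_collisions(agents: List[BacterialAgent], width: float,
                       max_iter: int = 10,
                       tol: float = SHOVE_TOL) -> Tuple[List[BacterialAgent],
                                                        int, bool]:
    """Iterate :func:`shove_iteration` until no overlap above ``tol``
    remains or ``max_iter`` sweeps have run.  Positions are updated in
    place; masses are untouched.  Returns (agents, iterations, converged)."""
    if not agents:
        return agents, 0, True
    pos = np.array([a.position for a in agents], dtype=float)
    rad = np.array([a.radius for a in agents], dtype=float)
    it = 0
    converged = len(_overlap_pairs(pos, rad, width, tol)) == 0 and \
        bool(np.all(pos[:, 1] >= rad - tol))
    while not converged and it < max_iter:
        new = shove_iteration(agents, width, tol)
        for a, p in zip(agents, new):
            a.position = p
        pos = new
        it += 1
        converged = len(_overlap_pairs(pos, rad, width, tol)) == 0 and \
            bool(np.all(pos[:, 1] >= rad - tol))
    return agents, it, converged


def attach_by_contact(agents: Sequence[BacterialAgent], width: float,
                      tol: float = 1e-9) -> int:
    """Attach planktonic agents touching the bottom wall or any attached
    agent; contact propagates within one call (breadth-first over touching
    pairs).  Returns how many agents newly attached."""
    n = len(agents)
    if n == 0:
        return 0
    n_new = 0
    frontier = []
    for idx, a in enumerate(agents):
        if not a.attached and a.position[1] <= a.radius + tol:
            a.attached = True
            n_new += 1
            frontier.append(idx)
        elif a.attached:
            frontier.append(idx)
    if not any(not a.attached for a in agents):
        return n_new
    pos = np.array([a.position for a in agents], dtype=float)
    rad = np.array([a.radius for a in agents], dtype=float)
    # touching = overlapping within tol; reuse the overlap pair machinery
    pairs = _overlap_pairs(pos, rad, width, -tol)
    neighbors: Dict[int, List[int]] = {}
    for i, j in pairs:
        neighbors.setdefault(int(i), []).append(int(j))
        neighbors.setdefault(int(j), []).append(int(i))
    while frontier:
        i = frontier.pop()
        for j in neighbors.get(i, ()):
            if not agents[j].attached:
                agents[j].attached = True
                n_new += 1
                frontier.append(j)
    return n_new


# ---------------------------------------------------------------------------
# growth, division, sloughing
# ---------------------------------------------------------------------------


def grow(agent: BacterialAgent, growth_rate: float, dt: float
         ) -> BacterialAgent:
    """Exponential mass increase: m <- m * exp(mu * dt); radius follows."""
    if growth_rate < 0:
        raise ValueError(f"agent {agent.id}: negative growth rate")
    agent.set_mass(agent.mass * math.exp(growth_rate * dt))
    return agent


def divide(agent: BacterialAgent, rng: np.random.Generator,
           spec: SpeciesSpec, next_id: int, domain_width: float
           ) -> Optional[Tuple[BacterialAgent, BacterialAgent]]:
    """Split an agent exceeding its division size into two equal offspring
    placed at the parent's center +/- r_child along a random unit vector.
    Returns None when below threshold."""
    if spec.division_mass is not None:
        if agent.mass <= spec.division_mass:
            return None
    elif agent.radius <= spec.division_radius:
        return None
    half = agent.mass / 2.0
    r_child = radius_from_mass(half, agent.rho_cell)
    ang = rng.uniform(0.0, 2.0 * math.pi)
    offset = r_child * np.array([math.cos(ang), math.sin(ang)])
    children = []
    for k, sgn in enumerate((1.0, -1.0)):
        p = agent.position + sgn * offset
        p[0] %= domain_width
        p[1] = max(p[1], r_child)   # stay above the wall; shoving tidies up
        child = BacterialAgent(
            id=next_id + k, species_id=agent.species_id, position=p,
            mass=half, rho_cell=agent.rho_cell,
            direction=agent.direction.copy(), attached=agent.attached)
        children.append(child)
    return children[0], children[1]


def slough(agents: Sequence[BacterialAgent], max_height: float
           ) -> Tuple[List[BacterialAgent], Dict[str, int]]:
    """Remove agents whose sphere bottom (y - r) exceeds the maximum biofilm
    height; returns (survivors, removal counts per species)."""
    if max_height <= 0:
        raise ValueError("max_height must be positive")
    kept: List[BacterialAgent] = []
    removed: Dict[str, int] = {}
    for a in agents:
        if a.position[1] - a.radius > max_height:
            removed[a.species_id] = removed.get(a.species_id, 0) + 1
        else:
            kept.append(a)
    return kept, removed


def total_biomass(agents: Sequence[BacterialAgent],
                  species_id: Optional[str] = None) -> float:
    """Summed agent mass in pg, optionally for one species."""
    return sum(a.mass for a in agents
               if species_id is None or a.species_id == species_id)
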