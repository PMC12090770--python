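"""Finite-volume layer: metabolite fields on the lattice.

Metabolite concentrations S_i (mM) obey the steady-state reaction-diffusion
balance  div(D_i grad S_i) + R_i = 0  on a regular 2D lattice (10 um cells by
default), periodic in x, with per-metabolite boundary conditions on the top
(lumen) and bottom (mucosa/epithelium) edges:

* top: Dirichlet — a fixed inflow concentration for nutrients, or zero for
  fermentation products diffusing away into the lumen;
* bottom: zero-flux Neumann (default), Dirichlet (e.g. oxygen supplied by the
  vascularized submucosa), or a Robin-type absorptive sink with flux
  k_abs * S (host uptake of SCFAs).

Diffusivity is reduced inside the biofilm (default 0.6x bulk); face values
use the harmonic mean of the adjacent cells.  Sources R_i come from the
per-agent exchange fluxes of the metabolic layer, rasterized per cell.

Solutes are assumed to relax much faster than bacteria grow, so each timestep
solves the steady-state system directly (sparse LU) rather than a transient
equation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .gem_core import SingularSystemError, exchange_fluxes

logger = logging.getLogger(__name__)

#: pg -> g
PG_TO_G = 1e-12
#: um^3 -> L
UM3_TO_L = 1e-15


@dataclass
class LatticeGrid:
    """Regular lattice of square cells; index order arrays[iy, ix]."""

    nx: int
    ny: int
    cell_size: float = 10.0   # um
    biofilm_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.biofilm_mask is None:
            self.biofilm_mask = np.zeros((self.ny, self.nx), dtype=bool)

    @property
    def width(self) -> float:
        return self.nx * self.cell_size

    @property
    def height(self) -> float:
        return self.ny * self.cell_size

    def cell_of(self, position: Sequence[float]) -> Tuple[int, int]:
        """(ix, iy) of the cell containing a point; x wrapped periodically."""
        x = position[0] % self.width
        ix = min(int(x / self.cell_size), self.nx - 1)
        iy = int(position[1] / self.cell_size)
        if not (0 <= iy < self.ny):
            raise ValueError(f"position {tuple(position)} outside grid "
                             f"(height {self.height})")
        return ix, iy

    def cell_volume_L(self, slab_depth: float) -> float:
        """Volume of one cell in liters for a slab of given depth (um)."""
        return self.cell_size * self.cell_size * slab_depth * UM3_TO_L


@dataclass
class BoundarySpec:
    """Top/bottom boundary conditions; sides are always periodic.

    kinds: 'dirichlet' (value = concentration, mM), 'neumann' (zero flux),
    'robin' (bottom only; value = absorption rate k_abs, um/h, flux out
    k_abs * S)."""

    top_kind: str = "dirichlet"
    top_value: float = 0.0
    bottom_kind: str = "neumann"
    bottom_value: float = 0.0

    def __post_init__(self) -> None:
        if self.top_kind not in ("dirichlet", "neumann"):
            raise ValueError(f"unknown top boundary kind '{self.top_kind}'")
        if self.bottom_kind not in ("dirichlet", "neumann", "robin"):
            raise ValueError(
                f"unknown bottom boundary kind '{self.bottom_kind}'")


@dataclass
class MetaboliteField:
    """One metabolite's concentration field and source term."""

    metabolite: str
    grid: LatticeGrid
    D_bulk: float                    # um^2 / h
    boundary: BoundarySpec
    biofilm_factor: float = 0.6
    S: np.ndarray = field(default=None)   # mM, (ny, nx)
    R: np.ndarray = field(default=None)   # mM / h, (ny, nx)

    def __post_init__(self) -> None:
        if self.D_bulk <= 0:
            raise ValueError(f"{self.metabolite}: D_bulk must be positive")
        if not (0.0 < self.biofilm_factor <= 1.0):
            raise ValueError(
                f"{self.metabolite}: biofilm_factor must be in (0, 1]")
        shape = (self.grid.ny, self.grid.nx)
        if self.S is None:
            self.S = np.zeros(shape)
        if self.R is None:
            self.R = np.zeros(shape)

    def mean_concentration(self) -> float:
        return float(self.S.mean())


# ---------------------------------------------------------------------------
# rasterization and sources
# ---------------------------------------------------------------------------


def rasterize(agents: Sequence, grid: LatticeGrid,
              dry_mass_fraction: float = 0.3) -> Dict[str, np.ndarray]:
    """Per-species dry biomass (gDW) per lattice cell; each agent's mass is
    assigned to the cell containing its center.  Also refreshes
    ``grid.biofilm_mask`` (cells holding any attached biomass)."""
    fields: Dict[str, np.ndarray] = {}
    mask = np.zeros((grid.ny, grid.nx), dtype=bool)
    for a in agents:
        ix, iy = grid.cell_of(a.position)
        arr = fields.setdefault(
            a.species_id, np.zeros((grid.ny, grid.nx)))
        arr[iy, ix] += a.mass * PG_TO_G * dry_mass_fraction
        if a.attached:
            mask[iy, ix] = True
    grid.biofilm_mask = mask
    return fields


def accumulate_sources(agents: Sequence, flux_results: Sequence,
                       models: Mapping[str, object], grid: LatticeGrid,
                       dry_mass_fraction: float = 0.3,
                       slab_depth: float = 10.0) -> Dict[str, np.ndarray]:
    """Net volumetric source R (mM/h) per metabolite per cell from per-agent
    exchange fluxes: flux (mmol/gDW/h) x agent dry mass (gDW) / cell volume
    (L).  Uptake (flux < 0) yields negative R."""
    if len(agents) != len(flux_results):
        raise ValueError("one FluxResult per agent required")
    vol = grid.cell_volume_L(slab_depth)
    out: Dict[str, np.ndarray] = {}
    for agent, res in zip(agents, flux_results):
        ix, iy = grid.cell_of(agent.position)
        gdw = agent.mass * PG_TO_G * dry_mass_fraction
        model = models[agent.species_id]
        for met, v in exchange_fluxes(model, res).items():
            if v == 0.0:
                continue
            arr = out.setdefault(met, np.zeros((grid.ny, grid.nx)))
            arr[iy, ix] += v * gdw / vol
    return out


def diffusion_map(grid: LatticeGrid, D_bulk: float,
                  biofilm_factor: float = 0.6) -> np.ndarray:
    """Per-cell diffusivity: biofilm_factor * D_bulk inside the biofilm mask,
    D_bulk elsewhere."""
    D = np.full((grid.ny, grid.nx), D_bulk, dtype=float)
    D[grid.biofilm_mask] = biofilm_factor * D_bulk
    return D


def harmonic_mean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Face diffusivity between adjacent cells."""
    return 2.0 * a * b / (a + b)


# ---------------------------------------------------------------------------
# steady-state solve
# ---------------------------------------------------------------------------


def _assemble(field: MetaboliteField, D: np.ndarray, R: np.ndarray):
    """Sparse linear system A s = b for the 5-point FVM stencil, periodic in
    x.  Every cell equation is the flux balance multiplied by h^2 so that
    row sums telescope for the conservation check."""
    grid = field.grid
    nx, ny, h = grid.nx, grid.ny, grid.cell_size
    bc = field.boundary
    n = nx * ny

    def k(ix: int, iy: int) -> int:
        return iy * nx + ix

    rows: List[int] = []
    cols: List[int] = []
    vals: List[float] = []
    b = np.zeros(n)

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for iy in range(ny):
        for ix in range(nx):
            me = k(ix, iy)
            diag = 0.0
            # x neighbors (periodic)
            for jx in ((ix - 1) % nx, (ix + 1) % nx):
                Df = harmonic_mean(D[iy, ix], D[iy, jx])
                add(me, k(jx, iy), Df)
                diag -= Df
            # y- (bottom)
            if iy > 0:
                Df = harmonic_mean(D[iy, ix], D[iy - 1, ix])
                add(me, k(ix, iy - 1), Df)
                diag -= Df
            else:
                if bc.bottom_kind == "dirichlet":
                    diag -= 2.0 * D[iy, ix]
                    b[me] -= 2.0 * D[iy, ix] * bc.bottom_value
                elif bc.bottom_kind == "robin":
                    # outflux k_abs * S through the face of length h;
                    # scaled by h to match the h^2-multiplied balance
                    diag -= bc.bottom_value * h
                # neumann: no flux term
            # y+ (top)
            if iy < ny - 1:
                Df = harmonic_mean(D[iy, ix], D[iy + 1, ix])
                add(me, k(ix, iy + 1), Df)
                diag -= Df
            else:
                if bc.top_kind == "dirichlet":
                    diag -= 2.0 * D[iy, ix]
                    b[me] -= 2.0 * D[iy, ix] * bc.top_value
                # neumann top: no term
            add(me, me, diag)
            b[me] -= R[iy, ix] * h * h
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return A, b


def _is_singular_setup(field: MetaboliteField) -> bool:
    bc = field.boundary
    return bc.top_kind == "neumann" and bc.bottom_kind == "neumann"


def solve_steady_state(field: MetaboliteField, D: np.ndarray,
                       max_rescue: int = 5) -> np.ndarray:
    """Solve div(D grad S) + R = 0 on the lattice with the field's boundary
    spec.  Negative concentrations caused by over-consumption are handled by
    damping the negative sources in offending cells and re-solving (up to
    ``max_rescue`` times), then clamping at zero; clamp events are logged.
    Updates and returns ``field.S``."""
    if _is_singular_setup(field):
        net = float(field.R.sum())
        if abs(net) > 0:
            raise SingularSystemError(
                f"metabolite '{field.metabolite}': all-Neumann boundaries "
                f"with nonzero net source {net:.3g} mM/h have no steady "
                f"state")
        raise SingularSystemError(
            f"metabolite '{field.metabolite}': all-Neumann boundaries give "
            f"a singular system (concentration level undetermined)")
    R = field.R.copy()
    S = None
    for attempt in range(max_rescue + 1):
        A, b = _assemble(field, D, R)
        S = spsolve(A, b).reshape(field.grid.ny, field.grid.nx)
        neg = S < -1e-9
        if not neg.any():
            break
        # over-consumption: damp uptake where the solution went negative
        scale = np.ones_like(R)
        scale[neg & (R < 0)] = 0.5
        if np.all(scale == 1.0):
            break
        R = R * scale
        logger.debug("%s: damping consumption in %d cells (attempt %d)",
                     field.metabolite, int((scale != 1).sum()), attempt + 1)
    n_clamped = int((S < 0).sum())
    if n_clamped:
        logger.info("%s: clamped %d negative cells (min %.3g mM)",
                    field.metabolite, n_clamped, float(S.min()))
    field.S = np.maximum(S, 0.0)
    field._last_effective_R = R  # for conservation diagnostics
    field._last_clamped = n_clamped
    return field.S


def conservation_residual(field: MetaboliteField, D: np.ndarray,
                          R: Optional[np.ndarray] = None) -> float:
    """Relative closure of the discrete flux balance: boundary fluxes plus
    total source, normalized by the largest flux magnitude.  Zero (to solver
    precision) when no clamping occurred."""
    grid = field.grid
    h = grid.cell_size
    bc = field.boundary
    S = field.S
    if R is None:
        R = getattr(field, "_last_effective_R", field.R)
    source_total = float(R.sum()) * h * h
    boundary_total = 0.0
    # top
    if bc.top_kind == "dirichlet":
        boundary_total += float(
            np.sum(2.0 * D[-1, :] * (bc.top_value - S[-1, :])))
    if bc.bottom_kind == "dirichlet":
        boundary_total += float(
            np.sum(2.0 * D[0, :] * (bc.bottom_value - S[0, :])))
    elif bc.bottom_kind == "robin":
        boundary_total -= float(np.sum(bc.bottom_value * h * S[0, :]))
    total = boundary_total + source_total
    scale = max(abs(source_total), abs(boundary_total), 1e-300)
    return abs(total) / scale
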