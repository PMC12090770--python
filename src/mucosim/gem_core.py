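"""Constraint-based metabolic layer.

Each bacterial agent carries a stoichiometric model (a genome-scale metabolic
model, GEM, or a small hand-built analogue).  Growth and exchange fluxes are
obtained by linear programming under the steady-state mass-balance assumption
``S @ v = 0`` with flux bounds:

* :func:`fba` maximizes the biomass objective (flux balance analysis),
* :func:`pfba` additionally minimizes total absolute flux at the optimum
  (parsimonious FBA, via the standard irreversible flux split),
* :func:`fva` computes per-reaction flux ranges with the objective held at a
  fraction of its optimum (flux variability analysis),
* :func:`constrain_uptake` couples a model to its local environment by setting
  Michaelis–Menten uptake bounds on exchange reactions.

Sign convention (community standard): exchange flux < 0 is uptake from the
environment, > 0 is secretion into it.

Units: fluxes in mmol·gDW⁻¹·h⁻¹ (the biomass reaction in h⁻¹), concentrations
in mM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

#: infinity-norm tolerance on the mass-balance residual of an optimal solution
MASS_BALANCE_TOL = 1e-6

#: default bound magnitude treated as "unbounded" when exporting/importing
DEFAULT_BOUND = 1000.0

_LINPROG_OPTIONS = {"presolve": True}


class ModelValidationError(ValueError):
    """A structurally malformed model (distinct from LP infeasibility)."""


class SingularSystemError(RuntimeError):
    """Raised by the environment layer for unsolvable boundary setups."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Reaction:
    """One reaction: signed stoichiometry and flux bounds.

    ``stoichiometry`` maps metabolite id -> coefficient (negative = consumed).
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: Optional[str] = None

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoichiometry),
                        self.lower_bound, self.upper_bound, self.gpr)


@dataclass
class GEMModel:
    """A stoichiometric model with a biomass objective and exchange mapping.

    ``exchange_map`` maps exchange-reaction id -> environment metabolite id;
    only metabolites appearing here are coupled to the extracellular fields.
    """

    species_id: str
    metabolites: list
    reactions: list
    objective_id: str
    exchange_map: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {r.id: i for i, r in enumerate(self.reactions)}

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._index[rxn_id]]

    @property
    def reaction_ids(self) -> list:
        return [r.id for r in self.reactions]

    def copy(self) -> "GEMModel":
        return GEMModel(
            self.species_id,
            list(self.metabolites),
            [r.copy() for r in self.reactions],
            self.objective_id,
            dict(self.exchange_map),
        )

    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on structural defects."""
        met_set = set(self.metabolites)
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ModelValidationError(
                f"{self.species_id}: duplicate reaction ids")
        for rxn in self.reactions:
            unknown = set(rxn.stoichiometry) - met_set
            if unknown:
                raise ModelValidationError(
                    f"{self.species_id}/{rxn.id}: undeclared metabolites "
                    f"{sorted(unknown)}")
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"{self.species_id}/{rxn.id}: lower_bound "
                    f"{rxn.lower_bound} > upper_bound {rxn.upper_bound}")
        if self.objective_id not in self._index:
            raise ModelValidationError(
                f"{self.species_id}: objective reaction "
                f"'{self.objective_id}' not declared")
        for ex_id, met in self.exchange_map.items():
            if ex_id not in self._index:
                raise ModelValidationError(
                    f"{self.species_id}: exchange_map key '{ex_id}' is not "
                    f"a declared reaction")
            stoich = self.reaction(ex_id).stoichiometry
            if len(stoich) != 1:
                raise ModelValidationError(
                    f"{self.species_id}/{ex_id}: exchange reactions must "
                    f"have exactly one metabolite participant, got "
                    f"{sorted(stoich)}")

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S matrix, metabolites x reactions (small models only)."""
        met_idx = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                S[met_idx[met], j] = coef
        return S


@dataclass
class FluxResult:
    """One LP solution: per-reaction fluxes and the growth rate mu (h^-1)."""

    fluxes: Dict[str, float]
    growth_rate: float
    status: str  # "optimal" | "infeasible"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAResult:
    """Per-reaction flux intervals at a given objective fraction."""

    intervals: Dict[str, Tuple[float, float]]
    fraction: float


class MichaelisMenten(NamedTuple):
    """Saturation kinetics of one uptake: v = v_max * S / (K_m + S)."""

    v_max: float  # mmol·gDW^-1·h^-1, > 0
    K_m: float    # mM, > 0


class UptakeKinetics:
    """Per-species mapping of environment metabolite -> Michaelis–Menten
    uptake parameters.  Metabolites without an entry keep the model's own
    default uptake bound."""

    def __init__(self, params: Mapping[str, Tuple[float, float]]):
        self.params: Dict[str, MichaelisMenten] = {}
        for met, pair in params.items():
            mm = MichaelisMenten(*pair)
            if not (mm.v_max > 0 and mm.K_m > 0):
                raise ValueError(
                    f"kinetics for '{met}': v_max and K_m must be positive, "
                    f"got {mm}")
            self.params[met] = mm

    def __contains__(self, met: str) -> bool:
        return met in self.params

    def __getitem__(self, met: str) -> MichaelisMenten:
        return self.params[met]

    def items(self):
        return self.params.items()


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------


def _lp_arrays(model: GEMModel):
    """Equality system S v = 0 and bound list for linprog."""
    S = model.stoichiometric_matrix()
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    return S, bounds


def _run_lp(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs", options=_LINPROG_OPTIONS)
    return res


def _infeasible(model: GEMModel) -> FluxResult:
    return FluxResult({r.id: 0.0 for r in model.reactions}, 0.0, "infeasible")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def fba(model: GEMModel) -> FluxResult:
    """Maximize the biomass objective subject to S v = 0 and flux bounds."""
    model.validate()
    S, bounds = _lp_arrays(model)
    n = len(model.reactions)
    c = np.zeros(n)
    c[model._index[model.objective_id]] = -1.0  # linprog minimizes
    res = _run_lp(c, S, np.zeros(S.shape[0]), bounds)
    if not res.success:
        return _infeasible(model)
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    mu = fluxes[model.objective_id]
    return FluxResult(fluxes, mu, "optimal")


def pfba(model: GEMModel) -> FluxResult:
    """Parsimonious FBA: among FBA-optimal solutions, minimize total
    absolute flux (l1 norm), via splitting every reaction into an
    irreversible forward/backward pair."""
    base = fba(model)
    if not base.optimal:
        return base
    mu = base.growth_rate

    S, bounds = _lp_arrays(model)
    m, n = S.shape
    # v = v_plus - v_minus with v_plus in [max(l,0), max(u,0)],
    # v_minus in [max(-u,0), max(-l,0)]
    split_bounds = []
    for (lo, hi) in bounds:
        split_bounds.append((max(lo, 0.0), max(hi, 0.0)))
    for (lo, hi) in bounds:
        split_bounds.append((max(-hi, 0.0), max(-lo, 0.0)))
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(m)
    # pin the objective at its FBA optimum
    obj_row = np.zeros(2 * n)
    j = model._index[model.objective_id]
    obj_row[j] = 1.0
    obj_row[n + j] = -1.0
    A_eq = np.vstack([A_eq, obj_row])
    b_eq = np.append(b_eq, mu)
    c = np.ones(2 * n)
    res = _run_lp(c, A_eq, b_eq, split_bounds)
    if not res.success:  # pragma: no cover - optimum is feasible by constr.
        logger.warning("%s: pFBA stage infeasible, falling back to FBA",
                       model.species_id)
        return base
    v = res.x[:n] - res.x[n:]
    fluxes = {r.id: float(x) for r, x in zip(model.reactions, v)}
    return FluxResult(fluxes, float(fluxes[model.objective_id]), "optimal")


def fva(model: GEMModel, fraction: float = 0.9,
        reaction_ids: Optional[Sequence[str]] = None) -> FVAResult:
    """Flux variability analysis: per-reaction min/max flux with the
    objective constrained to ``fraction`` of its FBA optimum."""
    if not (0.0 < fraction <= 1.0):
        raise ModelValidationError(
            f"fva fraction must be in (0, 1], got {fraction}")
    base = fba(model)
    if not base.optimal:
        raise ModelValidationError(
            f"{model.species_id}: fva requires a feasible base problem")
    mu = base.growth_rate

    S, bounds = _lp_arrays(model)
    n = len(model.reactions)
    # v_objective >= fraction * mu  ->  -v_obj <= -fraction*mu
    row = np.zeros(n)
    row[model._index[model.objective_id]] = -1.0
    A_ub = row[None, :]
    b_ub = np.array([-fraction * mu])
    b_eq = np.zeros(S.shape[0])

    if reaction_ids is None:
        reaction_ids = model.reaction_ids
    intervals: Dict[str, Tuple[float, float]] = {}
    for rid in reaction_ids:
        j = model._index[rid]
        c = np.zeros(n)
        c[j] = 1.0
        lo = _run_lp(c, S, b_eq, bounds, A_ub, b_ub)
        hi = _run_lp(-c, S, b_eq, bounds, A_ub, b_ub)
        if not (lo.success and hi.success):  # pragma: no cover
            raise RuntimeError(f"FVA subproblem failed for {rid}")
        v_min, v_max = float(lo.x[j]), float(hi.x[j])
        if v_min > v_max:  # solver noise on degenerate problems
            v_min = v_max = 0.5 * (v_min + v_max)
        intervals[rid] = (v_min, v_max)
    return FVAResult(intervals, fraction)


def michaelis_menten_bound(conc: float, mm: MichaelisMenten) -> float:
    """Uptake lower bound (negative) at substrate concentration ``conc``."""
    if conc <= 0.0:
        return 0.0
    return -mm.v_max * conc / (mm.K_m + conc)


def constrain_uptake(model: GEMModel, local_concs: Mapping[str, float],
                     kinetics: UptakeKinetics) -> GEMModel:
    """Return a copy of ``model`` with uptake lower bounds on exchange
    reactions set from Michaelis–Menten kinetics at the local metabolite
    concentrations.  Secretion (upper) bounds are untouched; exchanges whose
    metabolite has no kinetics entry keep the model's default bound."""
    out = model.copy()
    for ex_id, met in out.exchange_map.items():
        if met not in kinetics:
            logger.debug("%s/%s: no kinetics for '%s', keeping default bound",
                         model.species_id, ex_id, met)
            continue
        conc = float(local_concs.get(met, 0.0))
        if conc < 0:
            raise ValueError(f"negative concentration for '{met}': {conc}")
        rxn = out.reaction(ex_id)
        rxn.lower_bound = michaelis_menten_bound(conc, kinetics[met])
    return out


def mass_balance_residual(model: GEMModel, result: FluxResult) -> float:
    """Infinity norm of S v for a flux solution (mass-balance check)."""
    S = model.stoichiometric_matrix()
    v = np.array([result.fluxes[r.id] for r in model.reactions])
    return float(np.max(np.abs(S @ v))) if len(v) else 0.0


def exchange_fluxes(model: GEMModel, result: FluxResult) -> Dict[str, float]:
    """Map environment metabolite -> exchange flux (uptake < 0)."""
    return {met: result.fluxes[ex_id]
            for ex_id, met in model.exchange_map.items()}
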