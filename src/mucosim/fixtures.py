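"""Synthetic toy communities with hand-verifiable LP optima.

These small models make the whole pipeline testable offline: every FBA
optimum has a closed form (growth = uptake x biomass yield), so the metabolic
layer can be checked against arithmetic, and the ready-made scenarios give
runnable cross-feeding communities:

* ``pair_crossfeed`` — a glucose-fermenting acetate producer (the
  *B. thetaiotaomicron* role) plus a consumer that grows on glucose and on
  the producer's acetate, secreting butyrate (the *E. rectale* role);
* ``triple_with_slow_grower`` — the pair plus a slow-growing acetate consumer
  with a very low biomass yield (the methanogen role, expected not to form
  clusters);
* ``two_region_oxygen`` — producer plus an aerotolerant species whose
  respiration pathway outyields fermentation, run under a high- or
  low-oxygen bottom boundary (proximal-small-intestine vs cecum analogue).

Diffusivities and kinetic parameters are chosen for a desk-scale domain
(200 um x 80 um): bulk diffusion is scaled down so that the shrunken domain
develops the same millimolar-scale gradients a millimetric mucosal layer
would, and scenarios reach a biomass/concentration plateau within ~150 steps
with at most a few hundred agents.
"""

from __future__ import annotations

from .agents import SpeciesSpec
from .environment import BoundarySpec
from .gem_core import GEMModel, Reaction, UptakeKinetics
from .orchestrator import MetaboliteSpec, SimulationConfig

BIG = 1000.0

#: dissolved O2 per unit partial pressure at 37 C, mM per mm Hg
HENRY_O2_MM_PER_MMHG = 1.3e-3


def o2_mm_hg_to_mM(p_mm_hg: float,
                   henry: float = HENRY_O2_MM_PER_MMHG) -> float:
    """Convert an oxygen partial pressure to dissolved concentration."""
    return p_mm_hg * henry


# ---------------------------------------------------------------------------
# toy models
# ---------------------------------------------------------------------------


def make_producer(glc_uptake_max: float = 10.0, acetate_yield: float = 0.8,
                  biomass_yield: float = 0.5,
                  propionate_yield: float = 0.2,
                  species_id: str = "producer") -> GEMModel:
    """Glucose fermenter secreting acetate (and propionate).

    FBA optimum (hand LP): the single conversion runs at the glucose uptake
    bound, so mu* = glc_uptake_max * biomass_yield, acetate secretion =
    glc_uptake_max * acetate_yield."""
    if min(glc_uptake_max, acetate_yield, biomass_yield) <= 0:
        raise ValueError("producer parameters must be positive")
    stoich = {"glc": -1.0, "ac": acetate_yield, "X": biomass_yield}
    mets = ["glc", "ac", "X"]
    reactions = [
        Reaction("EX_glc", {"glc": -1.0}, -glc_uptake_max, 0.0),
        Reaction("EX_ac", {"ac": -1.0}, 0.0, BIG),
        Reaction("BIOMASS", {"X": -1.0}, 0.0, BIG),
    ]
    exchange = {"EX_glc": "glucose", "EX_ac": "acetate"}
    if propionate_yield > 0:
        stoich["pr"] = propionate_yield
        mets.append("pr")
        reactions.append(Reaction("EX_pr", {"pr": -1.0}, 0.0, BIG))
        exchange["EX_pr"] = "propionate"
    reactions.insert(1, Reaction("FERM", stoich, 0.0, BIG,
                                 gpr="toyA_ferm"))
    model = GEMModel(species_id, mets, reactions, "BIOMASS", exchange)
    model.validate()
    return model


def make_consumer(glc_uptake_max: float = 5.0, ac_uptake_max: float = 10.0,
                  butyrate_yield: float = 0.5,
                  biomass_yields: tuple = (0.35, 0.15),
                  species_id: str = "consumer") -> GEMModel:
    """Grows on glucose and on acetate; butyrate comes from the acetate
    route only, so butyrate appears only under cross-feeding.

    FBA optimum: both uptakes saturate, mu* = glc_max * y_glc +
    ac_max * y_ac; without acetate, mu* = glc_max * y_glc."""
    y_glc, y_ac = biomass_yields
    if min(glc_uptake_max, ac_uptake_max, butyrate_yield, y_glc, y_ac) <= 0:
        raise ValueError("consumer parameters must be positive")
    mets = ["glc", "ac", "bu", "X"]
    reactions = [
        Reaction("EX_glc", {"glc": -1.0}, -glc_uptake_max, 0.0),
        Reaction("EX_ac", {"ac": -1.0}, -ac_uptake_max, 0.0),
        Reaction("GLC_GROWTH", {"glc": -1.0, "X": y_glc}, 0.0, BIG,
                 gpr="toyB_glc"),
        Reaction("AC_TO_BU", {"ac": -1.0, "X": y_ac, "bu": butyrate_yield},
                 0.0, BIG, gpr="toyB_but"),
        Reaction("EX_bu", {"bu": -1.0}, 0.0, BIG),
        Reaction("BIOMASS", {"X": -1.0}, 0.0, BIG),
    ]
    model = GEMModel(species_id, mets, reactions, "BIOMASS",
                     {"EX_glc": "glucose", "EX_ac": "acetate",
                      "EX_bu": "butyrate"})
    model.validate()
    return model


def make_slow_grower(ac_uptake_max: float = 5.0,
                     biomass_yield: float = 0.02,
                     species_id: str = "slowgrower") -> GEMModel:
    """Acetate-consuming methanogen analogue with a very low biomass flux;
    expected to stay dispersed (shoved around by faster growers)."""
    mets = ["ac", "ch4", "X"]
    reactions = [
        Reaction("EX_ac", {"ac": -1.0}, -ac_uptake_max, 0.0),
        Reaction("METHANOGENESIS",
                 {"ac": -1.0, "ch4": 0.8, "X": biomass_yield}, 0.0, BIG,
                 gpr="toyM_mtg"),
        Reaction("EX_ch4", {"ch4": -1.0}, 0.0, BIG),
        Reaction("BIOMASS", {"X": -1.0}, 0.0, BIG),
    ]
    model = GEMModel(species_id, mets, reactions, "BIOMASS",
                     {"EX_ac": "acetate", "EX_ch4": "methane"})
    model.validate()
    return model


def make_aerotolerant(glc_uptake_max: float = 10.0,
                      o2_uptake_max: float = 15.0,
                      o2_per_glc: float = 2.0,
                      resp_biomass_yield: float = 0.3,
                      ferm_biomass_yield: float = 0.1,
                      acetate_yield: float = 1.5,
                      species_id: str = "aerotolerant") -> GEMModel:
    """Facultative species: respiration (glucose + O2) outyields
    fermentation (glucose -> acetate), so growth increases with local O2."""
    mets = ["glc", "o2", "ac", "X"]
    reactions = [
        Reaction("EX_glc", {"glc": -1.0}, -glc_uptake_max, 0.0),
        Reaction("EX_o2", {"o2": -1.0}, -o2_uptake_max, 0.0),
        Reaction("RESP", {"glc": -1.0, "o2": -o2_per_glc,
                          "X": resp_biomass_yield}, 0.0, BIG,
                 gpr="toyE_resp"),
        Reaction("FERM", {"glc": -1.0, "ac": acetate_yield,
                          "X": ferm_biomass_yield}, 0.0, BIG,
                 gpr="toyE_ferm"),
        Reaction("EX_ac", {"ac": -1.0}, 0.0, BIG),
        Reaction("BIOMASS", {"X": -1.0}, 0.0, BIG),
    ]
    model = GEMModel(species_id, mets, reactions, "BIOMASS",
                     {"EX_glc": "glucose", "EX_o2": "oxygen",
                      "EX_ac": "acetate"})
    model.validate()
    return model


#: single-chain toy used in LP oracle examples: mu* = 10 * 0.5 = 5,
#: FVA glucose interval at fraction 0.9 = [-10, -9]
def make_toy_chain(glc_uptake_max: float = 10.0,
                   biomass_yield: float = 0.5) -> GEMModel:
    reactions = [
        Reaction("EX_glc", {"glc": -1.0}, -glc_uptake_max, BIG),
        Reaction("GROWTH", {"glc": -1.0, "X": biomass_yield}, 0.0, BIG),
        Reaction("BIOMASS", {"X": -1.0}, 0.0, BIG),
    ]
    model = GEMModel("toychain", ["glc", "X"], reactions, "BIOMASS",
                     {"EX_glc": "glucose"})
    model.validate()
    return model


# ---------------------------------------------------------------------------
# mechanical benchmark state
# ---------------------------------------------------------------------------


def post_growth_biofilm(seed: int, n: int = 500,
                        domain_width: float = 250.0, mass: float = 8.0,
                        growth_frac: float = 0.03,
                        layer_frac: float = 0.33):
    """A dense biofilm right after one growth-and-division phase: a fully
    relaxed staggered bed of ``n`` equal spheres in which the nutrient-
    exposed surface layer (top ``layer_frac`` of the bed) has just grown by
    up to ``growth_frac`` in radius.  Pair overlaps are then at most
    ``2 * growth_frac`` of a radius — the regime a single timestep of the
    coupled simulation hands to the shoving loop, where nutrient limitation
    confines growth to the biofilm surface.

    Returns (agents, domain_width)."""
    import numpy as np

    from .agents import BacterialAgent, radius_from_mass, resolve_collisions

    rng = np.random.default_rng(seed)
    r = radius_from_mass(mass)
    spacing = 2.05 * r
    gx = max(int(domain_width / spacing), 1)
    agents = []
    k = 0
    iy = 0
    while k < n:
        for ix in range(gx):
            if k >= n:
                break
            x = (ix * spacing + (iy % 2) * spacing / 2
                 + rng.uniform(-0.02 * r, 0.02 * r)) % domain_width
            y = r + iy * spacing * 0.95 + rng.uniform(0, 0.02 * r)
            agents.append(BacterialAgent(
                k, "benchmark", np.array([x, y]), mass))
            k += 1
        iy += 1
    resolve_collisions(agents, domain_width, max_iter=200)
    y_top = max(a.position[1] for a in agents)
    for a in agents:
        if a.position[1] > (1.0 - layer_frac) * y_top:
            a.set_mass(a.mass * rng.uniform(1.0, 1.0 + growth_frac) ** 3)
    return agents, domain_width


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

#: desk-scale effective diffusivity, um^2/h (scaled down with the domain so
#: an 80-um strip develops millimolar gradients like a millimetric mucosa)
D_EFFECTIVE = 3.6e4

_GLC_KIN = ("glucose", (10.0, 0.5))
_AC_KIN = ("acetate", (10.0, 0.5))
_O2_KIN = ("oxygen", (15.0, 0.01))

# scenario-level biomass yields: specific growth rates of ~0.2-0.5 1/h
# (gut-bacterium scale, doubling times of 1.5-3.5 h), slow enough that the
# shoving relaxation and sloughing keep pace with division
_SCEN_PRODUCER = dict(biomass_yield=0.05)
# the consumer is an acetate specialist (the butyrate-producer role): its
# glucose route alone sustains only slow growth, so its fate is tied to the
# producer's acetate rather than to glucose competition
_SCEN_CONSUMER = dict(biomass_yields=(0.01, 0.04))
_SCEN_SLOW = dict(biomass_yield=0.002)
_SCEN_AERO = dict(resp_biomass_yield=0.03, ferm_biomass_yield=0.01)
_SCEN_PRODUCER_O2 = dict(biomass_yield=0.02)


def _met(met: str, top_mM: float, bottom_kind: str = "neumann",
         bottom_value: float = 0.0, D: float = D_EFFECTIVE) -> MetaboliteSpec:
    return MetaboliteSpec(met, D, BoundarySpec("dirichlet", top_mM,
                                               bottom_kind, bottom_value))


def make_scenario(name: str, oxygen: str = "high",
                  seed: int = 0, **overrides) -> SimulationConfig:
    """Ready-made runnable configurations; see module docstring.

    ``oxygen`` selects the bottom-boundary oxygen level for
    ``two_region_oxygen`` ('high' = proximal-small-intestine analogue,
    'low' = cecum analogue)."""
    if name == "pair_crossfeed":
        species = [
            SpeciesSpec("producer", make_producer(**_SCEN_PRODUCER),
                        UptakeKinetics(dict([_GLC_KIN])),
                        initial_count=30, initial_mass=20.0),
            SpeciesSpec("consumer", make_consumer(**_SCEN_CONSUMER),
                        UptakeKinetics(dict([_GLC_KIN, _AC_KIN])),
                        initial_count=30, initial_mass=20.0),
        ]
        metabolites = [
            _met("glucose", 10.0),
            _met("acetate", 0.0),
            _met("propionate", 0.0),
            _met("butyrate", 0.0, bottom_kind="robin", bottom_value=20.0),
        ]
    elif name == "triple_with_slow_grower":
        species = [
            SpeciesSpec("producer", make_producer(**_SCEN_PRODUCER),
                        UptakeKinetics(dict([_GLC_KIN])),
                        initial_count=20, initial_mass=20.0),
            SpeciesSpec("consumer", make_consumer(**_SCEN_CONSUMER),
                        UptakeKinetics(dict([_GLC_KIN, _AC_KIN])),
                        initial_count=20, initial_mass=20.0),
            SpeciesSpec("slowgrower", make_slow_grower(**_SCEN_SLOW),
                        UptakeKinetics(dict([("acetate", (5.0, 0.5))])),
                        initial_count=20, initial_mass=20.0),
        ]
        metabolites = [
            _met("glucose", 10.0),
            _met("acetate", 0.0),
            _met("propionate", 0.0),
            _met("butyrate", 0.0, bottom_kind="robin", bottom_value=20.0),
            _met("methane", 0.0),
        ]
    elif name == "two_region_oxygen":
        if oxygen not in ("high", "low"):
            raise ValueError(f"oxygen must be 'high' or 'low', got {oxygen}")
        # proximal small intestine: ~59 mm Hg at the wall, ~10 in the lumen;
        # cecum: ~10 mm Hg near the crypt-villi interface, ~3 in the lumen
        if oxygen == "high":
            o2_bottom, o2_top = o2_mm_hg_to_mM(59.0), o2_mm_hg_to_mM(10.0)
        else:
            o2_bottom, o2_top = o2_mm_hg_to_mM(10.0), o2_mm_hg_to_mM(3.0)
        species = [
            SpeciesSpec("producer", make_producer(**_SCEN_PRODUCER_O2),
                        UptakeKinetics(dict([_GLC_KIN])),
                        initial_count=30, initial_mass=20.0),
            SpeciesSpec("aerotolerant", make_aerotolerant(**_SCEN_AERO),
                        UptakeKinetics(dict([_GLC_KIN, _O2_KIN])),
                        initial_count=30, initial_mass=20.0),
        ]
        metabolites = [
            _met("glucose", 10.0),
            _met("acetate", 0.0),
            _met("propionate", 0.0),
            MetaboliteSpec("oxygen", D_EFFECTIVE,
                           BoundarySpec("dirichlet", o2_top,
                                        "dirichlet", o2_bottom)),
        ]
    else:
        raise ValueError(
            f"unknown scenario '{name}'; choose from pair_crossfeed, "
            f"triple_with_slow_grower, two_region_oxygen")

    cfg = SimulationConfig(
        species=species, metabolites=metabolites,
        nx=16, ny=8, cell_size=10.0, max_biofilm_height=40.0,
        dt=0.1, max_steps=150, steady_tol=0.02, steady_window=20,
        field_relaxation=0.5,
        seed=seed, name=name,
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config override '{key}'")
        setattr(cfg, key, value)
    cfg.validate()
    return cfg
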