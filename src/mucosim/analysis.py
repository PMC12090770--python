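"""Post-processing of simulation output.

* :func:`crossfeeding_graph` — a directed species graph of mean exchange
  fluxes per metabolite, with an extra ``environment`` node absorbing net
  surplus and supplying net deficit;
* :func:`kde_map` — Gaussian kernel density of agent positions per species,
  periodic in x;
* :func:`normalize_scfa` — sum-normalized short-chain fatty acid profile;
* :func:`fva_per_agent` / :func:`shift_analysis` — suboptimal flux
  variability per agent under its own local constraints, and per-reaction
  flux-range-shift statistics with a 95th-percentile significance threshold;
* :func:`wilcoxon_signed_rank` — two-sided signed-rank test, exact for small
  samples (dynamic programming over all sign assignments), normal
  approximation with tie correction otherwise.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .gem_core import FVAResult, constrain_uptake, exchange_fluxes, fva

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# exchange-flux bookkeeping
# ---------------------------------------------------------------------------


def exchange_flux_table(state, config) -> pd.DataFrame:
    """Long-form table of the last step's per-agent exchange fluxes:
    columns (agent_id, species, metabolite, flux)."""
    specs = config.species_by_id()
    rows = []
    for a in state.agents:
        res = state.last_fluxes.get(a.id)
        if res is None:
            continue
        for met, v in exchange_fluxes(specs[a.species_id].gem, res).items():
            rows.append((a.id, a.species_id, met, v))
    return pd.DataFrame(rows,
                        columns=["agent_id", "species", "metabolite", "flux"])


ENVIRONMENT_NODE = "environment"


def crossfeeding_graph(flux_table: pd.DataFrame,
                       concentrations: Mapping[str, float],
                       conc_threshold: float = 0.1,
                       exclude: Iterable[str] = ()) -> nx.MultiDiGraph:
    """Directed cross-feeding graph from per-agent exchange fluxes.

    Mean flux per (species, metabolite) across that species' agents defines
    producers (mean > 0) and consumers (mean < 0).  Transferred flux is
    allocated proportionally producer -> consumer; any surplus flows to the
    ``environment`` node and any deficit flows from it.  Metabolites whose
    concentration is below ``conc_threshold`` (mM) or listed in ``exclude``
    are omitted.  Edge data: metabolite, weight (flux magnitude)."""
    if flux_table.empty:
        raise ValueError("flux table is empty")
    g = nx.MultiDiGraph()
    g.add_node(ENVIRONMENT_NODE)
    g.add_nodes_from(sorted(flux_table["species"].unique()))
    excluded = set(exclude)
    means = (flux_table.groupby(["species", "metabolite"])["flux"]
             .mean().reset_index())
    for met, sub in means.groupby("metabolite"):
        if met in excluded:
            continue
        if concentrations.get(met, 0.0) < conc_threshold:
            continue
        producers = sub[sub["flux"] > 0]
        consumers = sub[sub["flux"] < 0]
        T_s = float(producers["flux"].sum())
        T_u = float(-consumers["flux"].sum())
        transferred = min(T_s, T_u)
        for _, prow in producers.iterrows():
            for _, crow in consumers.iterrows():
                w = transferred * (prow["flux"] / T_s) * (-crow["flux"] / T_u)
                if w > 0:
                    g.add_edge(prow["species"], crow["species"],
                               metabolite=met, weight=w)
        if T_s > T_u:  # net secretion into the environment
            for _, prow in producers.iterrows():
                w = (T_s - T_u) * prow["flux"] / T_s
                if w > 0:
                    g.add_edge(prow["species"], ENVIRONMENT_NODE,
                               metabolite=met, weight=w)
        elif T_u > T_s:  # net draw from the environment
            for _, crow in consumers.iterrows():
                w = (T_u - T_s) * (-crow["flux"]) / T_u
                if w > 0:
                    g.add_edge(ENVIRONMENT_NODE, crow["species"],
                               metabolite=met, weight=w)
    return g


def graph_edge_list(g: nx.MultiDiGraph) -> pd.DataFrame:
    rows = [(u, v, d["metabolite"], d["weight"])
            for u, v, d in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["source", "target",
                                       "metabolite", "weight"])


# ---------------------------------------------------------------------------
# spatial density
# ---------------------------------------------------------------------------


def kde_map(positions: np.ndarray, domain_width: float, domain_height: float,
            grid_shape: Tuple[int, int] = (64, 64),
            bandwidth: Optional[float] = None) -> Optional[np.ndarray]:
    """2D Gaussian kernel density of agent positions, periodic in x (kernel
    images at +/- width), evaluated on a regular grid and normalized to
    integrate to 1 over the domain.  Returns None (with a warning) for fewer
    than two points.  Bandwidth defaults to Scott's rule."""
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        warnings.warn("kde_map needs at least two positions; returning None")
        return None
    n = len(pts)
    if bandwidth is None:
        sigma = np.std(pts, axis=0, ddof=1)
        sigma = np.where(sigma > 0, sigma, 1.0)
        bandwidth = float(np.mean(sigma)) * n ** (-1.0 / 6.0)  # Scott, d=2
        bandwidth = max(bandwidth, 1e-6)
    ny, nx_ = grid_shape
    xs = (np.arange(nx_) + 0.5) * domain_width / nx_
    ys = (np.arange(ny) + 0.5) * domain_height / ny
    X, Y = np.meshgrid(xs, ys)
    dens = np.zeros((ny, nx_))
    for shift in (-domain_width, 0.0, domain_width):
        dx = X[None, :, :] - (pts[:, 0, None, None] + shift)
        dy = Y[None, :, :] - pts[:, 1, None, None]
        dens += np.exp(-(dx ** 2 + dy ** 2) / (2.0 * bandwidth ** 2)).sum(0)
    dens /= (2.0 * math.pi * bandwidth ** 2) * n
    cell_area = (domain_width / nx_) * (domain_height / ny)
    total = dens.sum() * cell_area
    if total <= 0:
        warnings.warn("kde_map: degenerate density")
        return None
    return dens / total


# ---------------------------------------------------------------------------
# SCFA normalization
# ---------------------------------------------------------------------------


def normalize_scfa(concentrations: Mapping[str, float]) -> Dict[str, float]:
    """Each SCFA concentration divided by the sum over all of them."""
    total = float(sum(concentrations.values()))
    if total <= 0:
        raise ValueError("normalize_scfa: all concentrations are zero")
    return {k: v / total for k, v in concentrations.items()}


# ---------------------------------------------------------------------------
# per-agent FVA and range shifts
# ---------------------------------------------------------------------------


def fva_per_agent(state, config, species_id: str, fraction: float = 0.9,
                  reaction_ids: Optional[Sequence[str]] = None
                  ) -> Dict[int, FVAResult]:
    """Suboptimal FVA for every agent of one species, re-applying that
    agent's own environmental constraints (Michaelis–Menten bounds from its
    cell's concentrations).  Infeasible agents are skipped with a log line."""
    sp = config.species_by_id()[species_id]
    out: Dict[int, FVAResult] = {}
    cache: Dict[tuple, FVAResult] = {}
    for a in state.agents:
        if a.species_id != species_id:
            continue
        concs = state.local_concentrations(a)
        model = constrain_uptake(sp.gem, concs, sp.kinetics)
        key = tuple(round(model.reaction(ex).lower_bound, 9)
                    for ex in sorted(model.exchange_map))
        if key in cache:
            out[a.id] = cache[key]
            continue
        try:
            res = fva(model, fraction, reaction_ids)
        except Exception as exc:
            logger.info("agent %d: FVA skipped (%s)", a.id, exc)
            continue
        cache[key] = res
        out[a.id] = res
    return out


@dataclass
class ShiftTable:
    """Per-reaction flux-range-shift statistics across agents."""

    table: pd.DataFrame  # reaction, min_lb, max_ub, shift, significant
    percentile_threshold: float

    def significant_reactions(self) -> List[str]:
        return list(self.table.loc[self.table["significant"], "reaction"])


def shift_analysis(fva_results: Mapping[int, FVAResult],
                   report_threshold: float = 2.0,
                   gpr: Optional[Mapping[str, str]] = None) -> ShiftTable:
    """Across-agent displacement of FVA interval ends per reaction.

    shift(r) = max(spread of lower ends, spread of upper ends); a reaction is
    flagged significant when its shift reaches the 95th percentile of all
    shifts.  ``report_threshold`` (mmol/gDW/h) marks reactions for reporting
    alongside their GPR annotation when provided."""
    if len(fva_results) < 2:
        raise ValueError("shift_analysis needs FVA results for >= 2 agents")
    per_rxn: Dict[str, List[Tuple[float, float]]] = {}
    for res in fva_results.values():
        for rid, (lo, hi) in res.intervals.items():
            per_rxn.setdefault(rid, []).append((lo, hi))
    rows = []
    for rid, pairs in sorted(per_rxn.items()):
        los = np.array([p[0] for p in pairs])
        his = np.array([p[1] for p in pairs])
        shift = max(float(los.max() - los.min()),
                    float(his.max() - his.min()))
        rows.append((rid, float(los.min()), float(his.max()), shift))
    df = pd.DataFrame(rows, columns=["reaction", "min_lb", "max_ub", "shift"])
    threshold = float(np.percentile(df["shift"], 95))
    df["significant"] = df["shift"] >= threshold
    df["reportable"] = df["shift"] > report_threshold
    df["gpr"] = [gpr.get(r, "") if gpr else "" for r in df["reaction"]]
    return ShiftTable(df, threshold)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


def _exact_signed_rank_p(doubled_ranks: np.ndarray, w_doubled: int) -> float:
    """Two-sided exact p-value by dynamic programming over all 2^n sign
    assignments.  Ranks are mid-ranks doubled to integers so ties are exact.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:len(counts) - r]
        counts = counts + shifted
    n_total = counts.sum()  # 2^n
    p_le = counts[: w_doubled + 1].sum() / n_total
    p_ge = counts[w_doubled:].sum() / n_total
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float],
                         exact_max_n: int = 25) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are removed; ties get mid-ranks.  The null distribution
    is enumerated exactly (DP over sign assignments) for n <= ``exact_max_n``
    and approximated by a tie-corrected normal with continuity correction
    otherwise.  Returns (W+, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0.0]
    if len(d) == 0:
        warnings.warn("wilcoxon: all differences are zero; p = 1")
        return 0.0, 1.0
    if len(d) < 5:
        raise ValueError(
            f"wilcoxon needs >= 5 nonzero differences, got {len(d)}")
    n = len(d)
    order = np.abs(d)
    # mid-ranks
    from scipy.stats import rankdata
    ranks = rankdata(order)
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        doubled = np.round(2 * ranks).astype(int)
        w_doubled = int(round(2 * w_plus))
        p = _exact_signed_rank_p(doubled, w_doubled)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        # tie correction
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
        from scipy.stats import norm
        p = min(1.0, 2.0 * norm.sf(abs(z)))
    return w_plus, float(p)
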