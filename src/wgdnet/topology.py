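"""Degree-distribution fitting and modularity decomposition.

The degree distributions of metabolic networks are heavy-tailed; a power
law p(k) ∝ k^-t is fitted by ordinary least squares on log-transformed
(k, p(k)) pairs.  Module structure is found by simulated annealing on
Newman modularity

    Q = Σ_s [ l_s/L − (d_s / 2L)² ]

over partitions of the undirected simple projection of the network, with
single-node moves and collective merge/split moves per temperature step.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .network_build import MetabolicNetwork
from .reaction_io import EnzymeGeneMap, ReactionRecord

__all__ = [
    "PowerLawFit",
    "ModulePartition",
    "degree_distribution",
    "fit_power_law",
    "modularity_q",
    "sa_modularity",
    "pathway_composition",
    "majority_pathways",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log p(k) = log C − t·log k on points with k≥1, p(k)>0."""

    exponent_t: float
    intercept: float
    r_squared: float
    points_used: int


@dataclass
class ModulePartition:
    assignment: dict[str, int]
    modularity_Q: float
    n_modules: int
    null_q_mean: float | None = None
    null_q_sd: float | None = None
    pathway_composition: dict[int, dict[str, int]] | None = None


def degree_distribution(network: MetabolicNetwork, mode: str) -> dict[int, float]:
    """Relative frequency of in- or out-degrees (frequencies sum to 1)."""
    from .network_build import compute_degrees

    if mode not in ("in", "out"):
        raise ValueError("mode must be 'in' or 'out'")
    records = compute_degrees(network)
    if not records:
        return {}
    degs = [
        rec.in_degree if mode == "in" else rec.out_degree
        for rec in records.values()
    ]
    counts = Counter(degs)
    n = len(degs)
    return {k: c / n for k, c in sorted(counts.items())}


def fit_power_law(distribution: Mapping[int, float]) -> PowerLawFit:
    """Least-squares power-law exponent from a degree distribution.

    Only points with k ≥ 1 and p(k) > 0 enter the fit; the exponent is
    reported positive for decaying distributions.
    """
    pts = [(k, p) for k, p in distribution.items() if k >= 1 and p > 0]
    if len(pts) < 3:
        raise ValueError(f"power-law fit needs >=3 usable points, got {len(pts)}")
    x = np.log(np.array([k for k, _ in pts], dtype=float))
    y = np.log(np.array([p for _, p in pts], dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        exponent_t=float(-slope),
        intercept=float(intercept),
        r_squared=r2,
        points_used=len(pts),
    )


def modularity_q(graph: nx.Graph, assignment: Mapping[str, int]) -> float:
    """Newman modularity of a partition of an undirected simple graph."""
    L = graph.number_of_edges()
    if L == 0:
        return 0.0
    within: Counter = Counter()
    degsum: Counter = Counter()
    for u, v in graph.edges:
        if assignment[u] == assignment[v]:
            within[assignment[u]] += 1
    for v in graph.nodes:
        degsum[assignment[v]] += graph.degree(v)
    q = 0.0
    for mod in degsum:
        q += within.get(mod, 0) / L - (degsum[mod] / (2.0 * L)) ** 2
    return q


class _SAState:
    """Partition state with incremental modularity bookkeeping."""

    def __init__(self, graph: nx.Graph, assignment: dict):
        self.graph = graph
        self.L = graph.number_of_edges()
        self.assignment = dict(assignment)
        self.members: dict[int, set] = {}
        self.d: Counter = Counter()
        self.l: Counter = Counter()
        for v, m in self.assignment.items():
            self.members.setdefault(m, set()).add(v)
            self.d[m] += graph.degree(v)
        for u, v in graph.edges:
            if self.assignment[u] == self.assignment[v]:
                self.l[self.assignment[u]] += 1

    def q(self) -> float:
        L = self.L
        return sum(
            self.l.get(m, 0) / L - (self.d[m] / (2.0 * L)) ** 2 for m in self.members
        )

    def _k_to(self, v, module: int) -> int:
        a = self.assignment
        return sum(1 for w in self.graph[v] if a[w] == module)

    def delta_move(self, v, b: int) -> float:
        a = self.assignment[v]
        if a == b:
            return 0.0
        kv = self.graph.degree(v)
        kva = self._k_to(v, a)
        kvb = self._k_to(v, b)
        L = self.L
        return (kvb - kva) / L - kv * (kv + self.d[b] - self.d[a]) / (2.0 * L * L)

    def apply_move(self, v, b: int) -> None:
        a = self.assignment[v]
        kva = self._k_to(v, a)
        kvb = self._k_to(v, b)
        kv = self.graph.degree(v)
        self.assignment[v] = b
        self.members[a].discard(v)
        self.members.setdefault(b, set()).add(v)
        self.d[a] -= kv
        self.d[b] += kv
        self.l[a] -= kva
        self.l[b] += kvb
        if not self.members[a]:
            del self.members[a]
            del self.d[a]
            self.l.pop(a, None)

    def delta_merge(self, a: int, b: int) -> float:
        small, other = (a, b) if len(self.members[a]) <= len(self.members[b]) else (b, a)
        l_ab = sum(
            1
            for v in self.members[small]
            for w in self.graph[v]
            if self.assignment[w] == other
        )
        L = self.L
        return l_ab / L - self.d[a] * self.d[b] / (2.0 * L * L)

    def apply_merge(self, a: int, b: int) -> None:
        for v in list(self.members[b]):
            self.apply_move(v, a)


def _anneal(
    graph: nx.Graph,
    rng: np.random.Generator,
    iteration_factor: float,
    cooling_factor: float,
    t0: float | None,
    patience: int,
    max_temp_steps: int,
) -> tuple[dict, float]:
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 1:
        return {nodes[0]: 0}, 0.0
    state = _SAState(graph, {v: i for i, v in enumerate(nodes)})
    L = graph.number_of_edges()
    temp = t0 if t0 is not None else 1.0 / (2.0 * max(L, 1))
    n_node_moves = max(1, int(round(iteration_factor * n * n)))
    n_collective = max(1, int(round(iteration_factor * n)))
    best_assignment = dict(state.assignment)
    best_q = state.q()
    stale = 0
    for _step in range(max_temp_steps):
        accepted = 0
        for _ in range(n_node_moves):
            v = nodes[rng.integers(n)]
            mods = list(state.members)
            b = mods[rng.integers(len(mods))]
            if b == state.assignment[v]:
                b = n + int(rng.integers(n))  # occasionally propose a fresh module
                if b in state.members or rng.random() < 0.5:
                    continue
            dq = state.delta_move(v, b)
            if dq >= 0 or rng.random() < math.exp(dq / temp):
                state.apply_move(v, b)
                accepted += 1
        for _ in range(n_collective):
            mods = list(state.members)
            if len(mods) >= 2 and rng.random() < 0.5:
                i, j = rng.choice(len(mods), size=2, replace=False)
                a, b = mods[int(i)], mods[int(j)]
                dq = state.delta_merge(a, b)
                if dq >= 0 or rng.random() < math.exp(dq / temp):
                    state.apply_merge(a, b)
                    accepted += 1
            else:
                big = [m for m in state.members if len(state.members[m]) >= 2]
                if not big:
                    continue
                m = big[int(rng.integers(len(big)))]
                group = sorted(state.members[m])
                mask = rng.random(len(group)) < 0.5
                if mask.all() or not mask.any():
                    continue
                fresh = max(state.members) + 1 + n
                q_before = state.q()
                moved = [v for v, mv in zip(group, mask) if mv]
                for v in moved:
                    state.apply_move(v, fresh)
                dq = state.q() - q_before
                if dq >= 0 or rng.random() < math.exp(dq / temp):
                    accepted += 1
                else:
                    for v in moved:
                        state.apply_move(v, m)
        q_now = state.q()
        if q_now > best_q + 1e-12:
            best_q = q_now
            best_assignment = dict(state.assignment)
        stale = stale + 1 if accepted == 0 else 0
        if stale >= patience:
            break
        temp *= cooling_factor
    return best_assignment, best_q


def _null_q(
    graph: nx.Graph, rng: np.random.Generator, n_randomizations: int
) -> tuple[float | None, float | None]:
    if n_randomizations <= 0 or graph.number_of_edges() < 4:
        return None, None
    qs = []
    for _ in range(n_randomizations):
        g = graph.copy()
        try:
            nx.double_edge_swap(
                g,
                nswap=2 * g.number_of_edges(),
                max_tries=100 * g.number_of_edges(),
                seed=int(rng.integers(2**31 - 1)),
            )
        except nx.NetworkXError:  # pragma: no cover - tiny/degenerate graphs
            pass
        comms = nx.algorithms.community.greedy_modularity_communities(g)
        qs.append(nx.algorithms.community.modularity(g, comms))
    return float(np.mean(qs)), float(np.std(qs, ddof=1)) if len(qs) > 1 else 0.0


def sa_modularity(
    network: MetabolicNetwork | nx.Graph,
    iteration_factor: float = 1.0,
    cooling_factor: float = 0.95,
    seed: int | None = None,
    n_randomizations: int = 100,
    t0: float | None = None,
    patience: int = 3,
    max_temp_steps: int = 250,
) -> ModulePartition:
    """Simulated-annealing modularity maximization (Guimerà-Amaral style).

    Works on the undirected simple projection.  Per temperature step,
    ``iteration_factor·n²`` single-node moves and ``iteration_factor·n``
    collective merge/split moves are proposed; the temperature is multiplied
    by ``cooling_factor`` each step, starting at ``1/(2L)``, and the search
    stops after ``patience`` consecutive temperatures without an accepted
    move.  Deterministic given ``seed``.  ``n_randomizations``
    degree-preserving rewirings provide a null mean/sd of Q for context.
    Disconnected inputs are partitioned per component (with a warning) and
    Q is reported for the combined partition on the whole graph.
    """
    graph = (
        network.undirected_projection()
        if isinstance(network, MetabolicNetwork)
        else nx.Graph(network)
    )
    graph.remove_edges_from(nx.selfloop_edges(graph))
    if graph.number_of_nodes() == 0:
        raise ValueError("network is empty")
    rng = np.random.default_rng(seed)
    components = sorted(nx.connected_components(graph), key=lambda c: (-len(c), sorted(c)))
    if len(components) > 1:
        warnings.warn(
            f"disconnected input: partitioning {len(components)} components separately",
            stacklevel=2,
        )
    assignment: dict = {}
    offset = 0
    for comp in components:
        sub = graph.subgraph(comp)
        sub_assign, _q = _anneal(
            sub, rng, iteration_factor, cooling_factor, t0, patience, max_temp_steps
        )
        relabel = {m: i for i, m in enumerate(sorted(set(sub_assign.values())))}
        for v, m in sub_assign.items():
            assignment[v] = offset + relabel[m]
        offset += len(relabel)
    q = modularity_q(graph, assignment)
    null_mean, null_sd = _null_q(graph, rng, n_randomizations)
    # canonical module numbering by size then lexicographic member order
    by_mod: dict[int, list] = {}
    for v, m in assignment.items():
        by_mod.setdefault(m, []).append(v)
    order = sorted(by_mod, key=lambda m: (-len(by_mod[m]), sorted(by_mod[m])))
    renum = {m: i for i, m in enumerate(order)}
    assignment = {v: renum[m] for v, m in assignment.items()}
    return ModulePartition(
        assignment=assignment,
        modularity_Q=q,
        n_modules=len(order),
        null_q_mean=null_mean,
        null_q_sd=null_sd,
    )


def pathway_composition(
    partition: ModulePartition,
    reactions: Iterable[ReactionRecord],
    enzyme_map: Mapping[str, EnzymeGeneMap],
) -> dict[int, dict[str, int]]:
    """Counts of member enzymes per pathway in each module.

    An enzyme contributes to every pathway of every reaction it catalyzes;
    enzymes with no pathway count under ``"unassigned"``.  The result is
    stored on the partition; the majority pathway per module is the max
    count (ties broken lexicographically).
    """
    rxn_pathways: dict[str, set[str]] = {}
    for r in reactions:
        if r.pathway_id:
            rxn_pathways.setdefault(r.reaction_id, set()).add(r.pathway_id)
    comp: dict[int, dict[str, int]] = {}
    for enz, module in partition.assignment.items():
        pathways: set[str] = set()
        rec = enzyme_map.get(enz)
        if rec is not None:
            for rid in rec.catalyzed_reaction_ids:
                pathways |= rxn_pathways.get(rid, set())
        if not pathways:
            pathways = {"unassigned"}
        table = comp.setdefault(module, {})
        for p in pathways:
            table[p] = table.get(p, 0) + 1
    partition.pathway_composition = comp
    return comp


def majority_pathways(composition: Mapping[int, Mapping[str, int]]) -> dict[int, str]:
    """Majority pathway per module (highest count, lexicographic tie-break)."""
    return {
        m: min((p for p in table if table[p] == max(table.values())))
        for m, table in composition.items()
    }
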