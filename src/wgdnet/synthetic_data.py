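"""Synthetic input bundles with the statistical structure the analysis assumes.

The generator emulates every input the pipeline consumes so all stages can
be exercised without any database download:

* a weakly connected, scale-free-ish directed enzyme network (out-degrees
  drawn from a truncated discrete power law, targets chosen by preferential
  attachment on in-degree), with a configured fraction of bidirectional
  edges, plus reaction records and an enzyme-gene map that reconstruct the
  network exactly through the parsing/filtering/building pipeline;
* WGD labels planted preferentially on high-degree enzymes (logistic hub
  bias) and on connected enzyme pairs (per-edge pair bias), with ground
  truth recorded;
* log-normal expression intensities in which hub genes are expressed
  higher; substitution-rate tables decreasing with degree; and a mirrored
  "foreign" species with configurable label conservation.

Default sizes follow the *Arabidopsis* analysis network: 478 enzymes,
1394 interactions of which 379 are bidirectional, 173 labeled enzymes,
59 expression conditions, intensity floor 50, degree exponent 1.67.
Every output is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .evolution import RateRecord
from .network_build import (
    BIDIRECTIONAL,
    DIRECTIONAL,
    MetabolicNetwork,
    build_enzyme_network,
    compute_degrees,
)
from .reaction_io import (
    CURRENCY_NAME_TO_KEGG,
    CurrencyFilter,
    EnzymeGeneMap,
    ReactionRecord,
    apply_currency_filter,
    format_reaction_line,
)

__all__ = [
    "ExpressionConfig",
    "RateConfig",
    "SyntheticConfig",
    "SyntheticBundle",
    "OrthologBundle",
    "worked_example_network",
    "generate_network",
    "plant_labels",
    "generate_wgd_pairs",
    "generate_expression",
    "generate_rates",
    "generate_orthologs",
    "generate_bundle",
    "write_bundle",
]

# seed-derivation keys: one sub-stream per generator stage
_STAGE_NETWORK = 0
_STAGE_LABELS = 1
_STAGE_EXPRESSION = 2
_STAGE_RATES = 3
_STAGE_ORTHOLOGS = 4
_STAGE_PAIRS = 5


@dataclass(frozen=True)
class ExpressionConfig:
    n_conditions: int = 59
    log_mu: float = 6.0
    log_sigma: float = 1.0
    hub_intensity_slope: float = 0.4
    floor: float = 50.0


@dataclass(frozen=True)
class RateConfig:
    ka_baseline: float = 0.25
    knc_baseline: float = 0.35
    degree_slope: float = -0.01
    noise_sd: float = 0.05


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic bundle; ``seed`` is mandatory."""

    seed: int
    n_enzymes: int = 478
    target_edges: int = 1394
    degree_exponent: float = 1.67
    max_out_degree: int = 20
    preferential_attachment_strength: float = 1.0
    bidirectional_fraction: float = 379 / 1394
    label_fraction: float = 173 / 478
    hub_bias: float = 1.0
    pair_bias: float = 0.3
    min_genes: int = 1
    max_genes: int = 3
    currency_rate: float = 0.3
    n_pathways: int = 8
    foreign_conservation: float = 0.9
    foreign_background: float = 0.05
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    rates: RateConfig = field(default_factory=RateConfig)

    def __post_init__(self) -> None:
        for name in ("bidirectional_fraction", "label_fraction", "currency_rate",
                     "foreign_conservation", "foreign_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class OrthologBundle:
    table: pd.DataFrame
    foreign_gene_map: dict[str, EnzymeGeneMap]
    foreign_labels: "object"
    enzyme_ortholog_map: dict[str, set[str]]


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    network: MetabolicNetwork
    reactions: list[ReactionRecord]
    enzyme_map: dict[str, EnzymeGeneMap]
    labels: "object"
    label_truth: dict
    wgd_pairs: list[tuple[str, str]]
    expression: pd.DataFrame
    rates: list[RateRecord]
    orthologs: OrthologBundle


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


def worked_example_network() -> MetabolicNetwork:
    """The 10-node worked example: five feeders into α, α→β, β into 3 sinks."""
    feeders = [f"S{i}" for i in range(1, 6)]
    sinks = [f"T{i}" for i in range(1, 4)]
    nodes = feeders + ["ALPHA", "BETA"] + sinks
    from .network_build import InteractionEdge

    edges = [InteractionEdge(s, "ALPHA", DIRECTIONAL) for s in feeders]
    edges.append(InteractionEdge("ALPHA", "BETA", DIRECTIONAL))
    edges += [InteractionEdge("BETA", t, DIRECTIONAL) for t in sinks]
    gene_map = {
        node: EnzymeGeneMap(node, {f"At1g{10000 + i:05d}"}, set())
        for i, node in enumerate(nodes)
    }
    return MetabolicNetwork(enzymes=set(nodes), edges=edges, gene_map=gene_map)


def _sample_out_degrees(
    rng: np.random.Generator, n: int, exponent: float, kmax: int, target: int
) -> np.ndarray:
    """Out-degrees from a truncated power law, nudged to sum to ``target``.

    The default cutoff keeps the mean near the empirical network's ~2.9
    links per enzyme at the default exponent; the nudge moves single units
    on uniformly chosen nodes so the tail shape is preserved.
    """
    ks = np.arange(1, kmax + 1, dtype=float)
    pmf = ks**-exponent
    pmf /= pmf.sum()
    degs = rng.choice(np.arange(1, kmax + 1), size=n, p=pmf).astype(np.int64)
    diff = int(degs.sum()) - target
    while diff > 0:
        i = int(rng.integers(n))
        if degs[i] > 0:
            degs[i] -= 1
            diff -= 1
    while diff < 0:
        i = int(rng.integers(n))
        if degs[i] < n - 1:
            degs[i] += 1
            diff += 1
    return degs


def _assign_targets(
    rng: np.random.Generator,
    degs: np.ndarray,
    strength: float,
    n: int,
) -> set[tuple[int, int]]:
    """Preferential attachment of out-stubs on in-degree; one edge per
    unordered node pair, no self-loops."""
    in_deg = np.zeros(n, dtype=np.int64)
    edge_targets: list[int] = []  # one entry per in-edge, for O(1) PA draws
    edges: set[tuple[int, int]] = set()
    used_pairs: set[frozenset[int]] = set()
    order = rng.permutation(n)
    base_mass = strength * n
    for u in order:
        for _ in range(int(degs[u])):
            placed = False
            for _try in range(200):
                total_in = len(edge_targets)
                if rng.random() < base_mass / (base_mass + total_in):
                    v = int(rng.integers(n))
                else:
                    v = edge_targets[int(rng.integers(total_in))]
                if v == u or frozenset((int(u), v)) in used_pairs:
                    continue
                placed = True
                break
            if not placed:
                free = [
                    w for w in range(n)
                    if w != u and frozenset((int(u), w)) not in used_pairs
                ]
                if not free:
                    raise ValueError("edge target infeasible: node pairs exhausted")
                v = free[int(rng.integers(len(free)))]
            edges.add((int(u), v))
            used_pairs.add(frozenset((int(u), v)))
            edge_targets.append(v)
            in_deg[v] += 1
    return edges


def _connect_components(
    rng: np.random.Generator, edges: set[tuple[int, int]], n: int
) -> set[tuple[int, int]]:
    """Rewire cycle edges so the undirected projection is connected.

    Keeps the edge count exact.  Requires |edges| ≥ n−1; while the graph is
    disconnected some component then necessarily contains a cycle, and one
    of its cycle edges can be re-targeted to bridge two components.
    """
    if len(edges) < n - 1:
        raise ValueError("too few edges for a connected network")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    while len(comps) > 1:
        candidates = sorted(edges)
        order = rng.permutation(len(candidates))
        for i in order:
            u, v = candidates[int(i)]
            g.remove_edge(u, v)
            if nx.has_path(g, u, v):  # (u, v) lay on a cycle
                others = [c for c in comps if u not in c]
                target_comp = sorted(others[int(rng.integers(len(others)))])
                w = target_comp[int(rng.integers(len(target_comp)))]
                edges.discard((u, v))
                edges.add((u, w))
                g.add_edge(u, w)
                break
            g.add_edge(u, v)
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
    return edges


def _gene_ids(rng: np.random.Generator, count: int) -> list[str]:
    nums = rng.choice(90000, size=count, replace=False) + 1000
    chroms = rng.integers(1, 6, size=count)
    return [f"At{c}g{m:05d}" for c, m in zip(chroms, nums)]


def generate_network(
    config: SyntheticConfig,
) -> tuple[MetabolicNetwork, list[ReactionRecord], dict[str, EnzymeGeneMap]]:
    """Synthesize the network together with reactions and an enzyme-gene map.

    The reaction records and map are constructed so that parsing, currency
    filtering and :func:`build_enzyme_network` reconstruct exactly the
    returned network (round-trip property).  Currency metabolites are
    sprinkled into a fraction of reactions to exercise the filter.
    """
    n, target = config.n_enzymes, config.target_edges
    if target > n * (n - 1) // 2:
        raise ValueError("target_edges exceeds the number of available node pairs")
    rng = _rng(config.seed, _STAGE_NETWORK)
    degs = _sample_out_degrees(
        rng, n, config.degree_exponent, config.max_out_degree, target
    )
    edges = _assign_targets(rng, degs, config.preferential_attachment_strength, n)
    edges = _connect_components(rng, edges, n)
    assert len(edges) == target

    enzymes = [
        f"EC{rng.integers(1, 7)}.{rng.integers(1, 10)}.{rng.integers(1, 10)}.{i + 1}"
        for i in range(n)
    ]
    edge_list = sorted(edges)
    n_bidir = int(round(config.bidirectional_fraction * target))
    bidir_idx = set(
        rng.choice(len(edge_list), size=n_bidir, replace=False).tolist()
    )

    currency_ids = sorted(CURRENCY_NAME_TO_KEGG.values())
    reactions: list[ReactionRecord] = []
    catalyzed: dict[str, set[str]] = {e: set() for e in enzymes}
    rid_counter = met_counter = 0

    def next_rid() -> str:
        nonlocal rid_counter
        rid_counter += 1
        return f"R{rid_counter:05d}"

    def next_met() -> str:
        nonlocal met_counter
        met_counter += 1
        return f"C{10000 + met_counter:05d}"

    def pathway() -> str:
        return f"P{int(rng.integers(config.n_pathways)) + 1:02d}"

    def maybe_currency(side: set[str]) -> frozenset[str]:
        if rng.random() < config.currency_rate:
            side = side | {currency_ids[int(rng.integers(len(currency_ids)))]}
        return frozenset(side)

    for idx, (u, v) in enumerate(edge_list):
        a, b = enzymes[u], enzymes[v]
        shared = next_met()
        if idx in bidir_idx:
            rid = next_rid()
            reactions.append(
                ReactionRecord(
                    rid,
                    substrates=maybe_currency({next_met()}),
                    products=maybe_currency({shared}),
                    direction="reversible",
                    pathway_id=pathway(),
                )
            )
            catalyzed[a].add(rid)
            catalyzed[b].add(rid)
        else:
            rid_a, rid_b = next_rid(), next_rid()
            reactions.append(
                ReactionRecord(
                    rid_a,
                    substrates=maybe_currency({next_met()}),
                    products=maybe_currency({shared}),
                    direction="forward",
                    pathway_id=pathway(),
                )
            )
            reactions.append(
                ReactionRecord(
                    rid_b,
                    substrates=maybe_currency({shared}),
                    products=maybe_currency({next_met()}),
                    direction="forward",
                    pathway_id=pathway(),
                )
            )
            catalyzed[a].add(rid_a)
            catalyzed[b].add(rid_b)

    counts = rng.integers(config.min_genes, config.max_genes + 1, size=n)
    all_genes = _gene_ids(rng, int(counts.sum()))
    enzyme_map: dict[str, EnzymeGeneMap] = {}
    pos = 0
    for i, enz in enumerate(enzymes):
        genes = set(all_genes[pos : pos + int(counts[i])])
        pos += int(counts[i])
        enzyme_map[enz] = EnzymeGeneMap(enz, genes, catalyzed[enz])

    filtered = apply_currency_filter(reactions, CurrencyFilter.default())
    network = build_enzyme_network(filtered, enzyme_map)
    assert network.n_edges == target
    return network, reactions, enzyme_map


def _standardized_degree(network: MetabolicNetwork) -> dict[str, float]:
    recs = compute_degrees(network)
    total = {e: r.in_degree + r.out_degree for e, r in recs.items()}
    values = np.array(list(total.values()), dtype=float)
    mu, sd = values.mean(), values.std()
    sd = sd if sd > 0 else 1.0
    return {e: (t - mu) / sd for e, t in total.items()}


def plant_labels(
    network: MetabolicNetwork, config: SyntheticConfig
) -> tuple["object", dict]:
    """Plant WGD labels with hub bias and pair (edge) bias; record ground truth.

    Label probability follows a logistic in standardized total degree; then,
    with probability ``pair_bias`` per edge, both endpoints are forced
    labeled until the label budget is met.  Only enzymes with ≥2 annotated
    genes are eligible (a WGD-enzyme needs a retained homeolog *pair*).
    """
    from .wgd import WGDLabelSet

    rng = _rng(config.seed, _STAGE_LABELS)
    nodes = sorted(network.enzymes)
    budget = int(round(config.label_fraction * len(nodes)))
    if network.gene_map:
        eligible = {
            e
            for e in nodes
            if e in network.gene_map and len(network.gene_map[e].gene_ids) >= 2
        }
    else:
        eligible = set(nodes)
    if budget > len(eligible):
        raise ValueError(
            f"label budget {budget} infeasible: only {len(eligible)} enzymes "
            "have >=2 annotated genes"
        )
    z = _standardized_degree(network)
    weight = {e: 1.0 / (1.0 + math.exp(-config.hub_bias * z[e])) for e in nodes}

    labeled: set[str] = set()
    forced_edges = 0
    if config.pair_bias > 0:
        for i in rng.permutation(network.n_edges):
            if len(labeled) >= budget:
                break
            e = network.edges[int(i)]
            if e.source in eligible and e.target in eligible:
                if rng.random() < config.pair_bias:
                    labeled.update(e.endpoints)
                    forced_edges += 1
    if len(labeled) > budget:
        drop = rng.choice(sorted(labeled), size=len(labeled) - budget, replace=False)
        labeled -= set(drop.tolist())
    if len(labeled) < budget:
        remaining = sorted(eligible - labeled)
        w = np.array([weight[e] for e in remaining])
        keys = np.log(rng.random(len(remaining))) / w  # weighted w/o replacement
        take = np.argsort(keys)[::-1][: budget - len(labeled)]
        labeled.update(remaining[int(i)] for i in take)
    truth = {
        "hub_bias": config.hub_bias,
        "pair_bias": config.pair_bias,
        "budget": budget,
        "forced_edges": forced_edges,
        "n_eligible": len(eligible),
    }
    return WGDLabelSet(frozenset(labeled), source="wgd"), truth


def generate_wgd_pairs(
    labels, enzyme_map: dict[str, EnzymeGeneMap], config: SyntheticConfig
) -> list[tuple[str, str]]:
    """One homeolog gene pair per labeled enzyme (two of its genes)."""
    rng = _rng(config.seed, _STAGE_PAIRS)
    pairs = []
    for enz in sorted(labels.labeled_enzymes):
        genes = sorted(enzyme_map[enz].gene_ids)
        if len(genes) < 2:
            raise ValueError(f"labeled enzyme {enz} has fewer than 2 genes")
        i, j = rng.choice(len(genes), size=2, replace=False)
        pairs.append((genes[int(i)], genes[int(j)]))
    return pairs


def generate_expression(
    network: MetabolicNetwork,
    enzyme_map: dict[str, EnzymeGeneMap],
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Log-normal gene×condition intensities; hub genes expressed higher."""
    rng = _rng(config.seed, _STAGE_EXPRESSION)
    z = _standardized_degree(network)
    cfg = config.expression
    rows = {}
    for enz in sorted(enzyme_map):
        mu = cfg.log_mu + cfg.hub_intensity_slope * z.get(enz, 0.0)
        for gene in sorted(enzyme_map[enz].gene_ids):
            rows[gene] = rng.lognormal(mu, cfg.log_sigma, size=cfg.n_conditions)
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    matrix.columns = [f"cond{j + 1:02d}" for j in range(cfg.n_conditions)]
    return matrix.sort_index()


def generate_rates(
    network: MetabolicNetwork,
    enzyme_map: dict[str, EnzymeGeneMap],
    config: SyntheticConfig,
) -> list[RateRecord]:
    """Per-gene Ka/K5u/K3u decreasing with the encoding enzyme's degree."""
    rng = _rng(config.seed, _STAGE_RATES)
    recs = compute_degrees(network)
    cfg = config.rates
    out = []
    for enz in sorted(enzyme_map):
        deg = recs[enz].in_degree + recs[enz].out_degree if enz in recs else 0
        for gene in sorted(enzyme_map[enz].gene_ids):
            def rate(base: float) -> float:
                return max(
                    0.0, base + cfg.degree_slope * deg + rng.normal(0, cfg.noise_sd)
                )

            out.append(
                RateRecord(
                    gene,
                    ka=rate(cfg.ka_baseline),
                    k5u=rate(cfg.knc_baseline),
                    k3u=rate(cfg.knc_baseline),
                )
            )
    return out


def generate_orthologs(
    network: MetabolicNetwork,
    enzyme_map: dict[str, EnzymeGeneMap],
    labels,
    config: SyntheticConfig,
) -> OrthologBundle:
    """Mirror the network into a foreign species with configurable label
    conservation; build the gene-level ortholog table and enzyme-level map."""
    from .wgd import WGDLabelSet

    rng = _rng(config.seed, _STAGE_ORTHOLOGS)
    rows = []
    foreign_gene_map: dict[str, EnzymeGeneMap] = {}
    enzyme_ortholog_map: dict[str, set[str]] = {}
    foreign_labeled: set[str] = set()
    gid = 0
    for enz in sorted(enzyme_map):
        fenz = f"P_{enz}"
        fgenes = set()
        for gene in sorted(enzyme_map[enz].gene_ids):
            gid += 1
            fgene = "Pt" + gene[2:]
            fgenes.add(fgene)
            rows.append({"group_id": f"OG{gid:05d}", "species": "arabidopsis", "gene": gene})
            rows.append({"group_id": f"OG{gid:05d}", "species": "populus", "gene": fgene})
        foreign_gene_map[fenz] = EnzymeGeneMap(fenz, fgenes, set())
        enzyme_ortholog_map[enz] = {fenz}
        if enz in labels.labeled_enzymes:
            if rng.random() < config.foreign_conservation:
                foreign_labeled.add(fenz)
        elif rng.random() < config.foreign_background:
            foreign_labeled.add(fenz)
    return OrthologBundle(
        table=pd.DataFrame(rows),
        foreign_gene_map=foreign_gene_map,
        foreign_labels=WGDLabelSet(frozenset(foreign_labeled), source="populus_wgd"),
        enzyme_ortholog_map=enzyme_ortholog_map,
    )


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the complete, mutually consistent input bundle."""
    network, reactions, enzyme_map = generate_network(config)
    labels, truth = plant_labels(network, config)
    pairs = generate_wgd_pairs(labels, enzyme_map, config)
    expression = generate_expression(network, enzyme_map, config)
    rates = generate_rates(network, enzyme_map, config)
    orthologs = generate_orthologs(network, enzyme_map, labels, config)
    return SyntheticBundle(
        config=config,
        network=network,
        reactions=reactions,
        enzyme_map=enzyme_map,
        labels=labels,
        label_truth=truth,
        wgd_pairs=pairs,
        expression=expression,
        rates=rates,
        orthologs=orthologs,
    )


def write_bundle(config: SyntheticConfig, outdir: str | Path) -> SyntheticBundle:
    """Write the full input bundle plus a ground-truth JSON to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_bundle(config)
    (out / "reactions.lst").write_text(
        "\n".join(format_reaction_line(r) for r in bundle.reactions) + "\n"
    )
    gene_rows = ["enzyme_id\tgene_id\treaction_id"]
    for enz in sorted(bundle.enzyme_map):
        rec = bundle.enzyme_map[enz]
        rids = sorted(rec.catalyzed_reaction_ids) or [""]
        for gene in sorted(rec.gene_ids):
            for rid in rids:
                gene_rows.append(f"{enz}\t{gene}\t{rid}")
    (out / "enzyme_genes.tsv").write_text("\n".join(gene_rows) + "\n")
    bundle.expression.to_csv(out / "expression.tsv", sep="\t")
    (out / "wgd_pairs.tsv").write_text(
        "\n".join(f"{a}\t{b}" for a, b in bundle.wgd_pairs) + "\n"
    )
    rate_rows = ["gene\tKa\tK5u\tK3u"]
    for r in bundle.rates:
        def fmt(v):
            return "" if v is None else f"{v:.6f}"

        rate_rows.append(f"{r.gene}\t{fmt(r.ka)}\t{fmt(r.k5u)}\t{fmt(r.k3u)}")
    (out / "rates.tsv").write_text("\n".join(rate_rows) + "\n")
    bundle.orthologs.table.to_csv(out / "orthologs.tsv", sep="\t", index=False)
    truth = {
        "config": asdict(config),
        "label_truth": bundle.label_truth,
        "labeled_enzymes": sorted(bundle.labels.labeled_enzymes),
        "foreign_labeled": sorted(bundle.orthologs.foreign_labels.labeled_enzymes),
        "n_edges": bundle.network.n_edges,
        "n_bidirectional": bundle.network.bidirectional_count,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return bundle
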