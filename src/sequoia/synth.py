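"""Synthetic query/target/similarity generator with known ground truth.

Emulates the conserved-module setting of cross-species network
querying: a connected query module is implanted into a sparse random
background graph as a perturbed copy — nodes deleted, extra nodes
inserted, edges rewired — and a similarity table mimicking BLAST bit
scores links surviving homolog pairs, contaminated with spurious
positive scores toward random non-homologous targets. All randomness
flows from one seeded generator, so a config and seed fully determine
the instance.

Defaults describe a moderately perturbed world: a 10-node query, a
300-node Erdős–Rényi background with mean degree 4 (sparse, PPI-like),
10% node deletion / insertion / edge rewiring, homolog scores around
100 ± 20 (a typical bit-score scale) and a 5% spurious-pair rate at a
quarter of the homolog score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .evaluate import match_score
from .io import QueryResult, SimilarityTable


class InfeasibleConfigError(ValueError):
    """The requested perturbation leaves no usable implanted module."""


@dataclass
class SynthConfig:
    query_size: int = 10
    background_size: int = 300
    background_model: str = "erdos_renyi"  # or "preferential_attachment"
    er_p: float | None = None  # None -> mean degree 4
    pa_m: int = 2
    p_node_delete: float = 0.1
    p_node_insert: float = 0.1
    p_edge_rewire: float = 0.1
    homolog_score_mean: float = 100.0
    homolog_score_sd: float = 20.0
    spurious_pair_rate: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("p_node_delete", "p_node_insert", "p_edge_rewire", "spurious_pair_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.query_size < 1 or self.background_size < 1:
            raise ValueError("sizes must be >= 1")
        if self.homolog_score_mean <= 0 or self.homolog_score_sd < 0:
            raise ValueError("homolog score mean must be positive, sd nonnegative")
        if self.p_node_delete >= 1.0 and self.query_size > 0:
            raise InfeasibleConfigError("p_node_delete = 1 deletes the whole module")


@dataclass(frozen=True)
class GroundTruth:
    """Injective partial map from query nodes to their implanted homologs,
    plus the full implanted node and edge sets (inserted nodes included)."""

    mapping: dict[str, str] = field(default_factory=dict)
    implanted_nodes: frozenset[str] = frozenset()
    implanted_edges: frozenset[tuple[str, str]] = frozenset()


def _truncated_positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    return float(max(mean, 1e-6))  # degenerate sd/mean combinations


def _random_connected_er(rng: np.random.Generator, n: int, prefix: str) -> nx.Graph:
    """Erdős–Rényi graph, resampled until connected (mean degree ~4)."""
    p = 1.0 if n <= 1 else min(1.0, 4.0 / (n - 1))
    nodes = [f"{prefix}{i}" for i in range(n)]
    for _ in range(10000):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in combinations(nodes, 2):
            if rng.random() < p:
                g.add_edge(a, b, weight=1.0, pseudo=False)
        if n == 1 or nx.is_connected(g):
            return g
        p = min(1.0, p * 1.1)  # nudge toward connectivity for tiny n
    raise RuntimeError("failed to sample a connected query graph")


def _background(rng: np.random.Generator, cfg: SynthConfig) -> nx.Graph:
    n = cfg.background_size
    nodes = [f"b{i}" for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if cfg.background_model == "erdos_renyi":
        p = cfg.er_p if cfg.er_p is not None else (1.0 if n <= 1 else min(1.0, 4.0 / (n - 1)))
        for a, b in combinations(nodes, 2):
            if rng.random() < p:
                g.add_edge(a, b, weight=1.0, pseudo=False)
    elif cfg.background_model == "preferential_attachment":
        m = min(cfg.pa_m, max(1, n - 1))
        ba = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
        for a, b in ba.edges:
            g.add_edge(nodes[a], nodes[b], weight=1.0, pseudo=False)
    else:
        raise ValueError(f"unknown background model: {cfg.background_model!r}")
    return g


def generate_pair(cfg: SynthConfig) -> tuple[nx.Graph, nx.Graph, SimilarityTable, GroundTruth]:
    """Sample one (query, target, similarity, truth) instance."""
    rng = np.random.default_rng(cfg.rng_seed)

    query = _random_connected_er(rng, cfg.query_size, "q")
    target = _background(rng, cfg)

    # implant a perturbed copy of the query
    qnodes = sorted(query.nodes)
    survivors = [q for q in qnodes if rng.random() >= cfg.p_node_delete]
    if not survivors:
        raise InfeasibleConfigError("node deletion removed the entire implanted module")
    homolog = {q: f"h{qnodes.index(q)}" for q in survivors}
    target.add_nodes_from(homolog.values())

    module_edges: set[tuple[str, str]] = set()
    for a, b in sorted(tuple(sorted(e)) for e in query.edges):
        if a in homolog and b in homolog:
            module_edges.add(tuple(sorted((homolog[a], homolog[b]))))
    # rewire each copied edge within the module w.p. p_edge_rewire
    module_nodes = sorted(homolog.values())
    rewired: set[tuple[str, str]] = set()
    for edge in sorted(module_edges):
        if len(module_nodes) > 2 and rng.random() < cfg.p_edge_rewire:
            for _ in range(20):
                pair = tuple(sorted(map(str, rng.choice(module_nodes, size=2, replace=False))))
                if pair not in module_edges and pair not in rewired and pair != edge:
                    rewired.add(pair)
                    break
            else:
                rewired.add(edge)
        else:
            rewired.add(edge)
    for a, b in sorted(rewired):
        target.add_edge(a, b, weight=1.0, pseudo=False)

    # inserted nodes, each wired to >= 1 module node
    n_insert = math.ceil(cfg.p_node_insert * cfg.query_size)
    inserted = [f"x{i}" for i in range(n_insert)]
    for node in inserted:
        target.add_node(node)
        k = min(len(module_nodes), max(1, int(rng.poisson(2))))
        for partner in rng.choice(module_nodes, size=k, replace=False):
            target.add_edge(node, str(partner), weight=1.0, pseudo=False)

    # bridge the implant to the background
    implant_nodes = sorted(set(module_nodes) | set(inserted))
    background_nodes = sorted(n for n in target.nodes if n.startswith("b"))
    n_bridges = 1 + int(rng.poisson(1.0))
    for _ in range(n_bridges):
        a = str(rng.choice(implant_nodes))
        b = str(rng.choice(background_nodes))
        target.add_edge(a, b, weight=1.0, pseudo=False)

    # similarity: homolog signal + spurious noise
    sim = SimilarityTable()
    for q in survivors:
        sim.set(q, homolog[q], _truncated_positive_normal(rng, cfg.homolog_score_mean, cfg.homolog_score_sd))
    if cfg.spurious_pair_rate > 0:
        spurious_mean = cfg.homolog_score_mean / 4.0
        spurious_sd = cfg.homolog_score_sd / 4.0
        for q in qnodes:
            partner = homolog.get(q)
            for t in sorted(target.nodes):
                if t == partner:
                    continue
                if rng.random() < cfg.spurious_pair_rate:
                    score = _truncated_positive_normal(rng, spurious_mean, spurious_sd)
                    if sim.score(q, t) == 0:
                        sim.set(q, t, score)

    truth = GroundTruth(
        mapping=dict(sorted(homolog.items())),
        implanted_nodes=frozenset(implant_nodes),
        implanted_edges=frozenset(
            tuple(sorted(e)) for e in target.edges if e[0] in set(implant_nodes) and e[1] in set(implant_nodes)
        ),
    )
    return query, target, sim, truth


def recovery_score(result: QueryResult | set[str] | frozenset[str], truth: GroundTruth) -> float:
    """Jaccard overlap between the recovered node set and the implant."""
    nodes = result.nodes if isinstance(result, QueryResult) else frozenset(result)
    if not nodes or not truth.implanted_nodes:
        return 0.0
    return match_score(set(nodes), set(truth.implanted_nodes))
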