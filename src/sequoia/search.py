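"""Seed-network construction, conductance, greedy extension and pruning.

The seed network is the largest connected component of the target
subgraph induced on the selected seeds. It is then grown greedily: at
each step the frontier node whose addition minimizes the subnetwork
conductance is added, provided it cuts the current conductance by at
least a fixed fraction (default 5%), until no such node exists or the
subnetwork would exceed ``cap_factor`` times the query size (default 2x).
Every existing member adjacent to a newly accepted node earns an
extension reward of 1; after extension, non-seed nodes whose reward does
not exceed a threshold (default 0) are pruned.

Conductance here follows the working definition cut / internal — the
number of edges crossing the subnetwork boundary over the number of
edges inside it — which approximates the classical
cut / min(vol(H), vol(complement)) when the subnetwork is much smaller
than the rest of the network. Both are exposed; edge counts ignore
weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .config import Config
from .correspondence import SeedList, normalize, seed_scores, select_seeds
from .csrw import correspondence
from .io import QueryResult, SimilarityTable
from .preprocess import insert_pseudo_edges, reduce_target

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Subnetwork:
    """A node subset of a parent network; induced edges are derived."""

    parent: nx.Graph = field(compare=False, hash=False)
    members: frozenset[str]

    def __post_init__(self):
        missing = self.members - set(self.parent.nodes)
        if missing:
            raise ValueError(f"subnetwork members not in parent: {sorted(missing)[:5]}")

    def induced(self) -> nx.Graph:
        return self.parent.subgraph(self.members)

    def __len__(self) -> int:
        return len(self.members)


def _cut_internal(parent: nx.Graph, members: frozenset[str]) -> tuple[int, int]:
    cut = 0
    internal = 0
    for u in members:
        for v in parent.neighbors(u):
            if v in members:
                internal += 1
            else:
                cut += 1
    return cut, internal // 2


def conductance(parent: nx.Graph, h: Subnetwork | frozenset[str], mode: str = "sequoia") -> float:
    """Conductance of a subnetwork under either definition.

    ``sequoia``: cut / internal edge count, +inf when there is no
    internal edge. ``standard``: cut / min(vol(H), vol(complement)) with
    vol the degree sum; 0 when the cut is empty, +inf when the smaller
    side has zero volume but the cut does not.
    """
    members = h.members if isinstance(h, Subnetwork) else frozenset(h)
    if not members:
        raise ValueError("subnetwork must be non-empty")
    if not members <= set(parent.nodes):
        raise ValueError("subnetwork members must belong to the parent network")
    cut, internal = _cut_internal(parent, members)
    if mode == "sequoia":
        return cut / internal if internal else math.inf
    if mode == "standard":
        if cut == 0:
            return 0.0
        vol_h = sum(parent.degree(u) for u in members)
        vol_rest = 2 * parent.number_of_edges() - vol_h
        denom = min(vol_h, vol_rest)
        return cut / denom if denom else math.inf
    raise ValueError(f"unknown conductance mode: {mode!r}")


def seed_network(target: nx.Graph, seeds: SeedList) -> Subnetwork:
    """Largest connected component of the target induced on the seeds.

    Size ties go to the component containing the best-scoring seed, then
    to the component with the lexicographically smallest member. With no
    induced edges, the single best-scoring seed is returned.
    """
    if len(seeds) == 0:
        raise ValueError("seed list is empty")
    missing = set(seeds.nodes) - set(target.nodes)
    if missing:
        raise ValueError(f"seeds not present in target: {sorted(missing)[:5]}")
    score = seeds.as_dict()
    induced = target.subgraph(seeds.nodes)
    components = [frozenset(c) for c in nx.connected_components(induced)]

    def rank(comp: frozenset[str]) -> tuple:
        return (-len(comp), min(score[n] for n in comp), min(comp))

    best = min(components, key=rank)
    return Subnetwork(target, best)


def extend(
    parent: nx.Graph,
    seed_h: Subnetwork,
    query_size: int,
    reduction: float = 0.05,
    cap_factor: float = 2.0,
    scores: Mapping[str, float] | None = None,
) -> tuple[Subnetwork, dict[str, int], tuple[float, ...]]:
    """Greedy conductance-minimizing extension with reward accounting.

    Returns the extended subnetwork, the reward map (seeds start at 0;
    each accepted node grants +1 to every adjacent existing member and
    itself enters at 0) and the conductance trace. A step is accepted
    when the best candidate's conductance is at most
    ``(1 - reduction)`` times the current one; any finite value beats
    +inf. Candidate ties break by better (lower) seed log-score, then
    lexicographic id.
    """
    if not (0 < reduction < 1):
        raise ValueError("reduction must lie in (0, 1)")
    if cap_factor < 1:
        raise ValueError("cap_factor must be >= 1")
    score_of = dict(scores or {})
    members = set(seed_h.members)
    rewards = {u: 0 for u in members}
    cut, internal = _cut_internal(parent, frozenset(members))
    phi = cut / internal if internal else math.inf
    trace = [phi]
    cap = cap_factor * query_size

    while len(members) + 1 <= cap:
        candidates = sorted(
            {v for u in members for v in parent.neighbors(u)} - members,
            key=lambda u: (score_of.get(u, 0.0), u),
        )
        if not candidates:
            break
        best_u = None
        best_phi = math.inf
        best_state = (cut, internal)
        for u in candidates:
            din = sum(1 for v in parent.neighbors(u) if v in members)
            internal_new = internal + din
            cut_new = cut - din + (parent.degree(u) - din)
            phi_new = cut_new / internal_new if internal_new else math.inf
            if phi_new < best_phi:  # candidate order already encodes tie-breaks
                best_u, best_phi, best_state = u, phi_new, (cut_new, internal_new)
        acceptable = best_u is not None and (
            (math.isinf(phi) and math.isfinite(best_phi)) or best_phi <= (1.0 - reduction) * phi
        )
        if not acceptable:
            break
        for v in parent.neighbors(best_u):
            if v in members:
                rewards[v] += 1
        rewards[best_u] = 0
        members.add(best_u)
        cut, internal = best_state
        phi = best_phi
        trace.append(phi)
    return Subnetwork(parent, frozenset(members)), rewards, tuple(trace)


def prune(
    h: Subnetwork,
    rewards: Mapping[str, int],
    seeds: frozenset[str] | set[str],
    threshold: int = 0,
) -> Subnetwork:
    """Retain seeds plus nodes whose reward strictly exceeds ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = frozenset(u for u in h.members if u in seeds or rewards.get(u, 0) > threshold)
    return Subnetwork(h.parent, keep)


def run_query(
    query: nx.Graph,
    target: nx.Graph,
    sim: SimilarityTable,
    config: Config | None = None,
    query_id: str = "query",
) -> QueryResult:
    """Full deterministic pipeline: reduce + pseudo-edges, CSRW
    correspondence, normalization, seed selection, seed network, greedy
    extension and pruning."""
    cfg = config or Config()
    if query.number_of_nodes() == 0:
        raise ValueError("query network is empty")

    reduced = reduce_target(target, sim, query, threshold=cfg["preprocess.threshold"])
    if reduced.number_of_nodes() == 0:
        raise ValueError(
            "reduced target network is empty: no target node has similarity above the threshold"
        )
    if cfg["preprocess.enable_pseudo_edges"]:
        reduced = insert_pseudo_edges(reduced, sim, sim_quantile=cfg["preprocess.pseudo_sim_quantile"])

    c = correspondence(query, reduced, sim, cfg)
    nc = normalize(c)
    scores = seed_scores(nc)
    n_q = cfg["seeds.n_q"] or query.number_of_nodes()
    seeds = select_seeds(nc, n_q)
    seed_h = seed_network(reduced, seeds)
    logger.info("seed network: %d of %d selected seeds", len(seed_h), len(seeds))

    extended, rewards, trace = extend(
        reduced,
        seed_h,
        query_size=query.number_of_nodes(),
        reduction=cfg["extend.reduction"],
        cap_factor=cfg["extend.cap_factor"],
        scores=scores,
    )
    final = prune(extended, rewards, seed_h.members, threshold=cfg["prune.threshold"])
    logger.info(
        "query %s: %d seeds -> %d extended -> %d final; trace=%s",
        query_id,
        len(seed_h),
        len(extended),
        len(final),
        trace,
    )

    provenance = {}
    for u in extended.members:
        if u in seed_h.members:
            provenance[u] = "seed"
        elif u in final.members:
            provenance[u] = "extended"
        else:
            provenance[u] = "pruned"
    seed_order = tuple(s for s in seeds.nodes if s in seed_h.members)
    return QueryResult(
        query_id=query_id,
        nodes=frozenset(final.members),
        seeds=seed_order,
        rewards=rewards,
        trace=trace,
        provenance=provenance,
    )
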