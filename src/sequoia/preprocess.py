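"""Target-network reduction and pseudo-edge reconnection.

Before the random walk, the target PPI network is reduced to the nodes
with at least one query homolog above a similarity threshold ``T_h``
(default 0, i.e. any positive BLAST-like score keeps a node). Because
that reduction can disconnect the target, pseudo-edges are then inserted
between node pairs that lie in *different* connected components and share
a query node with high similarity to both — a proxy for a plausible but
unobserved interaction. Pseudo-edges carry weight 1.0 and ``pseudo=True``
and are treated like real edges by every downstream stage.
"""

from __future__ import annotations

import logging
from itertools import combinations

import networkx as nx
import numpy as np

from .io import SimilarityTable

logger = logging.getLogger(__name__)


def reduce_target(
    target: nx.Graph,
    sim: SimilarityTable,
    query: nx.Graph,
    threshold: float = 0.0,
) -> nx.Graph:
    """Induced subgraph of ``target`` on nodes with some query similarity
    strictly above ``threshold``. The input graph is not modified."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    query_nodes = set(query.nodes)
    keep = set()
    for t in target.nodes:
        for q, s in sim.queries_of(t).items():
            if q in query_nodes and s > threshold:
                keep.add(t)
                break
    reduced = target.subgraph(keep).copy()
    logger.info(
        "reduced target: %d -> %d nodes (T_h=%g)", target.number_of_nodes(), reduced.number_of_nodes(), threshold
    )
    return reduced


def insert_pseudo_edges(
    reduced: nx.Graph,
    sim: SimilarityTable,
    sim_quantile: float = 0.0,
) -> nx.Graph:
    """Reconnect disconnected components of the reduced target.

    For every unordered target pair in different connected components of
    the *input* graph, a pseudo-edge is added when some query node scores
    "high" against both endpoints, where high means at least the
    ``sim_quantile``-quantile of all positive similarity scores (quantile
    0 accepts any positive score). Insertion is batched: component
    membership is evaluated once on the input, so added edges never
    cascade into further insertions.
    """
    if reduced.number_of_nodes() == 0:
        raise ValueError("reduced network has no nodes")
    if not (0 <= sim_quantile < 1):
        raise ValueError("sim_quantile must lie in [0, 1)")

    out = reduced.copy()
    comp_of: dict[str, int] = {}
    for i, comp in enumerate(nx.connected_components(reduced)):
        for n in comp:
            comp_of[n] = i
    if len(set(comp_of.values())) <= 1:
        return out

    scores = sim.positive_scores()
    cutoff = 0.0 if sim_quantile == 0 or not scores else float(np.quantile(scores, sim_quantile))

    present = set(reduced.nodes)
    added = 0
    for q in sorted(sim.query_nodes):
        hits = sorted(
            t for t, s in sim.targets_of(q).items() if t in present and (s >= cutoff if cutoff > 0 else s > 0)
        )
        for t1, t2 in combinations(hits, 2):
            if comp_of[t1] != comp_of[t2] and not out.has_edge(t1, t2):
                out.add_edge(t1, t2, weight=1.0, pseudo=True)
                added += 1
    if added:
        logger.info("inserted %d pseudo-edges across %d components", added, len(set(comp_of.values())))
    return out
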