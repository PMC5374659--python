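"""Independent brute-force oracles used to cross-check the implementation.

These re-derive the pair-walk transition probabilities, stationary
distribution, conductance and greedy extension with plain dense /
dictionary arithmetic, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math
from itertools import product

import networkx as nx
import numpy as np


def dense_csrw_transition(query: nx.Graph, target: nx.Graph, sim) -> tuple[list, np.ndarray, np.ndarray]:
    """Dense simultaneous / individual transition blocks over all pairs."""
    states = [(q, t) for q in sorted(query.nodes) for t in sorted(target.nodes)]
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    p_sim = np.zeros((n, n))
    p_ind = np.zeros((n, n))
    for (q, t), i in index.items():
        weights = {}
        for x in query.neighbors(q):
            for y in target.neighbors(t):
                s = sim.score(x, y)
                if s > 0:
                    w = query[q][x].get("weight", 1.0) * target[t][y].get("weight", 1.0) * s
                    weights[(x, y)] = weights.get((x, y), 0.0) + w
        if weights:
            total = sum(weights.values())
            for (x, y), w in weights.items():
                p_sim[i, index[(x, y)]] += w / total
        else:
            qn = list(query.neighbors(q))
            if qn:
                wsum = sum(query[q][x].get("weight", 1.0) for x in qn)
                for x in qn:
                    p_ind[i, index[(x, t)]] += 0.5 * query[q][x].get("weight", 1.0) / wsum
            else:
                p_ind[i, i] += 0.5
            tn = list(target.neighbors(t))
            if tn:
                wsum = sum(target[t][y].get("weight", 1.0) for y in tn)
                for y in tn:
                    p_ind[i, index[(q, y)]] += 0.5 * target[t][y].get("weight", 1.0) / wsum
            else:
                p_ind[i, i] += 0.5
    return states, p_sim, p_ind


def is_strongly_connected(p_full: np.ndarray) -> bool:
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components(p_full > 0, directed=True, connection="strong")
    return n_comp == 1


def stationary_eig(p_full: np.ndarray) -> np.ndarray:
    """Stationary distribution via a dense eigen-solve of P^T."""
    vals, vecs = np.linalg.eig(p_full.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def csrw_correspondence_oracle(query: nx.Graph, target: nx.Graph, sim) -> dict[tuple[str, str], float]:
    """Simultaneous-arrival rates from the dense stationary distribution."""
    states, p_sim, p_ind = dense_csrw_transition(query, target, sim)
    pi = stationary_eig(p_sim + p_ind)
    flow = pi @ p_sim
    return {s: float(flow[i]) for i, s in enumerate(states)}


# ---------------------------------------------------------------------------
# conductance and greedy extension


def conductance_bruteforce(graph: nx.Graph, members: set[str], mode: str) -> float:
    cut = sum(1 for a, b in graph.edges if (a in members) != (b in members))
    internal = sum(1 for a, b in graph.edges if a in members and b in members)
    if mode == "sequoia":
        return cut / internal if internal else math.inf
    if cut == 0:
        return 0.0
    vol_h = sum(d for n, d in graph.degree if n in members)
    vol_rest = sum(d for n, d in graph.degree if n not in members)
    denom = min(vol_h, vol_rest)
    return cut / denom if denom else math.inf


def greedy_extension_oracle(
    graph: nx.Graph,
    seed_members: set[str],
    query_size: int,
    reduction: float = 0.05,
    cap_factor: float = 2.0,
    scores: dict[str, float] | None = None,
) -> tuple[set[str], dict[str, int], list[float]]:
    """Exhaustive-scan replay of the greedy conductance extension."""
    scores = scores or {}
    members = set(seed_members)
    rewards = {u: 0 for u in members}
    phi = conductance_bruteforce(graph, members, "sequoia")
    trace = [phi]
    while len(members) + 1 <= cap_factor * query_size:
        frontier = {v for u in members for v in graph.neighbors(u)} - members
        if not frontier:
            break
        scored = []
        for u in sorted(frontier):
            phi_u = conductance_bruteforce(graph, members | {u}, "sequoia")
            scored.append((phi_u, scores.get(u, 0.0), u))
        scored.sort(key=lambda x: (x[0], x[1], x[2]))
        phi_new, _, u = scored[0]
        ok = (math.isinf(phi) and math.isfinite(phi_new)) or phi_new <= (1 - reduction) * phi
        if not ok:
            break
        for v in graph.neighbors(u):
            if v in members:
                rewards[v] += 1
        rewards[u] = 0
        members.add(u)
        phi = phi_new
        trace.append(phi)
    return members, rewards, trace
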