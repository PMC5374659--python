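"""Context-sensitive random walk (CSRW) over query-target node pairs.

The walker occupies a pair state ``(v_q, v_t)``. When the two current
nodes have neighbor pairs ``(x, y)`` with positive node similarity
``s(x, y) > 0``, it moves *simultaneously* on both networks, choosing
``(x, y)`` with probability proportional to
``w(v_q, x) * w(v_t, y) * s(x, y)`` — the product of the two edge
weights and the node similarity. Otherwise it moves *individually*:
it picks one network with probability 1/2 and steps to a neighbor on
that network proportionally to edge weight, the other coordinate held
fixed (a coordinate without neighbors stays in place for that
half-step). This mode switching mirrors the match / insert / delete
states of a pair HMM: an individual move skips over a node that has no
plausible counterpart, making the correspondence estimate robust to
node insertions and deletions.

The node correspondence score ``c(v_q, v_t)`` is the long-run rate at
which the walker *arrives simultaneously* at ``(v_q, v_t)``: the
stationary probability flow entering the state through simultaneous
moves. It is computed deterministically by power iteration on the lazy
chain ``p <- alpha * p + (1 - alpha) * p @ P`` (laziness guarantees
aperiodicity and leaves the stationary distribution unchanged), and the
simultaneous share is read off as ``p @ P_sim`` at convergence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse

from .config import Config
from .io import SimilarityTable

logger = logging.getLogger(__name__)


class WalkSupportError(ValueError):
    """No query/target pair has positive similarity: the walk has empty support."""


@dataclass
class CSRWChain:
    """Sparse transition operator of the pair walk.

    ``p_sim`` and ``p_ind`` are row-substochastic blocks (simultaneous
    and individual moves); their row sums add to 1. States are ordered
    row-major over sorted query then sorted target nodes.
    """

    query_nodes: tuple[str, ...]
    target_nodes: tuple[str, ...]
    p_sim: sparse.csr_matrix
    p_ind: sparse.csr_matrix
    init: np.ndarray  # uniform over positive-similarity pairs
    laziness: float = 0.5

    @property
    def n_states(self) -> int:
        return len(self.query_nodes) * len(self.target_nodes)

    def state_index(self, v_q: str, v_t: str) -> int:
        return self.query_nodes.index(v_q) * len(self.target_nodes) + self.target_nodes.index(v_t)


@dataclass
class CorrespondenceMatrix:
    """Simultaneous-visit rates c(v_q, v_t) as a dense |V_Q| x |V_T| array."""

    matrix: np.ndarray
    query_nodes: tuple[str, ...]
    target_nodes: tuple[str, ...]
    converged: bool = True
    n_iter: int = 0
    mass_deviation: float = 0.0  # max |sum(p) - 1| observed over iterations

    def score(self, v_q: str, v_t: str) -> float:
        return float(self.matrix[self.query_nodes.index(v_q), self.target_nodes.index(v_t)])


def build_chain(
    query: nx.Graph,
    target: nx.Graph,
    sim: SimilarityTable,
    laziness: float = 0.5,
) -> CSRWChain:
    """Construct the sparse CSRW transition blocks for a network pair."""
    if query.number_of_nodes() == 0 or target.number_of_nodes() == 0:
        raise ValueError("both networks must be non-empty")
    if not (0 <= laziness < 1):
        raise ValueError("laziness must lie in [0, 1)")
    qnodes = tuple(sorted(query.nodes))
    tnodes = tuple(sorted(target.nodes))
    qindex = {q: i for i, q in enumerate(qnodes)}
    tindex = {t: j for j, t in enumerate(tnodes)}
    nt = len(tnodes)

    support = [
        (qi, tindex[t])
        for qi, q in enumerate(qnodes)
        for t, s in sim.targets_of(q).items()
        if t in tindex and s > 0
    ]
    if not support:
        raise WalkSupportError("walk has empty support: no positive query/target similarity")

    # neighbor lists with weights, precomputed once
    qnbrs = {q: [(x, query[q][x].get("weight", 1.0)) for x in query.neighbors(q)] for q in qnodes}
    tnbrs = {t: [(y, target[t][y].get("weight", 1.0)) for y in target.neighbors(t)] for t in tnodes}

    sim_rows: list[int] = []
    sim_cols: list[int] = []
    sim_data: list[float] = []
    ind_rows: list[int] = []
    ind_cols: list[int] = []
    ind_data: list[float] = []

    for qi, q in enumerate(qnodes):
        row_of = sim.targets_of  # positive-score lookup per query node
        for ti, t in enumerate(tnodes):
            i = qi * nt + ti
            moves: list[tuple[int, float]] = []
            for x, wq in qnbrs[q]:
                xrow = row_of(x)
                if not xrow:
                    continue
                for y, wt in tnbrs[t]:
                    s = xrow.get(y, 0.0)
                    if s > 0:
                        moves.append((qindex[x] * nt + tindex[y], wq * wt * s))
            if moves:
                total = sum(m[1] for m in moves)
                for j, m in moves:
                    sim_rows.append(i)
                    sim_cols.append(j)
                    sim_data.append(m / total)
            else:
                # individual half-steps: query network then target network
                if qnbrs[q]:
                    wsum = sum(w for _, w in qnbrs[q])
                    for x, w in qnbrs[q]:
                        ind_rows.append(i)
                        ind_cols.append(qindex[x] * nt + ti)
                        ind_data.append(0.5 * w / wsum)
                else:
                    ind_rows.append(i)
                    ind_cols.append(i)
                    ind_data.append(0.5)
                if tnbrs[t]:
                    wsum = sum(w for _, w in tnbrs[t])
                    for y, w in tnbrs[t]:
                        ind_rows.append(i)
                        ind_cols.append(qi * nt + tindex[y])
                        ind_data.append(0.5 * w / wsum)
                else:
                    ind_rows.append(i)
                    ind_cols.append(i)
                    ind_data.append(0.5)

    n = len(qnodes) * nt
    p_sim = sparse.csr_matrix((sim_data, (sim_rows, sim_cols)), shape=(n, n))
    # duplicate (i, i) stay entries from both half-steps must accumulate
    p_ind = sparse.coo_matrix((ind_data, (ind_rows, ind_cols)), shape=(n, n)).tocsr()

    init = np.zeros(n)
    for qi, ti in support:
        init[qi * nt + ti] = 1.0
    init /= init.sum()
    return CSRWChain(qnodes, tnodes, p_sim, p_ind, init, laziness)


def steady_state(
    chain: CSRWChain,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> CorrespondenceMatrix:
    """Power iteration to the stationary distribution; returns the
    correspondence matrix of simultaneous arrival rates.

    Non-convergence after ``max_iter`` sweeps produces a warning and the
    last iterate, flagged ``converged=False``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    alpha = chain.laziness
    p_full = (chain.p_sim + chain.p_ind).tocsr()
    p = chain.init.copy()
    mass_dev = abs(p.sum() - 1.0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p_new = alpha * p + (1.0 - alpha) * (p @ p_full)
        mass_dev = max(mass_dev, abs(p_new.sum() - 1.0))
        delta = np.abs(p_new - p).sum()
        p = p_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"CSRW power iteration did not converge within {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    c_vec = p @ chain.p_sim  # incoming simultaneous flow at stationarity
    matrix = np.asarray(c_vec).reshape(len(chain.query_nodes), len(chain.target_nodes))
    return CorrespondenceMatrix(
        matrix=matrix,
        query_nodes=chain.query_nodes,
        target_nodes=chain.target_nodes,
        converged=converged,
        n_iter=it,
        mass_deviation=float(mass_dev),
    )


def correspondence(
    query: nx.Graph,
    target: nx.Graph,
    sim: SimilarityTable,
    config: Config | None = None,
) -> CorrespondenceMatrix:
    """build_chain followed by steady_state with configured parameters."""
    cfg = config or Config()
    chain = build_chain(query, target, sim, laziness=cfg["csrw.laziness"])
    result = steady_state(chain, tol=cfg["csrw.tol"], max_iter=cfg["csrw.max_iter"])
    logger.info("CSRW converged=%s after %d iterations", result.converged, result.n_iter)
    return result
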