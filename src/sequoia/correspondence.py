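"""Normalization of the correspondence matrix and seed selection.

The raw CSRW scores C are normalized as C_bar = (J_L C + C J_R) / 2,
where J_L and J_R hold the reciprocal row and column sums of C on their
diagonals. A row or column summing to zero contributes nothing to the
corresponding term. The normalized score estimates the *relative*
strength of a pairing within its row and column, which makes networks
of very different sizes comparable.

Seed nodes in the target are the minimizers of
``prod_q (1 - c_bar(v_q, v_t))`` — computed in the log domain — i.e.
the target nodes backed by many strongly corresponding query nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .csrw import CorrespondenceMatrix

_CLIP = 1.0 - 1e-12  # keeps log(1 - c_bar) finite for near-perfect pairs


@dataclass
class NormalizedCorrespondence:
    matrix: np.ndarray  # entries in [0, 1]
    query_nodes: tuple[str, ...]
    target_nodes: tuple[str, ...]

    def score(self, v_q: str, v_t: str) -> float:
        return float(self.matrix[self.query_nodes.index(v_q), self.target_nodes.index(v_t)])


@dataclass
class SeedList:
    """Target node ids ordered by non-decreasing seed log-score."""

    nodes: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self):
        assert len(self.nodes) == len(self.scores)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.nodes, self.scores))

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)


def normalize(c: CorrespondenceMatrix) -> NormalizedCorrespondence:
    """Row/column reciprocal-sum normalization, averaged."""
    m = np.asarray(c.matrix, dtype=float)
    if (m < 0).any():
        raise ValueError("correspondence entries must be nonnegative")
    rowsum = m.sum(axis=1, keepdims=True)
    colsum = m.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        left = np.where(rowsum > 0, m / rowsum, 0.0)
        right = np.where(colsum > 0, m / colsum, 0.0)
    return NormalizedCorrespondence(0.5 * (left + right), c.query_nodes, c.target_nodes)


def seed_scores(nc: NormalizedCorrespondence) -> dict[str, float]:
    """Log-domain seed score for every target node:
    ``sum_q log(1 - min(c_bar, 1 - 1e-12))``; lower is better."""
    clipped = np.minimum(nc.matrix, _CLIP)
    scores = np.log1p(-clipped).sum(axis=0)
    return {t: float(scores[j]) for j, t in enumerate(nc.target_nodes)}


def select_seeds(nc: NormalizedCorrespondence, n_q: int) -> SeedList:
    """The ``n_q`` lowest-scoring target nodes (all, if fewer exist).

    Ties break toward the node with the larger maximum normalized score
    over query nodes, then by lexicographic node id.
    """
    if n_q < 1:
        raise ValueError("n_q must be >= 1")
    if len(nc.target_nodes) == 0:
        raise ValueError("no target nodes to select seeds from")
    scores = seed_scores(nc)
    colmax = nc.matrix.max(axis=0) if nc.matrix.size else np.zeros(len(nc.target_nodes))
    maxscore = {t: float(colmax[j]) for j, t in enumerate(nc.target_nodes)}
    order = sorted(nc.target_nodes, key=lambda t: (scores[t], -maxscore[t], t))
    chosen = order[: min(n_q, len(order))]
    return SeedList(tuple(chosen), tuple(scores[t] for t in chosen))
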