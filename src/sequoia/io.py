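"""Readers and writers for networks, similarity tables, complex sets,
annotation tables and query results.

Networks are plain :class:`networkx.Graph` objects whose edges carry a
positive ``weight`` (default 1.0) and a boolean ``pseudo`` flag (default
False). The readers enforce the core invariants: unique node ids, no
self-loops, strictly positive weights, and max-weight collapse of
duplicate edge records.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input row; message names the file and line number."""


# ---------------------------------------------------------------------------
# networks


def _iter_rows(path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_network(path, directed_input: bool = False) -> nx.Graph:
    """Read an undirected weighted network from a 2- or 3-column TSV.

    Rows are ``node_a<TAB>node_b[<TAB>weight]``; a missing weight means 1.0.
    Duplicate records of the same unordered pair (including reversed order
    when ``directed_input`` is set) collapse to the maximum weight;
    self-loops are dropped with a warning.
    """
    g = nx.Graph()
    for lineno, cols in _iter_rows(path):
        if len(cols) not in (2, 3):
            raise ParseError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(cols)}")
        a, b = cols[0], cols[1]
        if len(cols) == 3:
            try:
                w = float(cols[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric weight {cols[2]!r}") from None
            if not math.isfinite(w) or w <= 0:
                raise ParseError(f"{path}:{lineno}: weight must be a positive finite number")
        else:
            w = 1.0
        if a == b:
            logger.warning("%s:%d: dropping self-loop on %r", path, lineno, a)
            g.add_node(a)
            continue
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], w)
        else:
            g.add_edge(a, b, weight=w, pseudo=False)
    return g


def write_network(path, network: nx.Graph) -> None:
    """Write a network as a sorted canonical edge-list TSV.

    Isolated nodes have no edge row; they are recorded on ``#isolated``
    comment lines, so the read/write round-trip is exact on edge lists.
    """
    with open(path, "w") as fh:
        for n in sorted(network.nodes):
            if network.degree(n) == 0:
                fh.write(f"#isolated\t{n}\n")
        for a, b in sorted(tuple(sorted(e)) for e in network.edges):
            w = network[a][b].get("weight", 1.0)
            fh.write(f"{a}\t{b}\t{w!r}\n")


# ---------------------------------------------------------------------------
# similarity tables


@dataclass
class SimilarityTable:
    """Sparse nonnegative query-node x target-node score map.

    Only strictly positive scores are stored; looking up an absent pair
    returns 0. Mirrors a BLAST-bit-score table between two proteomes.
    """

    _by_query: dict[str, dict[str, float]] = field(default_factory=dict)
    _by_target: dict[str, dict[str, float]] = field(default_factory=dict)

    def set(self, query: str, target: str, score: float) -> None:
        if score <= 0:
            raise ValueError("similarity scores must be strictly positive")
        self._by_query.setdefault(query, {})[target] = score
        self._by_target.setdefault(target, {})[query] = score

    def score(self, query: str, target: str) -> float:
        return self._by_query.get(query, {}).get(target, 0.0)

    def targets_of(self, query: str) -> Mapping[str, float]:
        return self._by_query.get(query, {})

    def queries_of(self, target: str) -> Mapping[str, float]:
        return self._by_target.get(target, {})

    @property
    def query_nodes(self) -> set[str]:
        return set(self._by_query)

    @property
    def target_nodes(self) -> set[str]:
        return set(self._by_target)

    def __len__(self) -> int:
        return sum(len(d) for d in self._by_query.values())

    def __iter__(self) -> Iterator[tuple[str, str, float]]:
        for q, row in self._by_query.items():
            for t, s in row.items():
                yield q, t, s

    def positive_scores(self) -> list[float]:
        return [s for _, _, s in self]


def read_similarity(path) -> SimilarityTable:
    """Read ``query_id<TAB>target_id<TAB>score`` rows; non-positive scores
    are skipped with a warning, duplicates keep the maximum."""
    table = SimilarityTable()
    for lineno, cols in _iter_rows(path):
        if len(cols) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
        q, t = cols[0], cols[1]
        try:
            s = float(cols[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric score {cols[2]!r}") from None
        if s <= 0:
            logger.warning("%s:%d: skipping non-positive score for (%s, %s)", path, lineno, q, t)
            continue
        prev = table.score(q, t)
        if prev:
            logger.warning("%s:%d: duplicate entry (%s, %s); keeping max", path, lineno, q, t)
        table.set(q, t, max(prev, s))
    return table


def write_similarity(path, table: SimilarityTable) -> None:
    with open(path, "w") as fh:
        for q, t, s in sorted(table):
            fh.write(f"{q}\t{t}\t{s!r}\n")


# ---------------------------------------------------------------------------
# complex sets & annotations


def read_complexes(path) -> dict[str, set[str]]:
    """Read a GMT-like file: ``name<TAB>member1<TAB>member2...``."""
    complexes: dict[str, set[str]] = {}
    for lineno, cols in _iter_rows(path):
        if len(cols) < 2:
            raise ParseError(f"{path}:{lineno}: complex {cols[0]!r} has no members")
        complexes[cols[0]] = set(cols[1:])
    return complexes


def write_complexes(path, complexes: Mapping[str, Iterable[str]]) -> None:
    with open(path, "w") as fh:
        for name in sorted(complexes):
            members = "\t".join(sorted(complexes[name]))
            fh.write(f"{name}\t{members}\n")


def read_annotations(path):
    """Read a flat ``protein_id<TAB>term_id`` table into an AnnotationMap."""
    from .evaluate import AnnotationMap

    pairs = []
    for lineno, cols in _iter_rows(path):
        if len(cols) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
        pairs.append((cols[0], cols[1]))
    return AnnotationMap.from_pairs(pairs)


# ---------------------------------------------------------------------------
# query results


@dataclass(frozen=True)
class QueryResult:
    """Final output of a network query.

    ``nodes`` is the final matched target node set; ``seeds`` the ordered
    seed-network members; ``rewards`` maps every node that entered the
    search to its extension-reward count; ``trace`` is the conductance
    sequence over extension steps; ``provenance`` tags each searched node
    as seed / extended / pruned.
    """

    query_id: str
    nodes: frozenset[str]
    seeds: tuple[str, ...]
    rewards: Mapping[str, int]
    trace: tuple[float, ...]
    provenance: Mapping[str, str]

    def __post_init__(self):
        object.__setattr__(self, "rewards", dict(self.rewards))
        object.__setattr__(self, "provenance", dict(self.provenance))

    @property
    def pruned(self) -> frozenset[str]:
        return frozenset(n for n, tag in self.provenance.items() if tag == "pruned")


def write_result(path, result: QueryResult) -> None:
    """Emit a structured key-value + node-table text record."""
    with open(path, "w") as fh:
        fh.write(f"query_id\t{result.query_id}\n")
        fh.write("seeds\t" + ",".join(result.seeds) + "\n")
        fh.write("trace\t" + ",".join(repr(x) for x in result.trace) + "\n")
        fh.write("#node\tprovenance\treward\n")
        for node in sorted(result.provenance):
            fh.write(f"{node}\t{result.provenance[node]}\t{result.rewards.get(node, 0)}\n")


def read_result(path) -> QueryResult:
    header: dict[str, str] = {}
    provenance: dict[str, str] = {}
    rewards: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] in {"query_id", "seeds", "trace"}:
                header[cols[0]] = cols[1] if len(cols) > 1 else ""
            elif len(cols) == 3:
                provenance[cols[0]] = cols[1]
                rewards[cols[0]] = int(cols[2])
            else:
                raise ParseError(f"{path}:{lineno}: unrecognized row")
    seeds = tuple(s for s in header.get("seeds", "").split(",") if s)
    trace = tuple(float(x) for x in header.get("trace", "").split(",") if x)
    nodes = frozenset(n for n, tag in provenance.items() if tag != "pruned")
    return QueryResult(
        query_id=header.get("query_id", ""),
        nodes=nodes,
        seeds=seeds,
        rewards=rewards,
        trace=trace,
        provenance=provenance,
    )
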