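"""Evaluation metrics for network querying results.

Implements the matching score (Jaccard index against a gold-standard
complex set), term information content with an informativeness filter,
a one-sided hypergeometric enrichment test with Benjamini-Hochberg FDR
over a flat protein-to-term annotation table, and the hit / functionally
coherent (FC) hit / specificity (SPE) classification of query results.

Annotations are consumed as a flat table: no ontology graph is parsed
and no ancestor propagation is performed, so any term propagation or
evidence-code filtering must be applied upstream. The annotation
universe (all annotated proteins) stands in for the per-root protein
set when computing information content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationMap:
    """protein -> term-set map with a consistent term -> protein reverse
    index and the universe of annotated proteins."""

    by_protein: dict[str, set[str]] = field(default_factory=dict)
    by_term: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnnotationMap":
        amap = cls()
        for protein, term in pairs:
            amap.by_protein.setdefault(protein, set()).add(term)
            amap.by_term.setdefault(term, set()).add(protein)
        return amap

    @property
    def universe(self) -> set[str]:
        return set(self.by_protein)

    def terms_of(self, protein: str) -> set[str]:
        return self.by_protein.get(protein, set())

    def proteins_of(self, term: str) -> set[str]:
        return self.by_term.get(term, set())


@dataclass(frozen=True)
class TermStats:
    p_value: float
    q_value: float
    overlap: int


@dataclass
class EnrichmentResult:
    """Per-term raw p, BH-adjusted q and overlap counts."""

    terms: dict[str, TermStats] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def best_term(self) -> str | None:
        """Most significantly enriched term: smallest q, then largest
        overlap, then lexicographic term id. None when nothing was tested."""
        if not self.terms:
            return None
        return min(self.terms, key=lambda t: (self.terms[t].q_value, -self.terms[t].overlap, t))


def match_score(q: set[str], c: set[str]) -> float:
    """Jaccard index |Q ∩ C| / |Q ∪ C| between two node sets."""
    if not q or not c:
        raise ValueError("matching score requires two non-empty node sets")
    q, c = set(q), set(c)
    return len(q & c) / len(q | c)


def count_matches(
    results: Mapping[str, set[str]],
    reference: Mapping[str, set[str]],
    threshold: float = 0.5,
) -> int:
    """Number of results matching at least one reference complex at
    ``match_score >= threshold``."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    count = 0
    for nodes in results.values():
        if any(nodes and ref and match_score(nodes, ref) >= threshold for ref in reference.values()):
            count += 1
    return count


def information_content(term: str, ann: AnnotationMap) -> float:
    """IC(g) = -log2(|g| / |root(g)|) with |root(g)| the annotated universe."""
    import math

    proteins = ann.proteins_of(term)
    if not proteins:
        raise KeyError(f"term {term!r} has no annotations")
    return -math.log2(len(proteins) / len(ann.universe))


def enrichment_test(
    nodes: set[str],
    ann: AnnotationMap,
    background: set[str] | None = None,
    ic_min: float = 2.0,
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation test with BH-FDR.

    Only terms with information content >= ``ic_min`` (computed against
    the full annotation universe) and at least one overlap with ``nodes``
    are tested. For a term with K annotated proteins in the background,
    overlap k and draw size n = |nodes|, p = P(X >= k) for
    X ~ Hypergeom(N, K, n).
    """
    bg = set(background) if background is not None else ann.universe
    if not bg:
        raise ValueError("background set is empty")
    if not set(nodes) <= bg:
        raise ValueError("query nodes must be a subset of the background")
    n = len(nodes)
    big_n = len(bg)
    tested: list[tuple[str, float, int]] = []
    for term in sorted(ann.by_term):
        if information_content(term, ann) < ic_min:
            continue
        term_bg = ann.proteins_of(term) & bg
        k = len(term_bg & set(nodes))
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, big_n, len(term_bg), n))
        tested.append((term, min(p, 1.0), k))
    result = EnrichmentResult()
    if tested:
        qvals = multipletests([p for _, p, _ in tested], method="fdr_bh")[1]
        for (term, p, k), q in zip(tested, qvals):
            result.terms[term] = TermStats(p_value=p, q_value=float(q), overlap=k)
    return result


@dataclass(frozen=True)
class HitRecord:
    """Hit classification of one querying result.

    ``significant_*`` fields relate the result to the query's most
    significantly enriched term; the plain ``hit``/``fc_hit`` fields use
    the result's own most enriched term, measuring biological
    significance regardless of agreement with the query.
    """

    hit: bool
    fc_hit: bool
    significant_hit: bool
    significant_fc_hit: bool
    spe: float
    significant_spe: float
    query_term: str | None
    result_term: str | None


def _annotated_fraction(nodes: set[str], term: str | None, ann: AnnotationMap) -> float:
    if term is None or not nodes:
        return 0.0
    return sum(1 for u in nodes if term in ann.terms_of(u)) / len(nodes)


def classify_hits(
    query_nodes: set[str],
    result_nodes: set[str],
    ann: AnnotationMap,
    background: set[str] | None = None,
    p_threshold: float = 0.05,
    ic_min: float = 2.0,
) -> HitRecord:
    """Classify a querying result against its query's enrichment profile.

    The query's significant term is its lowest-FDR enriched term; the
    result is a *significant hit* when that term is also enriched in the
    result below ``p_threshold``, and a *significant FC hit* when
    additionally at least half the result proteins carry the term. The
    plain hit / FC-hit flags apply the same rules to the result's own
    top term.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must lie in (0, 1)")
    q_enr = enrichment_test(query_nodes, ann, background, ic_min)
    r_enr = enrichment_test(result_nodes, ann, background, ic_min)

    query_term = q_enr.best_term()
    result_term = r_enr.best_term()

    hit = result_term is not None and r_enr.terms[result_term].q_value < p_threshold
    spe = _annotated_fraction(result_nodes, result_term, ann)
    fc_hit = hit and spe >= 0.5

    significant_hit = (
        query_term is not None
        and query_term in r_enr
        and r_enr.terms[query_term].q_value < p_threshold
    )
    significant_spe = _annotated_fraction(result_nodes, query_term, ann)
    significant_fc_hit = significant_hit and significant_spe >= 0.5

    return HitRecord(
        hit=hit,
        fc_hit=fc_hit,
        significant_hit=significant_hit,
        significant_fc_hit=significant_fc_hit,
        spe=spe,
        significant_spe=significant_spe,
        query_term=query_term,
        result_term=result_term,
    )
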