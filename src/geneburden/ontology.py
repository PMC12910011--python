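"""Phenotype-ontology statistics on an is_a DAG.

Parses an OBO file (e.g. the Human Phenotype Ontology) into a minimal
directed acyclic graph, derives per-term specificity statistics, and
computes information-content based patient-patient phenotype similarity.

Two statistics drive the downstream analyses:

* the *relative height* of a term, ``depth / (depth + height)`` with
  longest-path depth (root -> term) and height (term -> deepest leaf).
  It is 0 at the root and 1 at a leaf, and its mean over a patient's
  term set ("HPO mean") measures how specifically the patient was
  phenotyped;
* Lin similarity between terms, ``2 * IC(MICA) / (IC(t1) + IC(t2))``,
  with annotation-frequency information content, aggregated between two
  term sets by the symmetric best-match average. ``1 - similarity``
  yields a distance matrix suitable for external embedding tools.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyError",
    "OboParseError",
    "OntologyGraph",
    "TermStat",
    "AnnotationSet",
    "parse_obo",
    "compute_term_stats",
    "mean_specificity",
    "term_ic",
    "set_similarity",
    "similarity_matrix",
    "term_stats_frame",
]


class OntologyError(ValueError):
    """Structural problem with an ontology graph."""


class OboParseError(OntologyError):
    """Malformed OBO input."""


@dataclass(frozen=True)
class TermStat:
    """Longest-path position of a term within the DAG."""

    term_id: str
    depth: int
    height: int

    @property
    def relative_height(self) -> float:
        total = self.depth + self.height
        if total == 0:
            return 0.0
        return self.depth / total


@dataclass(frozen=True)
class AnnotationSet:
    """A non-empty set of ontology terms attached to one entity
    (a patient, or a disease treated as one individual)."""

    entity_id: str
    terms: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(self.terms))
        if not self.terms:
            raise OntologyError(
                f"annotation set for {self.entity_id!r} is empty"
            )

    def validate_against(self, graph: "OntologyGraph") -> None:
        unknown = self.terms - graph.terms
        if unknown:
            raise OntologyError(
                f"annotation set for {self.entity_id!r} uses unknown terms: "
                + ", ".join(sorted(unknown))
            )


class OntologyGraph:
    """An is_a DAG with a single root.

    ``parents`` maps every term to its (possibly empty) set of is_a
    parents; the unique term with no parents is the root.
    """

    def __init__(
        self,
        parents: Mapping[str, Iterable[str]],
        names: Mapping[str, str] | None = None,
    ) -> None:
        self.parents: dict[str, frozenset[str]] = {
            t: frozenset(p) for t, p in parents.items()
        }
        self.terms: frozenset[str] = frozenset(self.parents)
        self.name: dict[str, str] = dict(names or {})
        for term, ps in self.parents.items():
            missing = ps - self.terms
            if missing:
                raise OntologyError(
                    f"term {term} references unknown parent(s): "
                    + ", ".join(sorted(missing))
                )
        self.children: dict[str, set[str]] = {t: set() for t in self.terms}
        for term, ps in self.parents.items():
            for p in ps:
                self.children[p].add(term)
        roots = sorted(t for t, ps in self.parents.items() if not ps)
        if len(roots) != 1:
            raise OntologyError(
                f"expected exactly one root term, found {len(roots)}: "
                + ", ".join(roots[:5])
            )
        self.root: str = roots[0]
        dg = self._digraph()
        if not nx.is_directed_acyclic_graph(dg):
            cycle = nx.find_cycle(dg)
            raise OntologyError(
                f"ontology contains a cycle through {cycle[0][0]}"
            )
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def _digraph(self) -> nx.DiGraph:
        """parent -> child edges (direction of increasing specificity)."""
        dg = nx.DiGraph()
        dg.add_nodes_from(self.terms)
        for term, ps in self.parents.items():
            for p in ps:
                dg.add_edge(p, term)
        return dg

    def ancestors_with_self(self, term: str) -> frozenset[str]:
        """All terms on some path from the root to ``term``, inclusive."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        if term not in self.terms:
            raise OntologyError(f"unknown term {term!r}")
        out: set[str] = {term}
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents[t])
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def leaves(self) -> frozenset[str]:
        return frozenset(t for t, c in self.children.items() if not c)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def to_obo(self) -> str:
        """Serialise back to a minimal OBO 1.2 document (deterministic)."""
        out = ["format-version: 1.2", ""]
        for term in sorted(self.terms):
            out.append("[Term]")
            out.append(f"id: {term}")
            out.append(f"name: {self.name.get(term, term)}")
            for p in sorted(self.parents[term]):
                out.append(f"is_a: {p} ! {self.name.get(p, p)}")
            out.append("")
        return "\n".join(out) + "\n"


def _prescan_obo(text: str) -> int:
    """Validate stanza syntax, returning the count of obsolete terms.

    Raises :class:`OboParseError` with a 1-based line number for the
    first malformed line inside a [Term] stanza.
    """
    n_obsolete = 0
    in_term = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise OboParseError(
                    f"line {lineno}: malformed stanza header {line!r}"
                )
            in_term = line == "[Term]"
            continue
        if in_term and ":" not in line:
            raise OboParseError(
                f"line {lineno}: malformed tag-value line {line!r}"
            )
        if in_term and line.replace(" ", "").lower().startswith(
            "is_obsolete:true"
        ):
            n_obsolete += 1
    return n_obsolete


def parse_obo(source: Union[str, Path, IO[str]]) -> OntologyGraph:
    """Parse OBO 1.2/1.4 text into an :class:`OntologyGraph`.

    Obsolete terms are dropped (with a logged count); only ``is_a``
    edges are retained. The result is independent of stanza order.

    Parameters
    ----------
    source
        Path to an OBO file, or an open text stream, or a string of
        OBO text (recognised by containing a newline).
    """
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        s = str(source)
        text = s if "\n" in s else Path(s).read_text()

    n_obsolete = _prescan_obo(text)
    if n_obsolete:
        logger.info("parse_obo: dropped %d obsolete term(s)", n_obsolete)
    try:
        multigraph = obonet.read_obo(io.StringIO(text))
    except Exception as exc:  # pragma: no cover - obonet internals vary
        raise OboParseError(f"failed to parse OBO input: {exc}") from exc

    parents: dict[str, set[str]] = {t: set() for t in multigraph.nodes}
    names = {
        t: data.get("name", t) for t, data in multigraph.nodes(data=True)
    }
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a" and parent in parents:
            parents[child].add(parent)
    return OntologyGraph(parents, names)


def compute_term_stats(graph: OntologyGraph) -> dict[str, TermStat]:
    """Longest-path depth and height for every term.

    Depth is the length (in edges) of the longest root->term path;
    height the longest term->leaf path. Both are computed by a single
    topological relaxation over the DAG.
    """
    dg = graph._digraph()
    order = list(nx.topological_sort(dg))
    depth: dict[str, int] = {graph.root: 0}
    for term in order:
        if term == graph.root:
            continue
        ps = graph.parents[term]
        reachable = [depth[p] for p in ps if p in depth]
        if not reachable:
            raise OntologyError(f"term {term} unreachable from root")
        depth[term] = max(reachable) + 1
    if len(depth) != len(graph):
        missing = sorted(graph.terms - set(depth))
        raise OntologyError(
            f"{len(missing)} term(s) unreachable from root, e.g. {missing[0]}"
        )
    height: dict[str, int] = {}
    for term in reversed(order):
        kids = graph.children[term]
        height[term] = max((height[k] + 1 for k in kids), default=0)
    return {
        t: TermStat(term_id=t, depth=depth[t], height=height[t])
        for t in graph.terms
    }


def mean_specificity(
    annotation: AnnotationSet, stats: Mapping[str, TermStat]
) -> float:
    """Arithmetic mean of relative heights over a patient's terms
    (the "HPO mean" feature)."""
    missing = [t for t in annotation.terms if t not in stats]
    if missing:
        raise OntologyError(
            f"no term statistics for: {', '.join(sorted(missing))}"
        )
    values = [stats[t].relative_height for t in annotation.terms]
    return sum(values) / len(values)


def term_ic(
    graph: OntologyGraph, corpus: Sequence[AnnotationSet]
) -> dict[str, float]:
    """Annotation-frequency information content.

    ``IC(t) = -ln(n_t / N)`` where ``n_t`` counts corpus sets annotated
    with ``t`` or any descendant of ``t`` (i.e. whose ancestor closure
    contains ``t``) and ``N`` is the corpus size. Terms never observed
    receive the IC of the rarest observed term.
    """
    if not corpus:
        raise OntologyError("IC requires a non-empty corpus")
    counts: dict[str, int] = {t: 0 for t in graph.terms}
    for aset in corpus:
        aset.validate_against(graph)
        closure: set[str] = set()
        for t in aset.terms:
            closure |= graph.ancestors_with_self(t)
        for t in closure:
            counts[t] += 1
    n = len(corpus)
    ic: dict[str, float] = {}
    observed = [c for c in counts.values() if c > 0]
    max_ic = max((-math.log(c / n) for c in observed), default=0.0)
    for t, c in counts.items():
        ic[t] = -math.log(c / n) if c > 0 else max_ic
    return ic


def _lin(
    t1: str, t2: str, graph: OntologyGraph, ic: Mapping[str, float]
) -> float:
    common = graph.ancestors_with_self(t1) & graph.ancestors_with_self(t2)
    # MICA: max IC, ties broken by lexicographic id for determinism
    mica = max(common, key=lambda t: (ic[t], t))
    denom = ic[t1] + ic[t2]
    if denom <= 0.0:
        return 0.0
    return 2.0 * ic[mica] / denom


def set_similarity(
    a: AnnotationSet,
    b: AnnotationSet,
    graph: OntologyGraph,
    ic: Mapping[str, float],
) -> float:
    """Symmetric best-match-average Lin similarity between two term sets.

    For each term of one set the best Lin similarity in the other set is
    taken; the two directional means are averaged. Identical sets of
    informative terms score 1; sets whose only shared ancestor is the
    root score 0.
    """
    ta, tb = sorted(a.terms), sorted(b.terms)
    sim = [[_lin(x, y, graph, ic) for y in tb] for x in ta]
    best_a = sum(max(row) for row in sim) / len(ta)
    best_b = sum(max(sim[i][j] for i in range(len(ta))) for j in range(len(tb))) / len(tb)
    return 0.5 * (best_a + best_b)


def similarity_matrix(
    corpus: Sequence[AnnotationSet],
    graph: OntologyGraph,
    ic: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise similarity and distance (1 - similarity) matrices.

    Rows/columns follow corpus order and are labelled by entity id.
    """
    if len(corpus) < 2:
        raise OntologyError("similarity matrix needs at least two sets")
    if ic is None:
        ic = term_ic(graph, corpus)
    ids = [a.entity_id for a in corpus]
    n = len(corpus)
    mat = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i, n):
            s = set_similarity(corpus[i], corpus[j], graph, ic)
            mat[i][j] = mat[j][i] = s
    sim = pd.DataFrame(mat, index=ids, columns=ids)
    dist = 1.0 - sim
    return sim, dist


def term_stats_frame(stats: Mapping[str, TermStat]) -> pd.DataFrame:
    """Term statistics as a tidy frame (term_id, depth, height,
    relative_height), sorted by term id — the term-stats TSV layout."""
    rows = [
        {
            "term_id": s.term_id,
            "depth": s.depth,
            "height": s.height,
            "relative_height": s.relative_height,
        }
        for s in sorted(stats.values(), key=lambda s: s.term_id)
    ]
    return pd.DataFrame(rows)
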