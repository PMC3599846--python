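"""Gene Ontology graph handling: parsing, term resolution, semantic expansion.

The ontology is modelled as a directed acyclic graph whose edges point from
child to parent and are restricted to the two transitive relations ``is_a``
and ``part_of``.  The *semantic expansion* of a term is the term itself plus
every descendant reachable against those edges; genes annotated to any member
of the expansion inherit the meaning of the original term.

Granularity of a term is characterised by two numbers: the mean length (in
edges) of all distinct directed paths from the term to its namespace root,
and its descendant count.  Both are used to sample random terms comparable
to a reference term.
"""

from __future__ import annotations

import io
import logging
import random
import re
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import obonet

from .errors import (
    AmbiguousTermError,
    ObsoleteTermError,
    OboParseError,
    StructuralError,
    UnknownTermError,
)

logger = logging.getLogger(__name__)

NAMESPACES = frozenset(
    {"biological_process", "molecular_function", "cellular_component"}
)

#: relations followed when computing closures; all others are parsed but ignored
CLOSURE_RELATIONS = frozenset({"is_a", "part_of"})

_TERM_ID_RE = re.compile(r"^GO:\d{7}$")
_SYNONYM_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"')


class TermID(str):
    """A Gene Ontology identifier, ``GO:`` followed by seven digits."""

    def __new__(cls, value: str) -> "TermID":
        if not _TERM_ID_RE.match(value):
            raise ValueError(f"not a valid GO identifier: {value!r}")
        return super().__new__(cls, value)


def looks_like_term_id(text: str) -> bool:
    return bool(_TERM_ID_RE.match(text.strip().upper()))


@dataclass
class OntologyTerm:
    id: TermID
    name: str
    namespace: str
    synonyms: list[str] = field(default_factory=list)
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError(f"term {self.id} has an empty name")
        seen: set[str] = set()
        deduped = []
        for syn in self.synonyms:
            key = syn.casefold()
            if key not in seen:
                seen.add(key)
                deduped.append(syn)
        self.synonyms = deduped


@dataclass(frozen=True)
class OntologyEdge:
    child: TermID
    parent: TermID
    relation: str  # "is_a" or "part_of"


class OntologyGraph:
    """Terms plus typed child->parent edges, with closure helpers.

    ``closure`` is a :class:`networkx.DiGraph` over non-obsolete terms holding
    only ``is_a``/``part_of`` edges; every reachability query runs on it.
    """

    def __init__(self, terms: dict[TermID, OntologyTerm], edges: Iterable[OntologyEdge]):
        self.terms = dict(terms)
        self.edges: set[OntologyEdge] = set(edges)
        self.closure = nx.DiGraph()
        for tid, term in self.terms.items():
            if not term.obsolete:
                self.closure.add_node(tid)
        for e in self.edges:
            if e.child == e.parent:
                raise StructuralError(f"self-loop on {e.child}")
            for endpoint in (e.child, e.parent):
                if endpoint not in self.terms:
                    raise StructuralError(f"edge endpoint {endpoint} is not a known term")
            child_ns = self.terms[e.child].namespace
            parent_ns = self.terms[e.parent].namespace
            if child_ns != parent_ns:
                raise StructuralError(
                    f"cross-namespace edge {e.child} ({child_ns}) -> {e.parent} ({parent_ns})"
                )
            self.closure.add_edge(e.child, e.parent, relation=e.relation)
        if not nx.is_directed_acyclic_graph(self.closure):
            cycle = nx.find_cycle(self.closure)
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[0][0]}"
            raise StructuralError(f"cycle over is_a/part_of edges: {path}")

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def roots(self) -> set[TermID]:
        """Non-obsolete terms with no outgoing parent edge."""
        return {
            t for t in self.closure.nodes if self.closure.out_degree(t) == 0
        }

    def namespace_roots(self, namespace: str) -> set[TermID]:
        return {t for t in self.roots if self.terms[t].namespace == namespace}

    def _require_live(self, term: str) -> TermID:
        if term not in self.terms:
            raise UnknownTermError(f"unknown term: {term}")
        if self.terms[term].obsolete:
            raise ObsoleteTermError(f"term {term} is obsolete")
        return TermID(term)


def parse_obo(stream) -> OntologyGraph:
    """Parse OBO 1.2 flat-file text into an :class:`OntologyGraph`.

    Obsolete terms are retained but flagged; relationships other than
    ``is_a``/``part_of`` are dropped (a count is logged).  Accepts a string
    or a text file object.
    """
    if isinstance(stream, str):
        text = stream
    else:
        text = stream.read()
    _prescan(text)
    g = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)

    terms: dict[TermID, OntologyTerm] = {}
    for node, data in g.nodes(data=True):
        if "name" not in data:
            raise StructuralError(f"term {node} referenced by an edge but never defined")
        synonyms = []
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.match(raw)
            if not m:
                raise OboParseError(f"unparseable synonym line for {node}: {raw!r}")
            synonyms.append(m.group(1))
        terms[TermID(node)] = OntologyTerm(
            id=TermID(node),
            name=data["name"],
            namespace=data.get("namespace", "biological_process"),
            synonyms=synonyms,
            obsolete=data.get("is_obsolete", "false") == "true",
        )

    edges: list[OntologyEdge] = []
    ignored = 0
    for child, parent, relation in g.edges(keys=True):
        if relation in CLOSURE_RELATIONS:
            edges.append(OntologyEdge(TermID(child), TermID(parent), relation))
        else:
            ignored += 1
    if ignored:
        logger.info("ignored %d relationship(s) other than is_a/part_of", ignored)
    return OntologyGraph(terms, edges)


def _prescan(text: str) -> None:
    """Reject stanza lines without a tag, naming the offending line."""
    in_term = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("!"):
            continue
        if stripped.startswith("["):
            in_term = stripped == "[Term]"
            continue
        if in_term and ":" not in stripped:
            raise OboParseError(f"malformed stanza line {lineno}: {line!r}")


def resolve_term(graph: OntologyGraph, text: str) -> TermID:
    """Resolve user text to a term ID.

    Matching is case-insensitive after trimming; an identifier match takes
    precedence over a name match, and a name match over a synonym match.
    """
    needle = text.strip()
    if looks_like_term_id(needle):
        tid = needle.upper()
        if tid in graph.terms:
            if graph.terms[tid].obsolete:
                raise ObsoleteTermError(f"term {tid} is obsolete")
            return TermID(tid)
        raise UnknownTermError(f"unknown term identifier: {tid}")

    folded = needle.casefold()
    name_hits = [t for t in graph.terms.values() if t.name.casefold() == folded]
    winner = _pick(name_hits, text)
    if winner is not None:
        return winner
    syn_hits = [
        t
        for t in graph.terms.values()
        if any(s.casefold() == folded for s in t.synonyms)
    ]
    winner = _pick(syn_hits, text)
    if winner is not None:
        return winner
    raise UnknownTermError(f"no term matches {text!r}")


def _pick(hits: list[OntologyTerm], text: str) -> TermID | None:
    live = [t for t in hits if not t.obsolete]
    if len(live) > 1:
        raise AmbiguousTermError(text, [t.id for t in live])
    if live:
        return live[0].id
    if hits:  # only obsolete terms match at this tier
        raise ObsoleteTermError(f"{text!r} matches only obsolete term(s): "
                                + ", ".join(sorted(t.id for t in hits)))
    return None


def suggest_terms(
    graph: OntologyGraph, prefix: str, limit: int = 10
) -> list[tuple[TermID, str]]:
    """Prefix completion over names and synonyms (case-insensitive).

    Returns up to ``limit`` ``(term id, matched string)`` pairs ordered by
    term name.  Obsolete terms are never suggested.
    """
    if len(prefix) < 2:
        raise ValueError("prefix must be at least 2 characters")
    folded = prefix.casefold()
    out: list[tuple[TermID, str]] = []
    for term in sorted(graph.terms.values(), key=lambda t: (t.name.casefold(), t.id)):
        if term.obsolete:
            continue
        for candidate in [term.name, *term.synonyms]:
            if candidate.casefold().startswith(folded):
                out.append((term.id, candidate))
                break
        if len(out) >= limit:
            break
    return out


def expansion_set(graph: OntologyGraph, term: str) -> set[TermID]:
    """The term plus all of its descendants over is_a/part_of edges."""
    tid = graph._require_live(term)
    below = nx.ancestors(graph.closure, tid)  # nodes with a path *to* tid
    return {tid, *(TermID(t) for t in below)}


def descendant_count(graph: OntologyGraph, term: str) -> int:
    return len(expansion_set(graph, term)) - 1


def mean_path_to_root(graph: OntologyGraph, term: str) -> float:
    """Mean edge count over all distinct directed paths to the namespace root.

    Multiple inheritance multiplies paths; every distinct path contributes to
    the average (not just the shortest).  Computed by dynamic programming in
    topological order, so dense diamonds stay cheap.
    """
    tid = graph._require_live(term)
    ns = graph.terms[tid].namespace
    above = nx.descendants(graph.closure, tid) | {tid}
    reachable_roots = graph.namespace_roots(ns) & above
    if not reachable_roots:
        raise StructuralError(f"term {tid} does not reach a root of {ns}")
    if len(reachable_roots) > 1:
        raise StructuralError(
            f"term {tid} reaches multiple roots: {sorted(reachable_roots)}"
        )
    (root,) = reachable_roots
    if tid == root:
        return 0.0
    sub = graph.closure.subgraph(above)
    counts: dict[str, int] = {root: 1}
    totals: dict[str, int] = {root: 0}
    for node in reversed(list(nx.topological_sort(sub))):
        if node == root:
            continue
        c = t = 0
        for parent in sub.successors(node):
            pc = counts.get(parent, 0)
            c += pc
            t += totals.get(parent, 0) + pc
        counts[node], totals[node] = c, t
    return totals[tid] / counts[tid]


@dataclass
class GranularityFilter:
    """Admissible granularity window for random term sampling.

    Defaults span the window between the least and the most specific of the
    three lipid-metabolism reference terms: a mean path to the root between
    3.5 and 5.25 edges, and between 35 and 244 descendants.
    """

    min_mean_path: float = 3.5
    max_mean_path: float = 5.25
    min_descendants: int = 35
    max_descendants: int = 244

    def __post_init__(self) -> None:
        if self.min_mean_path > self.max_mean_path:
            raise ValueError("min_mean_path > max_mean_path")
        if self.min_descendants > self.max_descendants:
            raise ValueError("min_descendants > max_descendants")

    def admits(self, mean_path: float, n_descendants: int) -> bool:
        return (
            self.min_mean_path <= mean_path <= self.max_mean_path
            and self.min_descendants <= n_descendants <= self.max_descendants
        )


def sample_similar_terms(
    graph: OntologyGraph,
    namespace: str,
    granularity: GranularityFilter,
    n: int,
    seed: int,
) -> list[TermID]:
    """Sample ``n`` distinct terms of comparable granularity, uniformly.

    Deterministic for a fixed ``(graph, granularity, n, seed)``.  Terms that
    do not reach a unique namespace root are silently excluded from the
    candidate pool.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    candidates: list[TermID] = []
    for tid in sorted(graph.closure.nodes):
        if graph.terms[tid].namespace != namespace:
            continue
        try:
            mp = mean_path_to_root(graph, tid)
        except StructuralError:
            continue
        if granularity.admits(mp, descendant_count(graph, tid)):
            candidates.append(TermID(tid))
    if len(candidates) < n:
        raise UnknownTermError(
            f"only {len(candidates)} term(s) satisfy the granularity filter, need {n}"
        )
    return random.Random(seed).sample(candidates, n)
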