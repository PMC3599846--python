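"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the package's graph/retrieval code
paths: reachability is exhaustive DFS over raw edge lists, path statistics
come from explicit path enumeration, and query evaluation re-interprets the
boolean tree per record.
"""

from __future__ import annotations

import random

from gosempub.ontology import OntologyEdge, OntologyGraph, OntologyTerm, TermID
from gosempub.query_builder import FieldTag
from gosempub.retrieval import Citation, Corpus, phrase_in


def random_ontology(seed: int, n_terms: int = 15) -> OntologyGraph:
    """A random single-namespace DAG built directly from domain objects."""
    rng = random.Random(seed)
    terms = {}
    edges = []
    for i in range(1, n_terms + 1):
        tid = TermID(f"GO:{i:07d}")
        synonyms = [f"alias {i}"] if rng.random() < 0.4 else []
        terms[tid] = OntologyTerm(
            id=tid, name=f"random process {i:03d}",
            namespace="biological_process", synonyms=synonyms,
        )
        if i > 1:
            n_parents = 2 if (i > 2 and rng.random() < 0.3) else 1
            for parent in rng.sample(range(1, i), n_parents):
                edges.append(OntologyEdge(
                    tid, TermID(f"GO:{parent:07d}"),
                    "part_of" if rng.random() < 0.25 else "is_a",
                ))
    return OntologyGraph(terms, edges)


def brute_expansion(graph: OntologyGraph, term: str) -> set[str]:
    """Term plus descendants by exhaustive DFS from every candidate node."""
    parent_map: dict[str, set[str]] = {}
    for e in graph.edges:
        parent_map.setdefault(e.child, set()).add(e.parent)

    def reaches(start: str, target: str) -> bool:
        stack, seen = [start], set()
        while stack:
            node = stack.pop()
            if node == target:
                return True
            for p in parent_map.get(node, ()):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return False

    return {
        t for t, obj in graph.terms.items()
        if not obj.obsolete and reaches(t, term)
    }


def brute_mean_path(graph: OntologyGraph, term: str, root: str) -> float:
    """Mean length of all distinct directed paths term -> root, enumerated."""
    parent_map: dict[str, list[str]] = {}
    for e in sorted(graph.edges, key=lambda e: (e.child, e.parent)):
        parent_map.setdefault(e.child, []).append(e.parent)

    lengths: list[int] = []

    def walk(node: str, length: int) -> None:
        if node == root:
            lengths.append(length)
            return
        for p in parent_map.get(node, ()):
            walk(p, length + 1)

    walk(term, 0)
    return sum(lengths) / len(lengths)


def brute_suggest(graph: OntologyGraph, prefix: str) -> set[str]:
    """Term ids whose name or any synonym starts with the prefix."""
    folded = prefix.casefold()
    return {
        t for t, obj in graph.terms.items()
        if not obj.obsolete and any(
            s.casefold().startswith(folded) for s in [obj.name, *obj.synonyms]
        )
    }


def brute_gene_join(table, terms, taxa=None) -> set[str]:
    """Nested-loop join: db ids of genes annotated by any listed term."""
    out = set()
    for ann in table.annotations:
        for t in terms:
            if ann.term == t and (taxa is None or ann.taxon in taxa):
                out.add(ann.gene)
    return out


def naive_eval(expr, corpus: Corpus) -> set[int]:
    """Re-interpret the boolean tree independently on every citation."""
    return {c.pmid for c in corpus if _sat(expr, c)}


def _sat(expr, c: Citation) -> bool:
    if expr.kind == "AND":
        return all(_sat(child, c) for child in expr.children)
    if expr.kind == "OR":
        return any(_sat(child, c) for child in expr.children)
    a = expr.atom
    if a.tag is FieldTag.TIAB:
        return phrase_in(c.title, a.text) or phrase_in(c.abstract, a.text)
    if a.tag is FieldTag.MESH:
        return a.text.casefold() in {h.descriptor.casefold() for h in c.mesh}
    if a.tag is FieldTag.MAJR:
        return a.text.casefold() in {
            h.descriptor.casefold() for h in c.mesh if h.major
        }
    if a.tag is FieldTag.PDAT:
        lo, hi = a.date_range
        return lo <= c.pub_date <= hi
    return (
        phrase_in(c.title, a.text)
        or phrase_in(c.abstract, a.text)
        or any(phrase_in(h.descriptor, a.text) for h in c.mesh)
    )
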