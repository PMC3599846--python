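"""Synthetic test worlds with known answer keys, plus hand-written fixtures.

``generate_world`` builds a random ontology, an annotation table, a synonym
table and a planted citation corpus in which the set of records a correct
end-to-end run must retrieve is known by construction: every planted
relevant record carries a keyword of a gene annotated (directly or through a
descendant term) by the planted query's term, the query's MeSH headings and
an in-window date, while every distractor violates at least one of those
conditions.  The generator keeps its own independent bookkeeping (term,
edge, gene, annotation and record counts) so parsers can be checked against
it.

Hand-written fixtures encode the regulation-of-fatty-acid-metabolic-process
mini-ontology (two genes annotated directly, three reachable only through
descendants), a small lipid-metabolism ontology, and the published
per-query/per-tool result counts used by the evaluation module.
"""

from __future__ import annotations

import datetime as dt
import json
import random
from dataclasses import dataclass, field
from typing import Optional

from .annotations import TaxonID
from .evaluation import AgreementTable
from .ontology import TermID

# --- hand-written fixtures ---

FIG7_OBO = """\
format-version: 1.2
ontology: fig7-mini

[Term]
id: GO:0019217
name: regulation of fatty acid metabolic process
namespace: biological_process
synonym: "regulation of fatty acid metabolism" EXACT []

[Term]
id: GO:0045922
name: negative regulation of fatty acid metabolic process
namespace: biological_process
is_a: GO:0019217 ! regulation of fatty acid metabolic process

[Term]
id: GO:0045923
name: positive regulation of fatty acid metabolic process
namespace: biological_process
is_a: GO:0019217 ! regulation of fatty acid metabolic process

[Term]
id: GO:0042304
name: regulation of fatty acid biosynthetic process
namespace: biological_process
is_a: GO:0019217 ! regulation of fatty acid metabolic process

[Term]
id: GO:0045717
name: negative regulation of fatty acid biosynthetic process
namespace: biological_process
is_a: GO:0042304 ! regulation of fatty acid biosynthetic process
is_a: GO:0045922 ! negative regulation of fatty acid metabolic process
"""

_FIG7_GAF_ROWS = [
    # (id, symbol, term, name, synonyms)
    ("P37231", "PPAR", "GO:0019217",
     "peroxisome proliferator activated receptor", "PPARG|NR1C3"),
    ("Q03135", "CAV1", "GO:0019217", "caveolin 1", "CAV"),
    ("P38398", "BRCA1", "GO:0045922", "breast cancer 1", "RNF53"),
    ("Q9NP71", "ChREBP", "GO:0045923",
     "carbohydrate response element binding protein", "MLXIPL|WBSCR14"),
    ("P02647", "APOA1", "GO:0042304", "apolipoprotein A-I", "apoA-I"),
]


def fig7_fixture() -> tuple[str, str]:
    """Mini ontology + GAF: 2 genes annotated directly, 3 via descendants."""
    lines = ["!gaf-version: 2.1"]
    for gid, symbol, term, name, syns in _FIG7_GAF_ROWS:
        cols = ["UniProtKB", gid, symbol, "", term, "GO_REF:0000001", "IDA",
                "", "P", name, syns, "protein", "taxon:9606", "20110301",
                "UniProt", "", ""]
        lines.append("\t".join(cols))
    return FIG7_OBO, "\n".join(lines) + "\n"


LIPID_OBO = """\
format-version: 1.2
ontology: lipid-mini

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0008152
name: metabolic process
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0006629
name: lipid metabolic process
namespace: biological_process
is_a: GO:0008152 ! metabolic process

[Term]
id: GO:0008610
name: lipid biosynthetic process
namespace: biological_process
synonym: "lipogenesis" EXACT []
is_a: GO:0006629 ! lipid metabolic process

[Term]
id: GO:0006869
name: lipid transport
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0060191
name: regulation of lipase activity
namespace: biological_process
is_a: GO:0008150 ! biological_process
"""


def lipid_fixture() -> str:
    """Small ontology naming the three lipid-metabolism query terms."""
    return LIPID_OBO


@dataclass(frozen=True)
class PaperCounts:
    """Published per-query, per-tool result counts and the judgment table.

    ``counts[query][tool]`` is ``(returned, relevant_returned)``; ``pools``
    holds the relevant-pool size of each query; ``agreement`` the reviewers'
    2x2 table over all pooled judgments.
    """

    counts: dict[str, dict[str, tuple[int, int]]]
    pools: dict[str, int]
    agreement: AgreementTable


TOOLS = ("PubMed", "GoPM (std)", "GoPM (exp)", "GO2PUB")


def paper_counts_fixture() -> PaperCounts:
    counts = {
        "Q1": {"PubMed": (19, 8), "GoPM (std)": (16, 5),
               "GoPM (exp)": (16, 5), "GO2PUB": (24, 13)},
        "Q2": {"PubMed": (45, 2), "GoPM (std)": (9, 6),
               "GoPM (exp)": (9, 6), "GO2PUB": (16, 10)},
        "Q3": {"PubMed": (23, 2), "GoPM (std)": (6, 5),
               "GoPM (exp)": (8, 6), "GO2PUB": (24, 6)},
    }
    pools = {"Q1": 16, "Q2": 15, "Q3": 11}
    return PaperCounts(counts=counts, pools=pools,
                       agreement=AgreementTable(35, 3, 4, 113))


# --- random world generator ---

@dataclass
class GeneratorConfig:
    seed: int = 0
    # ontology shape
    term_count: int = 40
    max_depth: int = 6
    part_of_fraction: float = 0.2
    multi_parent_fraction: float = 0.15
    # annotations
    genes_per_species: int = 12
    extra_annotation_prob: float = 0.5
    max_synonyms_per_gene: int = 2
    # corpus
    n_planted_queries: int = 2
    relevant_per_query: int = 6
    distractors: int = 16
    window: tuple[dt.date, dt.date] = (dt.date(2006, 3, 28), dt.date(2011, 3, 28))
    species: tuple[tuple[int, str], ...] = ((10090, "Mice"), (9606, "Humans"))
    case_jumble: bool = False

    def __post_init__(self) -> None:
        if self.term_count < 3 or self.max_depth < 2:
            raise ValueError("need at least 3 terms and depth 2 to plant descendants")
        for frac in (self.part_of_fraction, self.multi_parent_fraction,
                     self.extra_annotation_prob):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class PlantedQuery:
    term: TermID
    taxon: TaxonID
    keyword: str
    is_major: bool
    window: tuple[dt.date, dt.date]
    pmids: set[int]


@dataclass
class AnswerKey:
    term_count: int
    edge_count: int
    gene_count: int
    annotation_count: int
    record_count: int
    planted: list[PlantedQuery] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "term_count": self.term_count,
            "edge_count": self.edge_count,
            "gene_count": self.gene_count,
            "annotation_count": self.annotation_count,
            "record_count": self.record_count,
            "planted": [
                {
                    "term": q.term, "taxon": int(q.taxon), "keyword": q.keyword,
                    "is_major": q.is_major,
                    "window": [q.window[0].isoformat(), q.window[1].isoformat()],
                    "pmids": sorted(q.pmids),
                }
                for q in self.planted
            ],
        }, indent=2)


@dataclass
class World:
    obo: str
    gaf: str
    synonyms: str
    corpus_jsonl: str
    key: AnswerKey


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def generate_world(config: GeneratorConfig) -> World:
    """Generate a deterministic synthetic world; see the module docstring."""
    rng = random.Random(config.seed)

    # ontology: term 1 is the namespace root; each later term attaches to an
    # earlier one, which guarantees acyclicity
    depth = {1: 0}
    parents: dict[int, list[tuple[int, str]]] = {1: []}
    children: dict[int, list[int]] = {i: [] for i in range(1, config.term_count + 1)}
    edge_count = 0
    for i in range(2, config.term_count + 1):
        eligible = [t for t in range(1, i) if depth[t] < config.max_depth - 1]
        first = rng.choice(eligible)
        rel = "part_of" if rng.random() < config.part_of_fraction else "is_a"
        parents[i] = [(first, rel)]
        children[first].append(i)
        depth[i] = depth[first] + 1
        edge_count += 1
        others = [t for t in range(1, i) if t != first]
        if others and rng.random() < config.multi_parent_fraction:
            second = rng.choice(others)
            rel2 = "part_of" if rng.random() < config.part_of_fraction else "is_a"
            parents[i].append((second, rel2))
            children[second].append(i)
            edge_count += 1

    has_synonym = {i: rng.random() < 0.3 for i in range(1, config.term_count + 1)}
    obo_lines = ["format-version: 1.2", "ontology: synthetic-world", ""]
    for i in range(1, config.term_count + 1):
        obo_lines += [f"[Term]", f"id: {_term_id(i)}",
                      f"name: synthetic process {i:03d}",
                      "namespace: biological_process"]
        if has_synonym[i]:
            obo_lines.append(f'synonym: "sp{i} alias" EXACT []')
        for parent, rel in parents[i]:
            if rel == "is_a":
                obo_lines.append(f"is_a: {_term_id(parent)}")
            else:
                obo_lines.append(f"relationship: part_of {_term_id(parent)}")
        obo_lines.append("")
    obo_text = "\n".join(obo_lines)

    def descendants(term: int) -> set[int]:
        out, stack = set(), [term]
        while stack:
            node = stack.pop()
            for child in children[node]:
                if child not in out:
                    out.add(child)
                    stack.append(child)
        return out

    # annotations
    gaf_rows: list[tuple[str, str, int, str, list[str], int]] = []
    # (db_id, symbol, term, name, synonyms, taxon)
    gene_serial = 0
    genes_by_taxon: dict[int, list[tuple[str, str, str, list[str]]]] = {}
    annotation_count = 0
    for si, (taxon, _descriptor) in enumerate(config.species, start=1):
        pool = []
        for j in range(config.genes_per_species):
            gene_serial += 1
            symbol = f"G{si}X{j:02d}"
            name = f"gene {si} {j} protein"
            synonyms = [f"{symbol}L{k}" for k in range(rng.randint(0, config.max_synonyms_per_gene))]
            db_id = f"SYN{gene_serial:05d}"
            terms = [rng.randint(1, config.term_count)]
            if rng.random() < config.extra_annotation_prob:
                terms.append(rng.randint(1, config.term_count))
            for t in terms:
                gaf_rows.append((db_id, symbol, t, name, synonyms, taxon))
                annotation_count += 1
            pool.append((db_id, symbol, name, synonyms))
        genes_by_taxon[taxon] = pool

    # planted queries: a term with at least one descendant, one gene forced
    # onto the term itself and one onto a strict descendant
    planted: list[PlantedQuery] = []
    plantable = [t for t in range(1, config.term_count + 1)
                 if descendants(t) and depth[t] >= 1]
    if len(plantable) < config.n_planted_queries:
        raise ValueError(
            f"only {len(plantable)} plantable term(s) for "
            f"{config.n_planted_queries} queries; enlarge the ontology"
        )
    query_records: list[dict] = []
    pmid = 100000
    for q in range(config.n_planted_queries):
        term = rng.choice(plantable)
        plantable.remove(term)
        taxon, descriptor = config.species[q % len(config.species)]
        desc_term = rng.choice(sorted(descendants(term)))
        gene_serial += 1
        direct_gene = (f"SYN{gene_serial:05d}", f"Q{q + 1}DIR",
                       f"query {q + 1} direct protein", [])
        gene_serial += 1
        desc_gene = (f"SYN{gene_serial:05d}", f"Q{q + 1}DESC",
                     f"query {q + 1} descendant protein", [])
        gaf_rows.append((direct_gene[0], direct_gene[1], term,
                         direct_gene[2], direct_gene[3], taxon))
        gaf_rows.append((desc_gene[0], desc_gene[1], desc_term,
                         desc_gene[2], desc_gene[3], taxon))
        annotation_count += 2
        genes_by_taxon[taxon].extend([
            (direct_gene[0], direct_gene[1], direct_gene[2], direct_gene[3]),
            (desc_gene[0], desc_gene[1], desc_gene[2], desc_gene[3]),
        ])

        # pool of (symbol-or-name-or-synonym) keywords of genes annotated by
        # the expansion, for this taxon
        expansion = {term} | descendants(term)
        pool_keywords: list[tuple[str, str]] = []  # (db_id, keyword)
        for db_id, symbol, t, name, synonyms, tax in gaf_rows:
            if tax == taxon and t in expansion:
                for kw in [symbol, name, *synonyms]:
                    pool_keywords.append((db_id, kw))

        topic = f"Topic Q{q + 1}"
        is_major = q % 2 == 0
        start, end = config.window
        span_days = (end - start).days
        pmids: set[int] = set()
        for r in range(config.relevant_per_query):
            pmid += 1
            if r == 0:
                kw = desc_gene[1]  # reachable only through the descendant term
            else:
                kw = rng.choice(pool_keywords)[1]
            shown = kw
            if config.case_jumble and rng.random() < 0.5:
                shown = kw.swapcase()
            date = start + dt.timedelta(days=rng.randint(0, span_days))
            query_records.append({
                "pmid": pmid,
                "title": f"Planted study {pmid}",
                "abstract": f"We investigated {shown} in a planted context.",
                "authors": [f"Author {pmid % 7}"],
                "journal": "Journal of Synthetic Results",
                "pub_date": date.isoformat(),
                "mesh": [
                    {"descriptor": descriptor, "major": False},
                    {"descriptor": topic, "major": is_major},
                ],
            })
            pmids.add(pmid)
        # distractors: each violates exactly one retrieval condition
        other_taxon = [t for t, _ in config.species if t != taxon]
        for d in range(config.distractors):
            pmid += 1
            kind = d % 4
            kw = rng.choice(pool_keywords)[1]
            date = start + dt.timedelta(days=rng.randint(0, span_days))
            mesh = [{"descriptor": descriptor, "major": False},
                    {"descriptor": topic, "major": is_major}]
            abstract = f"We investigated {kw} in a planted context."
            if kind == 0:  # no gene keyword
                abstract = "Nothing of note was observed in this unrelated report."
            elif kind == 1:  # missing topic heading
                mesh = [{"descriptor": descriptor, "major": False}]
            elif kind == 2:  # out-of-window date
                date = start - dt.timedelta(days=rng.randint(30, 400))
            else:  # keyword from a gene of another species
                if other_taxon:
                    other_pool = genes_by_taxon[other_taxon[0]]
                    abstract = (f"We investigated {rng.choice(other_pool)[1]} "
                                "in a planted context.")
                else:
                    abstract = "Nothing of note was observed in this unrelated report."
            query_records.append({
                "pmid": pmid,
                "title": f"Distractor study {pmid}",
                "abstract": abstract,
                "authors": [f"Author {pmid % 7}"],
                "journal": "Journal of Synthetic Results",
                "pub_date": date.isoformat(),
                "mesh": mesh,
            })
        planted.append(PlantedQuery(
            term=TermID(_term_id(term)), taxon=TaxonID(taxon), keyword=topic,
            is_major=is_major, window=config.window, pmids=pmids,
        ))

    gaf_lines = ["!gaf-version: 2.1"]
    for db_id, symbol, t, name, synonyms, taxon in gaf_rows:
        cols = ["SYNDB", db_id, symbol, "", _term_id(t), "REF:1", "IEA", "",
                "P", name, "|".join(synonyms), "protein", f"taxon:{taxon}",
                "20110301", "SYNDB", "", ""]
        gaf_lines.append("\t".join(cols))
    gaf_text = "\n".join(gaf_lines) + "\n"

    syn_lines = ["# taxon\tsymbol\textra synonyms"]
    for taxon, pool in sorted(genes_by_taxon.items()):
        for db_id, symbol, name, synonyms in pool:
            if rng.random() < 0.4:
                syn_lines.append(f"{taxon}\t{symbol}\t{symbol}EX")
    syn_text = "\n".join(syn_lines) + "\n"

    corpus_jsonl = "\n".join(json.dumps(rec) for rec in query_records) + "\n"

    gene_count = len({row[0] for row in gaf_rows})
    key = AnswerKey(
        term_count=config.term_count,
        edge_count=edge_count,
        gene_count=gene_count,
        annotation_count=annotation_count,
        record_count=len(query_records),
        planted=planted,
    )
    return World(obo=obo_text, gaf=gaf_text, synonyms=syn_text,
                 corpus_jsonl=corpus_jsonl, key=key)


def run_planted_query(world: World, query: PlantedQuery,
                      variant: Optional[str] = None) -> set[int]:
    """Execute one planted query end to end and return the retrieved pmids.

    Convenience wrapper chaining parse, expansion, gene lookup, composition
    and local evaluation — the path the answer key certifies.
    """
    from . import annotations as ann
    from . import ontology as onto
    from . import query_builder as qb
    from . import retrieval as ret

    graph = onto.parse_obo(world.obo)
    table = ann.parse_gaf(world.gaf)
    terms = onto.expansion_set(graph, query.term)
    genes = ann.genes_for_terms(table, terms, taxa={query.taxon})
    spec = qb.QuerySpec(
        go_terms=[query.term], species=[query.taxon],
        keywords=[(query.keyword, query.is_major)],
        year_window=query.window,
    )
    composed = qb.compose(
        spec, genes,
        qb.QueryVariant(variant) if variant else qb.QueryVariant.BASICq,
        today=query.window[1],
    )
    corpus = ret.load_corpus(world.corpus_jsonl, "jsonl")
    return ret.evaluate_query(composed.expr, corpus)
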