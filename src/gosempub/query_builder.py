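"""Boolean query composition in the PubMed field-tag dialect.

The enriched query follows the model ``(n gene names, symbols or synonyms
separated by OR) AND (m species) AND (p MeSH terms)``, optionally restricted
by a publication-date window and a free-text clause.  Four systematic
variants rewrite the field tags and connectors:

``BASICq``
    keywords tagged MeSH or Major-Topic as flagged by the user, species
    tagged MeSH;
``MeSHq``
    Major-Topic qualifiers are ignored and every keyword is searched as a
    plain MeSH term (a MAJR heading is also a MeSH heading, so this variant
    can only widen the result set);
``ORq``
    keyword connectors become OR and, to curb the extra noise, every keyword
    and every species is tagged Major-Topic;
``NOKq``
    keywords are dropped altogether and species are tagged Major-Topic.

Queries whose serialized form exceeds a URL length budget are split into
contiguous blocks of gene atoms, each ANDed with the full fixed clause, so
the union of the chunks' results equals the unsplit query's results.
"""

from __future__ import annotations

import datetime as dt
import enum
import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

from .annotations import GeneProduct, SpeciesDirectory, TaxonID
from .errors import EmptyQueryError, UnsplittableQueryError
from .ontology import TermID


class FieldTag(enum.Enum):
    TIAB = "tiab"
    MESH = "mesh"
    MAJR = "majr"
    PDAT = "PDAT"
    FREE = "free"


class QueryVariant(enum.Enum):
    BASICq = "BASICq"
    MeSHq = "MeSHq"
    ORq = "ORq"
    NOKq = "NOKq"


@dataclass(frozen=True)
class QueryAtom:
    """A fielded phrase, or a closed date range for PDAT atoms."""

    text: str = ""
    tag: FieldTag = FieldTag.FREE
    date_range: Optional[tuple[dt.date, dt.date]] = None

    def __post_init__(self) -> None:
        if self.tag is FieldTag.PDAT:
            if self.date_range is None:
                raise ValueError("PDAT atom requires a date range")
        elif not self.text:
            raise ValueError("atom text must be non-empty")


@dataclass(frozen=True)
class BooleanExpr:
    kind: str  # "ATOM" | "AND" | "OR"
    children: tuple["BooleanExpr", ...] = ()
    atom: Optional[QueryAtom] = None

    def __post_init__(self) -> None:
        if self.kind == "ATOM":
            if self.atom is None or self.children:
                raise ValueError("ATOM node carries an atom and no children")
        elif self.kind in ("AND", "OR"):
            if len(self.children) < 2:
                raise ValueError(f"{self.kind} node needs >= 2 children")
        else:
            raise ValueError(f"bad node kind {self.kind!r}")


def atom(text: str, tag: FieldTag) -> BooleanExpr:
    return BooleanExpr("ATOM", atom=QueryAtom(text=text, tag=tag))


def pdat(start: dt.date, end: dt.date) -> BooleanExpr:
    return BooleanExpr("ATOM", atom=QueryAtom(tag=FieldTag.PDAT, date_range=(start, end)))


def conj(kind: str, children: Sequence[BooleanExpr]) -> BooleanExpr:
    """AND/OR over children, collapsing the single-child case."""
    children = tuple(children)
    if len(children) == 1:
        return children[0]
    return BooleanExpr(kind, children=children)


@dataclass
class QuerySpec:
    """User-side query parameters: terms, species, keywords and options."""

    go_terms: list[TermID]
    species: list[TaxonID]
    keywords: list[tuple[str, bool]] = field(default_factory=list)  # (text, is_major)
    species_connector: str = "OR"
    keyword_connector: str = "AND"
    free_text: str = ""
    year_window: Union[int, tuple[dt.date, dt.date], None] = None
    exhaustive_synonyms: bool = False

    def __post_init__(self) -> None:
        if not self.go_terms:
            raise ValueError("at least one GO term is required")
        if not self.species:
            raise ValueError("at least one species is required")
        if self.species_connector not in ("AND", "OR"):
            raise ValueError("species connector must be AND or OR")
        if self.keyword_connector not in ("AND", "OR"):
            raise ValueError("keyword connector must be AND or OR")


@dataclass
class ComposedQuery:
    variant: QueryVariant
    expr: BooleanExpr
    chunks: list[str]
    #: ordered gene atoms (the OR-clause) — needed to re-partition on split
    gene_atoms: list[BooleanExpr] = field(default_factory=list)
    #: the fixed, non-gene children of the top-level AND
    fixed: list[BooleanExpr] = field(default_factory=list)
    #: expression of each chunk, parallel to ``chunks``
    chunk_exprs: list[BooleanExpr] = field(default_factory=list)


def gene_keywords(genes: set[GeneProduct]) -> list[str]:
    """Deduplicated (case-folded) keyword pool over all genes, stable order."""
    out: list[str] = []
    seen: set[str] = set()
    for gene in sorted(genes, key=lambda g: (g.symbol.casefold(), g.db_object_id)):
        for kw in gene.keyword_pool():
            key = kw.casefold()
            if key not in seen:
                seen.add(key)
                out.append(kw)
    return out


def _date_window(
    window: Union[int, tuple[dt.date, dt.date]], today: dt.date
) -> tuple[dt.date, dt.date]:
    if isinstance(window, int):
        try:
            start = today.replace(year=today.year - window)
        except ValueError:  # Feb 29 on a non-leap year
            start = today.replace(year=today.year - window, day=28)
        return (start, today)
    return window


def compose(
    spec: QuerySpec,
    genes: set[GeneProduct],
    variant: QueryVariant = QueryVariant.BASICq,
    today: Optional[dt.date] = None,
    directory: Optional[SpeciesDirectory] = None,
) -> ComposedQuery:
    """Compose the enriched boolean query for one variant.

    ``today`` anchors relative year windows and must be passed explicitly
    when a window is given (no hidden clock).
    """
    if not genes:
        raise EmptyQueryError("no gene keywords: the composed query would be empty")
    directory = directory or SpeciesDirectory.default()

    kws = gene_keywords(genes)
    gene_atoms = [atom(kw, FieldTag.TIAB) for kw in kws]
    gene_clause = conj("OR", gene_atoms)

    species_tag = (
        FieldTag.MAJR
        if variant in (QueryVariant.ORq, QueryVariant.NOKq)
        else FieldTag.MESH
    )
    species_atoms = [
        atom(directory.mesh_descriptor(t), species_tag) for t in spec.species
    ]
    fixed: list[BooleanExpr] = []
    if spec.species_connector == "OR":
        fixed.append(conj("OR", species_atoms))
    else:
        fixed.extend(species_atoms)

    if variant is not QueryVariant.NOKq and spec.keywords:
        if variant is QueryVariant.BASICq:
            kw_atoms = [
                atom(text, FieldTag.MAJR if major else FieldTag.MESH)
                for text, major in spec.keywords
            ]
            connector = spec.keyword_connector
        elif variant is QueryVariant.MeSHq:
            kw_atoms = [atom(text, FieldTag.MESH) for text, _ in spec.keywords]
            connector = spec.keyword_connector
        else:  # ORq
            kw_atoms = [atom(text, FieldTag.MAJR) for text, _ in spec.keywords]
            connector = "OR"
        if connector == "OR":
            fixed.append(conj("OR", kw_atoms))
        else:
            fixed.extend(kw_atoms)

    if spec.year_window is not None:
        if today is None:
            raise ValueError("a year window requires an explicit 'today'")
        start, end = _date_window(spec.year_window, today)
        fixed.append(pdat(start, end))
    if spec.free_text:
        fixed.append(atom(spec.free_text, FieldTag.FREE))

    expr = conj("AND", [gene_clause, *fixed])
    return ComposedQuery(
        variant=variant,
        expr=expr,
        chunks=[serialize(expr)],
        gene_atoms=gene_atoms,
        fixed=fixed,
        chunk_exprs=[expr],
    )


def serialize(expr: BooleanExpr) -> str:
    """Deterministic infix rendering in the PubMed field-tag dialect.

    Children are parenthesized whenever their operator differs from the
    parent's; date ranges always carry their own parentheses.
    """
    return _render(expr, parent_kind=None)


def _render(expr: BooleanExpr, parent_kind: Optional[str]) -> str:
    if expr.kind == "ATOM":
        a = expr.atom
        if a.tag is FieldTag.PDAT:
            start, end = a.date_range
            return (
                f'("{start:%Y/%m/%d}"[PDAT] : "{end:%Y/%m/%d}"[PDAT])'
            )
        if a.tag is FieldTag.FREE:
            return a.text
        return f'"{a.text}"[{a.tag.value}]'
    inner = f" {expr.kind} ".join(_render(c, expr.kind) for c in expr.children)
    if parent_kind is not None and parent_kind != expr.kind:
        return f"({inner})"
    return inner


def split_query(query: ComposedQuery, max_len: int = 2000) -> ComposedQuery:
    """Split the gene OR-clause into the fewest contiguous blocks.

    Greedy in gene order: each chunk is ``(gene block) AND (full fixed
    clause)`` and serializes to at most ``max_len`` characters.  If the
    unsplit query already fits, a single chunk is returned.
    """
    if len(query.chunks) == 1 and len(query.chunks[0]) <= max_len:
        return replace(query, chunks=list(query.chunks), chunk_exprs=list(query.chunk_exprs))

    atoms = query.gene_atoms
    chunks: list[str] = []
    chunk_exprs: list[BooleanExpr] = []
    i = 0
    while i < len(atoms):
        j = i + 1
        best = None
        while j <= len(atoms):
            candidate_expr = conj("AND", [conj("OR", atoms[i:j]), *query.fixed])
            s = serialize(candidate_expr)
            if len(s) > max_len:
                break
            best = (s, candidate_expr)
            j += 1
        if best is None:
            kw = atoms[i].atom.text
            raise UnsplittableQueryError(
                f"gene keyword {kw!r} plus the fixed clause exceeds max_len={max_len}"
            )
        chunks.append(best[0])
        chunk_exprs.append(best[1])
        i = j - 1
    return replace(query, chunks=chunks, chunk_exprs=chunk_exprs)


# --- parser for the serialized dialect (used for round-trip validation) ---

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<lpar>\() |
        (?P<rpar>\)) |
        (?P<colon>:) |
        (?P<tagged>"(?P<qtext>[^"]*)"\[(?P<tag>[A-Za-z]+)\]) |
        (?P<word>[^\s()]+)
    )""",
    re.VERBOSE,
)


def _tokenize(s: str) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if not m or m.end() == pos:
            raise ValueError(f"cannot tokenize at position {pos}: {s[pos:pos+20]!r}")
        pos = m.end()
        if m.group("lpar"):
            tokens.append(("LPAR", "("))
        elif m.group("rpar"):
            tokens.append(("RPAR", ")"))
        elif m.group("colon"):
            tokens.append(("COLON", ":"))
        elif m.group("tagged"):
            tokens.append(("TAGGED", m.group("qtext") + "\x00" + m.group("tag")))
        else:
            word = m.group("word")
            if word in ("AND", "OR"):
                tokens.append(("CONN", word))
            else:
                tokens.append(("WORD", word))
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> Optional[tuple[str, str]]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse_expr(self) -> BooleanExpr:
        children = [self.parse_term()]
        kind = None
        while self.peek() and self.peek()[0] == "CONN":
            conn = self.next()[1]
            if kind is None:
                kind = conn
            elif conn != kind:
                raise ValueError("mixed AND/OR at one nesting level")
            children.append(self.parse_term())
        return conj(kind or "AND", children)

    def parse_term(self) -> BooleanExpr:
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of query")
        if tok[0] == "LPAR":
            # lookahead: PDAT range or parenthesized sub-expression
            if (
                self.i + 1 < len(self.tokens)
                and self.tokens[self.i + 1][0] == "TAGGED"
                and self.tokens[self.i + 1][1].endswith("\x00PDAT")
            ):
                return self.parse_pdat()
            self.next()
            inner = self.parse_expr()
            if self.peek() is None or self.next()[0] != "RPAR":
                raise ValueError("missing closing parenthesis")
            return inner
        if tok[0] == "TAGGED":
            text, tag = self.next()[1].split("\x00")
            return atom(text, FieldTag(tag.lower()))
        if tok[0] == "WORD":
            words = []
            while self.peek() and self.peek()[0] == "WORD":
                words.append(self.next()[1])
            return atom(" ".join(words), FieldTag.FREE)
        raise ValueError(f"unexpected token {tok}")

    def parse_pdat(self) -> BooleanExpr:
        self.next()  # (
        start = self._pdat_date()
        if self.next()[0] != "COLON":
            raise ValueError("PDAT range missing ':'")
        end = self._pdat_date()
        if self.next()[0] != "RPAR":
            raise ValueError("PDAT range missing ')'")
        return pdat(start, end)

    def _pdat_date(self) -> dt.date:
        text, tag = self.next()[1].split("\x00")
        if tag != "PDAT":
            raise ValueError("expected a PDAT atom")
        return dt.datetime.strptime(text, "%Y/%m/%d").date()


def parse_query(s: str) -> BooleanExpr:
    """Parse a serialized query string back into a boolean tree."""
    parser = _Parser(_tokenize(s))
    expr = parser.parse_expr()
    if parser.peek() is not None:
        raise ValueError(f"trailing tokens from position {parser.i}")
    return expr
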