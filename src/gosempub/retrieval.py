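"""Local fielded retrieval over a MEDLINE-like citation corpus.

This engine gives the query dialect concrete offline semantics: TIAB atoms
are case-insensitive exact phrase matches on word boundaries in title or
abstract, MeSH/MAJR atoms compare whole descriptor strings, PDAT atoms test
the publication date against a closed range, and AND/OR combine result sets
by intersection/union.  No stemming, no MeSH-tree explosion, no relevance
ranking — matching is deliberately strict so gene symbols never partial-match.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from lxml import etree

from .errors import CorpusLoadError
from .query_builder import BooleanExpr, FieldTag

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MeshHeading:
    descriptor: str
    major: bool = False

    def __post_init__(self) -> None:
        if not self.descriptor:
            raise ValueError("MeSH descriptor must be non-empty")


@dataclass
class Citation:
    pmid: int
    title: str
    abstract: str = ""
    authors: list[str] = field(default_factory=list)
    journal: str = ""
    pub_date: dt.date = dt.date(1900, 1, 1)
    mesh: list[MeshHeading] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pmid <= 0:
            raise ValueError("pmid must be positive")


@dataclass
class Corpus:
    citations: dict[int, Citation] = field(default_factory=dict)

    def add(self, citation: Citation) -> None:
        if citation.pmid in self.citations:
            raise CorpusLoadError(f"duplicate PMID {citation.pmid}")
        self.citations[citation.pmid] = citation

    def __len__(self) -> int:
        return len(self.citations)

    def __iter__(self):
        return iter(self.citations.values())


_MONTHS = {m: i for i, m in enumerate(
    ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
     "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"], start=1)}


def load_corpus(stream, dialect: str = "jsonl") -> Corpus:
    """Load citations from MEDLINE-style XML or a JSON-lines dialect.

    ``jsonl``: one object per line with keys pmid, title, abstract, authors,
    journal, pub_date (ISO-8601) and mesh ([{descriptor, major}]).
    ``medline-xml``: a PubmedArticleSet subset.  Records missing a PMID,
    title or date are skipped with a warning; duplicate PMIDs abort the load.
    """
    text = stream if isinstance(stream, str) else stream.read()
    if dialect == "jsonl":
        return _load_jsonl(text)
    if dialect == "medline-xml":
        return _load_medline_xml(text)
    raise ValueError(f"unknown corpus dialect {dialect!r}")


def _load_jsonl(text: str) -> Corpus:
    corpus = Corpus()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        obj = json.loads(line)
        try:
            citation = Citation(
                pmid=int(obj["pmid"]),
                title=obj["title"],
                abstract=obj.get("abstract", ""),
                authors=list(obj.get("authors", [])),
                journal=obj.get("journal", ""),
                pub_date=dt.date.fromisoformat(obj["pub_date"]),
                mesh=[MeshHeading(h["descriptor"], bool(h.get("major", False)))
                      for h in obj.get("mesh", [])],
            )
        except (KeyError, ValueError) as exc:
            logger.warning("jsonl line %d skipped: %s", lineno, exc)
            continue
        corpus.add(citation)
    return corpus


def _load_medline_xml(text: str) -> Corpus:
    corpus = Corpus()
    root = etree.fromstring(text.encode())
    for article in root.iter("PubmedArticle"):
        cit = article.find("MedlineCitation")
        if cit is None:
            continue
        pmid_el = cit.find("PMID")
        art = cit.find("Article")
        title_el = art.find("ArticleTitle") if art is not None else None
        if pmid_el is None or title_el is None or not (title_el.text or "").strip():
            logger.warning("XML record missing PMID or title; skipped")
            continue
        date = _parse_pubdate(art)
        if date is None:
            logger.warning("XML record %s missing publication date; skipped",
                           pmid_el.text)
            continue
        abstract = " ".join(
            (el.text or "") for el in art.findall("Abstract/AbstractText")
        ).strip()
        authors = []
        for author in art.findall("AuthorList/Author"):
            last = author.findtext("LastName", "")
            initials = author.findtext("Initials", "")
            if last:
                authors.append(f"{last} {initials}".strip())
        mesh = []
        for heading in cit.findall("MeshHeadingList/MeshHeading"):
            descriptor = heading.find("DescriptorName")
            if descriptor is not None and (descriptor.text or "").strip():
                mesh.append(MeshHeading(
                    descriptor.text.strip(),
                    descriptor.get("MajorTopicYN", "N") == "Y",
                ))
        corpus.add(Citation(
            pmid=int(pmid_el.text),
            title=title_el.text.strip(),
            abstract=abstract,
            authors=authors,
            journal=art.findtext("Journal/Title", "").strip(),
            pub_date=date,
            mesh=mesh,
        ))
    return corpus


def _parse_pubdate(art) -> Optional[dt.date]:
    node = art.find("Journal/JournalIssue/PubDate") if art is not None else None
    if node is None:
        return None
    year = node.findtext("Year")
    if year is None:
        return None
    month = node.findtext("Month", "Jan")
    month_num = _MONTHS.get(month) or (int(month) if month.isdigit() else 1)
    day = int(node.findtext("Day", "1"))
    return dt.date(int(year), month_num, day)


# --- phrase matching ---

def _normalize(text: str) -> str:
    """Case-fold and collapse hyphen/en-dash and whitespace runs to a space."""
    return re.sub(r"[\s‐–-]+", " ", text.casefold())


def _phrase_pattern(phrase: str) -> re.Pattern:
    words = _normalize(phrase).strip().split(" ")
    body = r"\s+".join(re.escape(w) for w in words)
    return re.compile(rf"(?<!\w){body}(?!\w)")


def phrase_in(text: str, phrase: str) -> bool:
    """Word-boundary exact phrase containment after normalization."""
    return bool(_phrase_pattern(phrase).search(_normalize(text)))


def _matches_atom(citation: Citation, expr: BooleanExpr) -> bool:
    a = expr.atom
    if a.tag is FieldTag.TIAB:
        return phrase_in(citation.title, a.text) or phrase_in(citation.abstract, a.text)
    if a.tag is FieldTag.MESH:
        return any(h.descriptor.casefold() == a.text.casefold() for h in citation.mesh)
    if a.tag is FieldTag.MAJR:
        return any(
            h.major and h.descriptor.casefold() == a.text.casefold()
            for h in citation.mesh
        )
    if a.tag is FieldTag.PDAT:
        start, end = a.date_range
        return start <= citation.pub_date <= end
    # FREE: phrase match over title, abstract, or any mesh descriptor
    return (
        phrase_in(citation.title, a.text)
        or phrase_in(citation.abstract, a.text)
        or any(phrase_in(h.descriptor, a.text) for h in citation.mesh)
    )


def evaluate_query(expr: BooleanExpr, corpus: Corpus) -> set[int]:
    """Evaluate a boolean tree to the set of matching PMIDs.

    AND nodes intersect their children's result sets; OR nodes union them.
    """
    if expr.kind == "ATOM":
        return {c.pmid for c in corpus if _matches_atom(c, expr)}
    sets = [evaluate_query(child, corpus) for child in expr.children]
    if expr.kind == "AND":
        out = sets[0]
        for s in sets[1:]:
            out = out & s
        return out
    return set().union(*sets)


def matches_citation(expr: BooleanExpr, citation: Citation) -> bool:
    """Per-record interpreter: does one citation satisfy the tree?

    Logically equivalent to membership in :func:`evaluate_query`'s result;
    kept separate so the two routes can cross-check each other.
    """
    if expr.kind == "ATOM":
        return _matches_atom(citation, expr)
    if expr.kind == "AND":
        return all(matches_citation(c, citation) for c in expr.children)
    return any(matches_citation(c, citation) for c in expr.children)


# --- result compilation ---

@dataclass(frozen=True)
class Match:
    keyword: str
    field: str  # "title" | "abstract"
    span: tuple[int, int]  # 0-based half-open character offsets


@dataclass
class ResultEntry:
    rank: int
    citation: Citation
    matched_keywords: list[Match]


@dataclass
class ResultSet:
    entries: list[ResultEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def to_json(self) -> str:
        return json.dumps([
            {
                "rank": e.rank,
                "pmid": e.citation.pmid,
                "date": e.citation.pub_date.isoformat(),
                "title": e.citation.title,
                "matches": [
                    {"keyword": m.keyword, "field": m.field, "span": list(m.span)}
                    for m in e.matched_keywords
                ],
            }
            for e in self.entries
        ], indent=2)


def highlight_matches(citation: Citation, gene_keywords: list[str]) -> list[Match]:
    """Non-overlapping keyword occurrences in title and abstract.

    Occurrences are case-insensitive on word boundaries; where keywords nest
    (``FAS`` inside ``fatty acid synthase``) the leftmost-longest match wins
    and shorter keywords are not flagged inside it.  Spans index the original
    field text.
    """
    out: list[Match] = []
    for fieldname in ("title", "abstract"):
        text = getattr(citation, fieldname)
        candidates: list[tuple[int, int, str]] = []
        for kw in gene_keywords:
            pattern = re.compile(
                rf"(?<!\w){re.escape(kw)}(?!\w)", re.IGNORECASE
            )
            for m in pattern.finditer(text):
                candidates.append((m.start(), m.end(), kw))
        # leftmost first; among equal starts, longest first
        candidates.sort(key=lambda c: (c[0], -(c[1] - c[0])))
        taken_until = -1
        for start, end, kw in candidates:
            if start > taken_until:
                out.append(Match(keyword=kw, field=fieldname, span=(start, end)))
                taken_until = end - 1
    return out


def compile_results(
    pmids: set[int], corpus: Corpus, gene_keywords: list[str]
) -> ResultSet:
    """Number and sort the retrieved citations, newest first.

    Ties on the publication date are broken by descending PMID so the
    ordering is total and reproducible.
    """
    missing = pmids - set(corpus.citations)
    if missing:
        raise KeyError(f"pmids not in corpus: {sorted(missing)}")
    ordered = sorted(
        (corpus.citations[p] for p in pmids),
        key=lambda c: (c.pub_date, c.pmid),
        reverse=True,
    )
    return ResultSet(entries=[
        ResultEntry(rank=i, citation=c,
                    matched_keywords=highlight_matches(c, gene_keywords))
        for i, c in enumerate(ordered, start=1)
    ])
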