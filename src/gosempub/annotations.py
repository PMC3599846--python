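"""Gene-product annotations: GAF parsing, term-to-gene lookup, species names.

A gene product carries a *keyword pool* — its symbol, full name and synonyms,
deduplicated case-insensitively — which becomes the OR-clause of the enriched
literature query.  Annotations link gene products to ontology terms; the
lookup accepts an expanded term set so that genes annotated to any descendant
of a term of interest are found.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from Bio.UniProt import GOA

from .errors import UnknownSpeciesError
from .ontology import OntologyGraph, TermID

logger = logging.getLogger(__name__)


class TaxonID(int):
    """An NCBI taxonomy identifier (positive integer)."""

    def __new__(cls, value) -> "TaxonID":
        iv = int(value)
        if iv <= 0:
            raise ValueError(f"taxon id must be positive, got {value!r}")
        return super().__new__(cls, iv)


@dataclass
class GeneProduct:
    db_object_id: str
    symbol: str
    name: str
    synonyms: list[str] = field(default_factory=list)
    taxon: TaxonID = TaxonID(9606)

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError(f"gene {self.db_object_id} has an empty symbol")

    def keyword_pool(self) -> list[str]:
        """Symbol, name and synonyms without case-folded duplicates."""
        pool: list[str] = []
        seen: set[str] = set()
        for kw in [self.symbol, self.name, *self.synonyms]:
            key = kw.casefold()
            if kw and key not in seen:
                seen.add(key)
                pool.append(kw)
        return pool

    def __hash__(self) -> int:
        return hash(self.db_object_id)


@dataclass(frozen=True)
class Annotation:
    gene: str  # db_object_id reference
    term: TermID
    evidence_code: str
    taxon: TaxonID


@dataclass
class AnnotationTable:
    genes: dict[str, GeneProduct] = field(default_factory=dict)
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ann in self.annotations:
            if ann.gene not in self.genes:
                raise ValueError(f"annotation references unknown gene {ann.gene}")


_TAXON_RE = re.compile(r"^taxon:(\d+)$")
_N_GAF_COLUMNS = 17


def parse_gaf(stream) -> AnnotationTable:
    """Parse GAF 2.x text into an :class:`AnnotationTable`.

    One gene product per distinct object id; annotations with a ``NOT``
    qualifier are dropped (they assert the gene does *not* have the
    function, which would poison the query).  Lines with a wrong column
    count or an unparseable taxon are skipped with a logged warning.
    """
    text = stream if isinstance(stream, str) else stream.read()
    clean_lines: list[str] = []
    skipped = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("!"):
            clean_lines.append(line)
            continue
        n = len(line.split("\t"))
        if n != _N_GAF_COLUMNS:
            logger.warning("GAF line %d: expected %d columns, got %d; skipped",
                           lineno, _N_GAF_COLUMNS, n)
            skipped += 1
            continue
        clean_lines.append(line)
    if not any(l.startswith("!gaf-version") for l in clean_lines):
        clean_lines.insert(0, "!gaf-version: 2.1")

    genes: dict[str, GeneProduct] = {}
    annotations: list[Annotation] = []
    for rec in GOA.gafiterator(io.StringIO("\n".join(clean_lines) + "\n")):
        if any(q.split("|")[0] == "NOT" or q == "NOT" for q in rec["Qualifier"]):
            continue
        m = _TAXON_RE.match(rec["Taxon_ID"][0]) if rec["Taxon_ID"] else None
        if not m:
            logger.warning("unparseable taxon %r for %s; line skipped",
                           rec["Taxon_ID"], rec["DB_Object_ID"])
            continue
        taxon = TaxonID(int(m.group(1)))
        gid = rec["DB_Object_ID"]
        synonyms = [s for s in rec["Synonym"] if s]
        if gid not in genes:
            genes[gid] = GeneProduct(
                db_object_id=gid,
                symbol=rec["DB_Object_Symbol"],
                name=rec["DB_Object_Name"],
                synonyms=synonyms,
                taxon=taxon,
            )
        else:
            _merge_synonyms(genes[gid], synonyms)
        annotations.append(
            Annotation(gene=gid, term=TermID(rec["GO_ID"]),
                       evidence_code=rec["Evidence"], taxon=taxon)
        )
    if skipped:
        logger.warning("skipped %d malformed GAF line(s)", skipped)
    return AnnotationTable(genes=genes, annotations=annotations)


def _merge_synonyms(gene: GeneProduct, extra: Iterable[str]) -> None:
    seen = {s.casefold() for s in gene.synonyms}
    seen.add(gene.symbol.casefold())
    seen.add(gene.name.casefold())
    for syn in extra:
        if syn and syn.casefold() not in seen:
            seen.add(syn.casefold())
            gene.synonyms.append(syn)


def genes_for_terms(
    table: AnnotationTable,
    terms: set[TermID],
    taxa: Optional[set[TaxonID]] = None,
    exclude_evidence: Optional[set[str]] = None,
) -> set[GeneProduct]:
    """Genes with at least one annotation to a term in ``terms``.

    ``terms`` is usually an expansion set.  ``taxa`` restricts to the listed
    species (``None`` means no restriction); ``exclude_evidence`` optionally
    drops annotations by evidence code (none are dropped by default).  An
    empty result is allowed but logged, because the composed query would be
    empty.
    """
    hits: dict[str, GeneProduct] = {}
    for ann in table.annotations:
        if ann.term not in terms:
            continue
        if taxa is not None and ann.taxon not in taxa:
            continue
        if exclude_evidence and ann.evidence_code in exclude_evidence:
            continue
        hits[ann.gene] = table.genes[ann.gene]
    if not hits and terms:
        logger.warning("no genes annotated by the %d given term(s); "
                       "the composed query would be empty", len(terms))
    return set(hits.values())


def augment_synonyms(genes: set[GeneProduct], synonym_table) -> set[GeneProduct]:
    """Merge extra synonyms from a gene_info-style TSV into the gene pool.

    Rows are ``taxon <tab> symbol <tab> pipe-separated synonyms``; matching
    is by (taxon, case-folded symbol).  Genes absent from the table pass
    through unchanged.  Returns new gene objects; inputs are not mutated.
    """
    text = synonym_table if isinstance(synonym_table, str) else synonym_table.read()
    extra: dict[tuple[int, str], list[str]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            logger.warning("synonym table line %d: fewer than 3 columns; skipped", lineno)
            continue
        try:
            taxon = int(parts[0])
        except ValueError:
            logger.warning("synonym table line %d: bad taxon %r; skipped", lineno, parts[0])
            continue
        extra.setdefault((taxon, parts[1].casefold()), []).extend(
            s for s in parts[2].split("|") if s and s != "-"
        )

    out: set[GeneProduct] = set()
    for gene in genes:
        fresh = GeneProduct(gene.db_object_id, gene.symbol, gene.name,
                            list(gene.synonyms), gene.taxon)
        _merge_synonyms(fresh, extra.get((int(gene.taxon), gene.symbol.casefold()), []))
        out.add(fresh)
    return out


@dataclass(frozen=True)
class SpeciesEntry:
    taxon: TaxonID
    scientific_name: str
    common_names: tuple[str, ...]
    mesh_descriptor: str


class SpeciesDirectory:
    """Maps species names and taxon codes to MeSH descriptors.

    The directory is data, not code: a small editable TSV with one species
    per row.  A default covering seven well-annotated model species ships
    with the package.
    """

    def __init__(self, entries: Iterable[SpeciesEntry]):
        self.entries = list(entries)
        seen = set()
        for e in self.entries:
            if e.taxon in seen:
                raise ValueError(f"duplicate taxon {e.taxon} in species directory")
            if not e.mesh_descriptor:
                raise ValueError(f"taxon {e.taxon} has no MeSH descriptor")
            seen.add(e.taxon)

    @classmethod
    def from_tsv(cls, stream) -> "SpeciesDirectory":
        text = stream if isinstance(stream, str) else stream.read()
        entries = []
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            taxon, scientific, common, mesh = line.rstrip("\n").split("\t")
            entries.append(SpeciesEntry(
                taxon=TaxonID(int(taxon)),
                scientific_name=scientific,
                common_names=tuple(c for c in common.split("|") if c),
                mesh_descriptor=mesh,
            ))
        return cls(entries)

    @classmethod
    def default(cls) -> "SpeciesDirectory":
        text = resources.files("gosempub").joinpath("data/species.tsv").read_text()
        return cls.from_tsv(text)

    def mesh_descriptor(self, taxon: TaxonID) -> str:
        for e in self.entries:
            if e.taxon == taxon:
                return e.mesh_descriptor
        raise UnknownSpeciesError(f"taxon {int(taxon)} not in species directory")


def resolve_species(directory: SpeciesDirectory, text: str) -> TaxonID:
    """Resolve a taxon code, scientific name or common name to a TaxonID."""
    needle = text.strip()
    if needle.isdigit():
        taxon = int(needle)
        for e in directory.entries:
            if e.taxon == taxon:
                return e.taxon
        raise UnknownSpeciesError(f"taxon code {taxon} not in species directory")
    folded = needle.casefold()
    hits = [
        e for e in directory.entries
        if e.scientific_name.casefold() == folded
        or any(c.casefold() == folded for c in e.common_names)
    ]
    if not hits:
        raise UnknownSpeciesError(f"no species matches {text!r}")
    if len(hits) > 1:
        names = ", ".join(e.scientific_name for e in hits)
        raise UnknownSpeciesError(f"{text!r} is ambiguous between: {names}")
    return hits[0].taxon
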