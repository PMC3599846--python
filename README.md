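# gosempub

Ontology-driven, gene-enriched boolean literature retrieval.

After a transcriptomics or other high-throughput gene analysis, the question
a scientist brings to the literature is usually phrased as a Gene Ontology
(GO) term — "lipid biosynthetic process" — not as a list of gene names. But
PubMed has no `[GO]` search field, so a query built from the term alone
misses the articles that discuss the *genes* carrying out the process.
`gosempub` closes that gap with **semantic expansion**: a GO term is replaced
by itself plus every descendant reachable through the transitive `is_a` and
`part_of` relations, the genes annotated to any member of that expanded set
are collected from a Gene Association File (GAF), and their names, symbols
and synonyms become the OR-clause of a fielded boolean query:

```
(gene₁ OR gene₂ OR … OR geneₙ)[tiab] AND (species)[mesh] AND (keywords)[mesh|majr] AND (date range)[PDAT]
```

Expansion matters because annotation inheritance flows upward: a gene
annotated to *negative regulation of fatty acid metabolic process* is, by GO
semantics, also engaged in *regulation of fatty acid metabolic process* —
but a literal term lookup would never find it.

The package provides:

- **ontology** — OBO 1.2 parsing, term resolution (identifier > name >
  synonym), prefix suggestion, descendant closure, mean path-to-root
  granularity, and granularity-matched random term sampling;
- **annotations** — GAF 2.x parsing, term-set→gene lookup with species
  filtering, gene_info-style synonym augmentation, species name/taxon
  resolution with MeSH descriptors;
- **query_builder** — query composition with four systematic variants
  (`BASICq`, `MeSHq`, `ORq`, `NOKq`), deterministic serialization to the
  PubMed field-tag dialect, and length-bounded query splitting that
  preserves result-set semantics;
- **retrieval** — a local fielded search engine over MEDLINE-style XML or
  JSONL corpora (word-boundary phrase matching in title/abstract, whole
  MeSH-descriptor matching, closed date ranges), result compilation sorted
  by date, and keyword highlighting with character spans;
- **evaluation** — reviewer-union gold standards, precision / relative
  recall / F-score, Cohen's kappa, exact-subset overlap partitions, and
  cross-query pooled aggregates;
- **fixtures** — deterministic synthetic worlds (ontology + GAF + synonym
  table + planted citation corpus) whose correct retrieval answer is known
  by construction.

Relative recall is used because absolute recall is unknowable: the gold
standard is the union of the relevant articles returned by *any* compared
tool, as judged independently by two blinded reviewers.

## Worked example

Write the bundled mini-ontology (regulation of fatty acid metabolic process
and four descendants) with its five-gene GAF, then expand the top term:

```console
$ gosempub simulate --seed 7 --out demo --preset fig7
$ gosempub expand --obo demo/fig7.obo --term "regulation of fatty acid metabolism"
GO:0019217	regulation of fatty acid metabolic process
GO:0042304	regulation of fatty acid biosynthetic process
GO:0045717	negative regulation of fatty acid biosynthetic process
GO:0045922	negative regulation of fatty acid metabolic process
GO:0045923	positive regulation of fatty acid metabolic process
```

(The term was given by one of its GO synonyms; resolution is
case-insensitive and falls back from identifier to name to synonym.)

Only PPAR and CAV1 are annotated to GO:0019217 directly. With expansion the
gene pool grows to five:

```console
$ gosempub genes --obo demo/fig7.obo --gaf demo/fig7.gaf --term GO:0019217 --species human
APOA1	apolipoprotein A-I	apoA-I
BRCA1	breast cancer 1	RNF53
CAV1	caveolin 1	CAV
ChREBP	carbohydrate response element binding protein	MLXIPL|WBSCR14
PPAR	peroxisome proliferator activated receptor	PPARG|NR1C3
```

Compose the enriched query (species resolve to their MeSH descriptors;
`--last-years` needs an explicit `--today` so runs are reproducible):

```console
$ gosempub build-query --obo demo/fig7.obo --gaf demo/fig7.gaf \
    --term GO:0019217 --species "Homo sapiens" \
    --majr Liver --mesh "Lipid Metabolism" --last-years 5 --today 2011-03-28
("APOA1"[tiab] OR "apolipoprotein A-I"[tiab] OR … OR "NR1C3"[tiab]) AND "Humans"[mesh] AND "Lipid Metabolism"[mesh] AND "Liver"[majr] AND ("2006/03/28"[PDAT] : "2011/03/28"[PDAT])
```

Every keyword in the OR-clause is a name, symbol or synonym of one of the
five genes — three of which a non-expanded query would have missed.
`gosempub search` runs such a query against a local corpus file;
`gosempub eval` scores competing result lists against reviewer judgments
(`--kappa` prints inter-rater agreement, `--overlap` the exact-subset
partition of the tools' result sets).

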