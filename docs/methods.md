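# Methods

## Semantic expansion

The ontology is a directed acyclic graph whose edges point from child to
parent and are restricted to the two transitive relations `is_a` and
`part_of`. The expansion of a term *t* is *{t}* ∪ all terms from which *t*
is reachable along those edges — i.e. *t* plus its descendants. The
`regulates` family of relations is parsed but never traversed: regulation
edges do not carry annotation inheritance in the sense used here, and
following them would pull in genes whose products merely modulate the
process. Obsolete terms are retained in the graph for diagnostics but are
excluded from resolution, expansion and sampling.

Reachability runs on a `networkx` digraph; the oracle tests re-derive every
closure by exhaustive DFS over the raw edge list.

Each term must belong to exactly one of the three GO namespaces and reach
exactly one root of its namespace; cross-namespace edges are rejected at
parse time. Structural validation (acyclicity, edge endpoints defined)
happens on construction so that every downstream operation can assume a
well-formed DAG.

## Term granularity

A term's granularity is summarised by two numbers:

- **descendant count** — |expansion| − 1;
- **mean path to root** — the arithmetic mean of the lengths of *all
  distinct* directed paths from the term to its namespace root.

"All distinct paths" is a deliberate choice: with multiple inheritance a
term has several routes to the root, and averaging over every route weights
a term's placement by the full structure above it rather than by one
extremal path. The mean is computed by a topological-order dynamic program
(per node: number of paths to the root and their total length), so dense
diamond structures cost linear work rather than exponential enumeration;
tests check it against explicit path enumeration.

`sample_similar_terms` draws terms uniformly without replacement from the
candidates whose granularity falls in a window. The default window —
mean path in [3.5, 5.25] edges, descendants in [35, 244] — spans the range
between the broadest and the narrowest of the three lipid-metabolism
reference terms the evaluation is built around, so sampled terms are
comparable to them. Sampling is deterministic for a fixed (graph, filter,
n, seed).

## Gene keyword pools

Genes come from GAF 2.x. One gene product per object id; `NOT`-qualified
annotations are dropped (they assert the absence of a function and would
poison a retrieval query); all evidence codes are accepted by default, with
an optional exclusion set (`exclude_evidence`) for users who distrust e.g.
IEA. A gene's keyword pool is its symbol ∪ name ∪ synonyms, deduplicated
case-insensitively; pools from different genes are merged with the same
case-folded deduplication, keeping first-seen spelling and a stable order
(genes sorted by symbol). An optional gene_info-style synonym table merges
additional aliases by (taxon, symbol).

## Query model and variants

The composed query is
`(gene keywords, OR, tagged [tiab]) AND (species) AND (keywords) AND
(optional [PDAT] window) AND (optional free text)`, with species joined by
OR and keywords by AND unless overridden. Species atoms use the species'
MeSH descriptor ("Gallus gallus" → `"Chickens"[mesh]`), shipped as an
editable TSV, not hardcoded. Variants:

| variant | keywords | species |
|---|---|---|
| BASICq | MeSH or MAJR as flagged, AND | MeSH |
| MeSHq  | all MeSH (MAJR demoted), AND | MeSH |
| ORq    | all MAJR, OR | MAJR |
| NOKq   | dropped | MAJR |

Because every Major-Topic heading is also a MeSH heading, MeSHq can only
widen BASICq's result set — a containment the test suite asserts on every
generated world.

Serialization is deterministic: quoted phrases with lowercase field tags
(`[tiab]`, `[mesh]`, `[majr]`), date ranges as
`("YYYY/MM/DD"[PDAT] : "YYYY/MM/DD"[PDAT])`, parentheses exactly where a
child's operator differs from its parent's. A parser for the same dialect
ships with the package and round-trips every composed query, which is how
serializer injectivity is tested. Relative year windows ("last 5 years")
are closed intervals ending at an explicitly supplied `today` — there is no
hidden clock anywhere in the pipeline.

When the serialized query exceeds a URL length budget (default 2000
characters, configurable), the gene OR-clause is partitioned greedily, in
order, into the fewest contiguous blocks such that each block ANDed with
the *full* fixed clause fits the budget. Replicating the whole fixed clause
in every chunk is what makes the union of chunk results provably equal to
the unsplit result — a property tested against the local engine on random
worlds. Result sets from chunks are deduplicated by PMID.

## Local retrieval semantics

The offline engine gives the dialect concrete semantics: `[tiab]` atoms are
case-insensitive exact phrase matches on word boundaries in title or
abstract (hyphens and en-dashes normalized to spaces first, so "apoA-I"
matches "apoA I" but "FAS" never matches inside "FASN"); `[mesh]` compares
whole descriptor strings; `[majr]` does the same restricted to major-topic
headings; `[PDAT]` is a closed date interval; free-text atoms match title,
abstract or any descriptor. AND/OR evaluate set-theoretically. Two
independent code paths exist — set algebra over the corpus and a per-record
interpreter — and the tests require them to agree.

Deliberately **not** modelled: MeSH-tree explosion, PubMed's automatic term
mapping, stemming, and relevance ranking. Results are sorted by publication
date, newest first (the convention of literature tools), with descending
PMID as a deterministic tie-break; ranks are assigned 1..n. Highlighting
reports non-overlapping, leftmost-longest keyword occurrences as 0-based
half-open character spans into the original text (no normalization, so a
span's text always equals its keyword up to case).

## Evaluation

Gold standard: union of two reviewers' relevant selections over the pooled,
blinded result sets. Precision = hits/returned, relative recall =
hits/pool, F = 2PR/(P+R); empty denominators yield 0 (a convention the
benchmark data never exercises). Cohen's kappa on the 2×2 reviewer table is
(po − pe)/(1 − pe) and is refused (rather than returned) when pe = 1.
Pooled recall across queries sums hits and pools before dividing.

All metrics are computed unrounded; printed reports round **half-up** to 3
decimals (2 for kappa). Half-up matters: 5/16 = 0.3125 must print as 0.313,
which banker's rounding would miss.

The F-score formula is the standard harmonic mean; it reproduces all 36
published metric cells of the three benchmark queries from their raw
(returned, relevant, pool) counts, which is the regression the acceptance
suite runs.

## Synthetic worlds

`generate_world` emulates, at desk scale, the data the pipeline consumes in
production: a random single-namespace DAG (default 40 terms, depth ≤ 6,
20 % `part_of` edges, 15 % multi-parent terms), per-species gene sets
(default 12 genes each for mouse and human) with random annotations and
synonyms, and a citation corpus with planted queries. For each planted
query the generator forces one gene annotated to the query term itself and
one annotated only to a strict descendant, then writes 6 relevant records
(each containing a pool keyword, the query's topic heading, the species
descriptor and an in-window date — the first one carrying only the
descendant gene's keyword) and 16 distractors that each violate exactly one
of those conditions (no keyword / missing topic heading / out-of-window
date / keyword from another species' gene). Every query gets a distinct
topic heading, so answer keys cannot contaminate each other. The default
date window (2006-03-28..2011-03-28) mirrors the five-year window of the
benchmark queries.

The generator is byte-deterministic per seed and keeps its own bookkeeping
(term/edge/gene/annotation/record counts plus exact per-query PMID sets),
which doubles as an independent construction against which the parsers and
the end-to-end pipeline are checked. A `case_jumble` knob plants keywords
with flipped case to exercise the matcher.

What generated worlds do **not** emulate: real MEDLINE language (distractors
are structural, not linguistic), annotation-depth biases of real GOA,
homonymous gene symbols colliding with English words, or PubMed-side query
expansion. Passing tests therefore certify the machinery — closure,
composition, splitting, field semantics, scoring — not retrieval quality on
live PubMed, which additionally depends on those unmodelled effects. For
the same reason the published generalization-study counts (which depend on
2011 GO/GOA/PubMed snapshots) are replicated structurally — granularity-
filtered sampling and seeded world sweeps — rather than numerically.

## Degenerate inputs and errors

Empty gene pools abort composition (an empty OR-clause would silently match
nothing); a gene atom that cannot fit the length budget even alone raises
an unsplittable error naming the keyword; duplicate PMIDs abort corpus
loading; resolution distinguishes unknown, ambiguous (candidates listed)
and obsolete term errors; kappa with degenerate identical marginals raises
instead of dividing by zero.

## Known limitations

- Mean path to the root is the only path statistic offered; terms that
  reach zero or multiple namespace roots are excluded from sampling and
  rejected by the path computation.
- MeSH matching is whole-descriptor; no tree explosion or entry-term
  synonymy.
- The local engine's phrase matcher treats punctuation other than
  hyphen/en-dash literally.
- No live PubMed adapter ships; the serialized query dialect is the
  interface such an adapter would consume.
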