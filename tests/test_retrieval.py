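"""Corpus loading, boolean evaluation semantics, compilation, highlighting."""

import datetime as dt
import json

import pytest

from gosempub.errors import CorpusLoadError
from gosempub.fixtures import GeneratorConfig, generate_world, run_planted_query
from gosempub.query_builder import FieldTag, atom, conj, pdat
from gosempub.retrieval import (
    Citation,
    Corpus,
    MeshHeading,
    compile_results,
    evaluate_query,
    highlight_matches,
    load_corpus,
    matches_citation,
)

from oracles import naive_eval


def jsonl_record(pmid, title="A title", abstract="", date="2010-06-01", mesh=()):
    return json.dumps({
        "pmid": pmid, "title": title, "abstract": abstract,
        "authors": ["Doe J"], "journal": "J Test", "pub_date": date,
        "mesh": [{"descriptor": d, "major": m} for d, m in mesh],
    })


MEDLINE_XML = """<?xml version="1.0"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>12345</PMID>
      <Article>
        <Journal>
          <JournalIssue><PubDate><Year>2009</Year><Month>Mar</Month><Day>5</Day></PubDate></JournalIssue>
          <Title>Journal of Examples</Title>
        </Journal>
        <ArticleTitle>FASN regulates lipogenesis</ArticleTitle>
        <Abstract><AbstractText>Fatty acid synthase activity in liver.</AbstractText></Abstract>
        <AuthorList><Author><LastName>Doe</LastName><Initials>J</Initials></Author></AuthorList>
      </Article>
      <MeshHeadingList>
        <MeshHeading><DescriptorName MajorTopicYN="Y">Liver</DescriptorName></MeshHeading>
        <MeshHeading><DescriptorName MajorTopicYN="N">Lipid Metabolism</DescriptorName></MeshHeading>
      </MeshHeadingList>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""


class TestLoadCorpus:
    def test_empty_jsonl(self):
        assert len(load_corpus("", "jsonl")) == 0

    def test_duplicate_pmid_rejected(self):
        text = jsonl_record(1) + "\n" + jsonl_record(1)
        with pytest.raises(CorpusLoadError, match="duplicate"):
            load_corpus(text, "jsonl")

    def test_record_missing_mandatory_field_skipped(self, caplog):
        text = '{"pmid": 7}\n' + jsonl_record(8)
        with caplog.at_level("WARNING"):
            corpus = load_corpus(text, "jsonl")
        assert set(corpus.citations) == {8}

    def test_planted_corpus_size_matches_generator(self, world):
        corpus = load_corpus(world.corpus_jsonl, "jsonl")
        assert len(corpus) == world.key.record_count

    def test_medline_xml_major_topic_flag(self):
        corpus = load_corpus(MEDLINE_XML, "medline-xml")
        citation = corpus.citations[12345]
        assert citation.pub_date == dt.date(2009, 3, 5)
        assert MeshHeading("Liver", True) in citation.mesh
        assert MeshHeading("Lipid Metabolism", False) in citation.mesh
        assert citation.authors == ["Doe J"]


def small_corpus():
    corpus = Corpus()
    corpus.add(Citation(pmid=1, title="ACC1 in liver", abstract="",
                        pub_date=dt.date(2010, 1, 1),
                        mesh=[MeshHeading("Liver", True)]))
    corpus.add(Citation(pmid=2, title="SCD1 function", abstract="fatty acids",
                        pub_date=dt.date(2011, 1, 1),
                        mesh=[MeshHeading("Liver", False)]))
    corpus.add(Citation(pmid=3, title="Unrelated", abstract="nothing here",
                        pub_date=dt.date(2011, 1, 1),
                        mesh=[MeshHeading("Brain", True)]))
    return corpus


class TestEvaluate:
    def test_or_unions_disjoint_matches(self):
        corpus = small_corpus()
        expr = conj("OR", [atom("ACC1", FieldTag.TIAB), atom("SCD1", FieldTag.TIAB)])
        assert evaluate_query(expr, corpus) == {1, 2}

    def test_and_intersects(self):
        corpus = small_corpus()
        expr = conj("AND", [atom("SCD1", FieldTag.TIAB), atom("Liver", FieldTag.MESH)])
        assert evaluate_query(expr, corpus) == {2}

    def test_majr_is_a_restriction_of_mesh(self):
        corpus = small_corpus()
        mesh = evaluate_query(atom("Liver", FieldTag.MESH), corpus)
        majr = evaluate_query(atom("Liver", FieldTag.MAJR), corpus)
        assert majr <= mesh
        assert mesh == {1, 2} and majr == {1}

    def test_pdat_closed_range(self):
        corpus = small_corpus()
        window = pdat(dt.date(2010, 1, 1), dt.date(2010, 12, 31))
        assert evaluate_query(window, corpus) == {1}

    def test_phrase_needs_word_boundaries(self):
        corpus = Corpus()
        corpus.add(Citation(pmid=5, title="ChREBPx is not ChREBP match? FASN1",
                            pub_date=dt.date(2010, 1, 1)))
        assert evaluate_query(atom("ChREBP", FieldTag.TIAB), corpus) == {5}
        assert evaluate_query(atom("FASN", FieldTag.TIAB), corpus) == set()

    def test_hyphen_normalized_in_phrases(self):
        corpus = Corpus()
        corpus.add(Citation(pmid=6, title="apoA-I levels",
                            pub_date=dt.date(2010, 1, 1)))
        assert evaluate_query(atom("apoA I", FieldTag.TIAB), corpus) == {6}

    def test_adding_a_record_never_removes_results(self, world):
        planted = world.key.planted[0]
        before = run_planted_query(world, planted)
        grown = world.corpus_jsonl + jsonl_record(999999) + "\n"
        import dataclasses
        bigger = dataclasses.replace(world, corpus_jsonl=grown)
        assert run_planted_query(bigger, planted) >= before

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_per_record_interpreter(self, seed):
        world = generate_world(GeneratorConfig(seed=100 + seed))
        corpus = load_corpus(world.corpus_jsonl, "jsonl")
        planted = world.key.planted[0]
        exprs = [
            atom(planted.keyword, FieldTag.MESH),
            conj("OR", [atom(planted.keyword, FieldTag.MAJR),
                        atom("Mice", FieldTag.MESH)]),
            conj("AND", [atom("planted context", FieldTag.TIAB),
                         pdat(*planted.window)]),
        ]
        for expr in exprs:
            assert evaluate_query(expr, corpus) == naive_eval(expr, corpus)
            assert evaluate_query(expr, corpus) == {
                c.pmid for c in corpus if matches_citation(expr, c)
            }


class TestCompileResults:
    def test_empty_set(self):
        assert len(compile_results(set(), small_corpus(), ["x"])) == 0

    def test_sorted_newest_first_with_pmid_tiebreak(self):
        corpus = small_corpus()
        results = compile_results({1, 2, 3}, corpus, [])
        assert [e.citation.pmid for e in results.entries] == [3, 2, 1]
        assert [e.rank for e in results.entries] == [1, 2, 3]

    def test_unknown_pmid_is_an_error(self):
        with pytest.raises(KeyError):
            compile_results({99}, small_corpus(), [])


class TestHighlight:
    def citation(self, title, abstract=""):
        return Citation(pmid=1, title=title, abstract=abstract,
                        pub_date=dt.date(2010, 1, 1))

    def test_absent_keyword_gives_no_spans(self):
        assert highlight_matches(self.citation("nothing to see"), ["FASN"]) == []

    def test_direct_match_span(self):
        (m,) = highlight_matches(self.citation("FASN regulates lipogenesis"), ["FASN"])
        assert (m.field, m.span) == ("title", (0, 4))

    def test_leftmost_longest_suppresses_nested_keyword(self):
        cit = self.citation("fatty acid synthase and FAS levels")
        matches = highlight_matches(cit, ["fatty acid synthase", "FAS"])
        assert [(m.keyword, m.span) for m in matches] == [
            ("fatty acid synthase", (0, 19)),
            ("FAS", (24, 27)),
        ]

    def test_spans_disjoint_and_text_matches_keyword(self, world):
        from gosempub.annotations import parse_gaf
        from gosempub.query_builder import gene_keywords

        corpus = load_corpus(world.corpus_jsonl, "jsonl")
        keywords = gene_keywords(set(parse_gaf(world.gaf).genes.values()))
        for citation in corpus:
            matches = highlight_matches(citation, keywords)
            by_field: dict[str, list] = {}
            for m in matches:
                text = getattr(citation, m.field)[m.span[0]:m.span[1]]
                assert text.casefold() == m.keyword.casefold()
                by_field.setdefault(m.field, []).append(m.span)
            for spans in by_field.values():
                spans.sort()
                for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                    assert e1 <= s2
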