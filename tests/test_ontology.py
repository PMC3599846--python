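"""Ontology parsing, term resolution, closure and granularity checks."""

import pytest

from gosempub.errors import (
    AmbiguousTermError,
    ObsoleteTermError,
    OboParseError,
    StructuralError,
    UnknownTermError,
)
from gosempub.ontology import (
    GranularityFilter,
    TermID,
    descendant_count,
    expansion_set,
    mean_path_to_root,
    parse_obo,
    resolve_term,
    sample_similar_terms,
    suggest_terms,
)

from oracles import brute_expansion, brute_mean_path, brute_suggest, random_ontology


class TestParse:
    def test_minimal_chain(self, chain_graph):
        assert len(chain_graph.terms) == 3
        assert len(chain_graph.edges) == 2
        assert chain_graph.roots == {"GO:0000001"}

    def test_fig7_root_is_top_term(self, fig7):
        graph, _ = fig7
        assert graph.roots == {"GO:0019217"}

    def test_part_of_edges_are_followed(self):
        obo = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: whole\nnamespace: biological_process\n\n"
            "[Term]\nid: GO:0000002\nname: part\nnamespace: biological_process\n"
            "relationship: part_of GO:0000001\n"
        )
        graph = parse_obo(obo)
        assert expansion_set(graph, "GO:0000001") == {"GO:0000001", "GO:0000002"}

    def test_other_relationships_ignored(self):
        obo = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: a\nnamespace: biological_process\n\n"
            "[Term]\nid: GO:0000002\nname: b\nnamespace: biological_process\n"
            "is_a: GO:0000001\n"
            "relationship: regulates GO:0000001\n"
        )
        graph = parse_obo(obo)
        assert {e.relation for e in graph.edges} == {"is_a"}

    def test_malformed_stanza_line_is_named(self):
        obo = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: a\nnamespace: biological_process\n"
            "this line has no tag\n"
        )
        with pytest.raises(OboParseError, match="line 7"):
            parse_obo(obo)

    def test_cycle_is_reported(self):
        obo = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: a\nnamespace: biological_process\n"
            "is_a: GO:0000002\n\n"
            "[Term]\nid: GO:0000002\nname: b\nnamespace: biological_process\n"
            "is_a: GO:0000001\n"
        )
        with pytest.raises(StructuralError, match="cycle"):
            parse_obo(obo)

    def test_cross_namespace_edge_rejected(self):
        obo = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: a\nnamespace: biological_process\n\n"
            "[Term]\nid: GO:0000002\nname: b\nnamespace: molecular_function\n"
            "is_a: GO:0000001\n"
        )
        with pytest.raises(StructuralError, match="cross-namespace"):
            parse_obo(obo)

    def test_generated_world_counts_match_generator(self, world):
        graph = parse_obo(world.obo)
        assert len(graph.terms) == world.key.term_count
        assert len(graph.edges) == world.key.edge_count

    def test_term_id_format_is_validated(self):
        with pytest.raises(ValueError):
            TermID("GO:123")
        assert TermID("GO:0008610") == "GO:0008610"


OBSOLETE_OBO = (
    "format-version: 1.2\n\n"
    "[Term]\nid: GO:0000001\nname: live process\nnamespace: biological_process\n\n"
    "[Term]\nid: GO:0000002\nname: dead process\nnamespace: biological_process\n"
    "is_obsolete: true\n"
)


class TestResolve:
    def test_identifier_identity(self, lipid_graph):
        assert resolve_term(lipid_graph, "GO:0008610") == "GO:0008610"

    def test_synonym_maps_to_term(self, lipid_graph):
        assert resolve_term(lipid_graph, "lipogenesis") == "GO:0008610"

    def test_name_match_is_case_insensitive(self, lipid_graph):
        assert resolve_term(lipid_graph, "  LIPID TRANSPORT ") == "GO:0006869"

    def test_unknown_text_raises(self, lipid_graph):
        with pytest.raises(UnknownTermError):
            resolve_term(lipid_graph, "no such process")
        with pytest.raises(UnknownTermError):
            resolve_term(lipid_graph, "GO:9999999")

    def test_name_takes_precedence_over_synonym(self):
        obo = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: alpha process\nnamespace: biological_process\n\n"
            "[Term]\nid: GO:0000002\nname: beta process\nnamespace: biological_process\n"
            'synonym: "alpha process" EXACT []\n'
        )
        assert resolve_term(parse_obo(obo), "alpha process") == "GO:0000001"

    def test_shared_synonym_is_ambiguous(self):
        obo = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: a\nnamespace: biological_process\n"
            'synonym: "shared alias" EXACT []\n\n'
            "[Term]\nid: GO:0000002\nname: b\nnamespace: biological_process\n"
            'synonym: "shared alias" EXACT []\n'
        )
        with pytest.raises(AmbiguousTermError) as err:
            resolve_term(parse_obo(obo), "shared alias")
        assert err.value.candidates == ["GO:0000001", "GO:0000002"]

    def test_obsolete_term_raises(self):
        graph = parse_obo(OBSOLETE_OBO)
        with pytest.raises(ObsoleteTermError):
            resolve_term(graph, "GO:0000002")
        with pytest.raises(ObsoleteTermError):
            resolve_term(graph, "dead process")


class TestSuggest:
    def test_full_unique_name(self, lipid_graph):
        hits = suggest_terms(lipid_graph, "lipid transport", limit=5)
        assert hits == [("GO:0006869", "lipid transport")]

    def test_prefix_covers_names_and_synonyms(self, lipid_graph):
        ids = {t for t, _ in suggest_terms(lipid_graph, "lipid", limit=10)}
        assert {"GO:0008610", "GO:0006869"} <= ids

    def test_short_prefix_rejected(self, lipid_graph):
        with pytest.raises(ValueError):
            suggest_terms(lipid_graph, "l")

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_linear_scan(self, seed):
        graph = random_ontology(seed, n_terms=20)
        got = {t for t, _ in suggest_terms(graph, "random process 0", limit=100)}
        assert got == brute_suggest(graph, "random process 0")


class TestExpansion:
    def test_leaf_is_singleton(self, chain_graph):
        assert expansion_set(chain_graph, "GO:0000003") == {"GO:0000003"}
        assert descendant_count(chain_graph, "GO:0000003") == 0

    def test_fig7_top_term_covers_all_boxes(self, fig7):
        graph, _ = fig7
        assert expansion_set(graph, "GO:0019217") == {
            "GO:0019217", "GO:0045922", "GO:0045923", "GO:0042304", "GO:0045717",
        }

    def test_unknown_and_obsolete_rejected(self):
        graph = parse_obo(OBSOLETE_OBO)
        with pytest.raises(UnknownTermError):
            expansion_set(graph, "GO:0000042")
        with pytest.raises(ObsoleteTermError):
            expansion_set(graph, "GO:0000002")

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_reverse_dfs(self, seed):
        graph = random_ontology(seed)
        for term in graph.terms:
            assert expansion_set(graph, term) == brute_expansion(graph, term)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_under_containment(self, seed):
        graph = random_ontology(seed)
        sets = {t: expansion_set(graph, t) for t in graph.terms}
        for t2, s2 in sets.items():
            for t1 in s2:
                assert sets[t1] <= s2


class TestMeanPath:
    def test_root_is_zero(self, chain_graph):
        assert mean_path_to_root(chain_graph, "GO:0000001") == 0.0

    def test_pure_chain_equals_length(self, chain_graph):
        assert mean_path_to_root(chain_graph, "GO:0000003") == 2.0

    def test_diamond_averages_both_paths(self, diamond_graph):
        # paths of length 2 (via the middle term) and 1 (direct)
        assert mean_path_to_root(diamond_graph, "GO:0000012") == 1.5

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_path_enumeration(self, seed):
        graph = random_ontology(seed)
        (root,) = graph.roots
        for term in graph.terms:
            got = mean_path_to_root(graph, term)
            assert got == pytest.approx(brute_mean_path(graph, term, root))


class TestSampling:
    def test_forced_selection_and_determinism(self):
        graph = random_ontology(3, n_terms=25)
        wide = GranularityFilter(0.0, 100.0, 0, 10_000)
        everything = sample_similar_terms(graph, "biological_process", wide,
                                          n=25, seed=1)
        assert sorted(everything) == sorted(graph.terms)
        again = sample_similar_terms(graph, "biological_process", wide,
                                     n=25, seed=1)
        assert everything == again

    def test_samples_satisfy_both_predicates(self):
        graph = random_ontology(7, n_terms=40)
        window = GranularityFilter(1.0, 3.0, 1, 30)
        sampled = sample_similar_terms(graph, "biological_process", window,
                                       n=3, seed=5)
        assert len(set(sampled)) == 3
        for term in sampled:
            assert window.admits(mean_path_to_root(graph, term),
                                 descendant_count(graph, term))

    def test_too_few_candidates_reports_count(self):
        graph = random_ontology(3, n_terms=5)
        narrow = GranularityFilter(0.5, 0.5, 10_000, 10_001)
        with pytest.raises(UnknownTermError, match="0 term"):
            sample_similar_terms(graph, "biological_process", narrow, n=2, seed=0)

    def test_default_window_matches_reference_terms(self):
        default = GranularityFilter()
        assert default.admits(3.5, 243)   # broadest reference term
        assert default.admits(5.25, 35)   # narrowest reference term
        assert not default.admits(2.0, 100)
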