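"""Structural validation, path enumeration and provenance reporting."""

import pytest

from statselect import (
    ToyKbSpec,
    enumerate_paths,
    export_dot,
    make_toy_kb,
    provenance_report,
    shortest_path_to,
    validate_kb,
)
from statselect.errors import InvalidKBError, UnreachableTestError
from statselect.model import DecisionNode, Question, Recommendation


def brute_force_paths(kb):
    """Independent oracle: walk the raw node dicts recursively."""
    found = []

    def walk(target, prefix):
        if target in kb.recommendations:
            found.append(("".join(prefix), target, len(prefix)))
            return
        node = kb.nodes[target]
        walk(node.yes_target, prefix + ["y"])
        walk(node.no_target, prefix + ["n"])

    walk(kb.root, [])
    return found


class TestValidation:
    def test_packaged_kb_passes_with_zero_errors(self, kb):
        report = validate_kb(kb)
        assert report.passed
        assert report.errors() == []

    def test_cycle_is_detected_and_names_the_back_edge(self, toy_kb3):
        broken = toy_kb3.copy()
        # point a deep node's yes-branch at its own ancestor (the root)
        deep = next(n for n in broken.nodes.values()
                    if broken.is_recommendation(n.yes_target))
        broken.nodes[deep.id] = DecisionNode(
            id=deep.id, question_id=deep.question_id,
            yes_target=broken.root, no_target=deep.no_target)
        report = validate_kb(broken)
        assert not report.passed
        assert any(f.code == "cycle" for f in report.findings)

    def test_orphan_question_is_a_warning_not_an_error(self, toy_kb):
        kb2 = toy_kb.copy()
        kb2.questions["q_extra"] = Question(
            id="q_extra", text="Unused question?", category="special_case")
        report = validate_kb(kb2)
        assert report.passed
        assert any(f.code == "orphan_question" and f.record_id == "q_extra"
                   for f in report.findings)

    def test_unreachable_recommendation_is_an_error(self, toy_kb):
        kb2 = toy_kb.copy()
        kb2.recommendations["r_island"] = Recommendation(
            id="r_island", test_ids=("t001",))
        report = validate_kb(kb2)
        assert not report.passed
        assert any(f.code == "unreachable_recommendation" for f in
                   report.findings)


class TestEnumeration:
    def test_packaged_structure_counts(self, kb):
        s = enumerate_paths(kb).summary
        assert s.n_questions_used == 44
        assert s.n_distinct_recommendations == 59
        assert s.n_tests_covered == 85
        assert (s.depth_min, s.depth_max) == (4, 11)
        assert sum(s.depth_histogram.values()) == s.n_paths

    def test_toy_minimal_tree(self, toy_kb):
        catalog = enumerate_paths(toy_kb)
        assert [p.depth for p in catalog.paths] == [1, 1]

    @pytest.mark.parametrize("spec", [
        ToyKbSpec(depth=3, n_recommendations=4),
        ToyKbSpec(depth=6, complete=False, n_recommendations=3, seed=2),
        ToyKbSpec(depth=12, complete=False, n_recommendations=5, seed=9),
    ])
    def test_enumeration_matches_brute_force_oracle(self, spec):
        kb = make_toy_kb(spec)
        catalog = enumerate_paths(kb)
        oracle = brute_force_paths(kb)
        assert [(p.answers, p.recommendation_id, p.depth)
                for p in catalog.paths] == oracle
        assert catalog.summary.n_paths == len(oracle)
        assert catalog.summary.depth_max == max(d for _, _, d in oracle)

    def test_oracle_equivalence_on_packaged_kb(self, kb):
        catalog = enumerate_paths(kb)
        assert [(p.answers, p.recommendation_id, p.depth)
                for p in catalog.paths] == brute_force_paths(kb)

    def test_conservation_every_recommendation_is_reached(self, kb):
        catalog = enumerate_paths(kb)
        reached = {p.recommendation_id for p in catalog.paths}
        assert reached == set(kb.recommendations)

    def test_invalid_kb_is_refused(self, toy_kb):
        broken = toy_kb.copy()
        broken.recommendations["r_island"] = Recommendation(
            id="r_island", test_ids=("t001",))
        with pytest.raises(InvalidKBError):
            enumerate_paths(broken)

    def test_test_lists_do_not_affect_topology(self, kb):
        """Dropping a leaf's second test changes no path or depth."""
        before = enumerate_paths(kb)
        kb2 = kb.copy()
        rec = kb2.recommendations["r_wilcoxon_sign"]
        kb2.recommendations["r_wilcoxon_sign"] = Recommendation(
            id=rec.id, test_ids=rec.test_ids[:1], guidance=rec.guidance)
        after = enumerate_paths(kb2)
        assert [(p.answers, p.depth) for p in after.paths] == \
            [(p.answers, p.depth) for p in before.paths]
        assert after.summary.n_paths == before.summary.n_paths


class TestShortestPath:
    def test_ordered_logistic_is_the_four_question_minimum(self, kb):
        vector, depth = shortest_path_to(kb, "ordered logistic regression")
        assert depth == 4
        assert depth == enumerate_paths(kb).summary.depth_min

    def test_chi_square_trend_is_the_eleven_question_maximum(self, kb):
        vector, depth = shortest_path_to(kb, "Chi-square test for trend")
        assert depth == 11
        assert depth == enumerate_paths(kb).summary.depth_max

    def test_toy_first_leaf(self, toy_kb):
        vector, depth = shortest_path_to(toy_kb, "t001")
        assert (vector, depth) == ("y", 1)

    def test_unreachable_test_raises(self, toy_kb):
        with pytest.raises(UnreachableTestError):
            shortest_path_to(toy_kb, "no such test")


class TestProvenance:
    def test_ten_sources_with_expected_counts(self, kb):
        prov = provenance_report(kb)
        assert len(prov) == 10
        assert prov["Rosner"]["n_tests"] == 36
        assert prov["Rosner"]["is_base"] is True
        assert prov["UCLA"]["n_tests"] == 31
        assert sum(1 for v in prov.values() if v["is_base"]) == 1

    def test_source_lists_resolve_to_canonical_names(self, kb):
        prov = provenance_report(kb)
        assert "Mann-Whitney U test" in prov["Gaddis and Gaddis"]["tests"]


class TestDotExport:
    def test_dot_contains_every_node_and_leaf(self, kb):
        dot = export_dot(kb)
        assert dot.startswith("digraph")
        for nid in kb.nodes:
            assert f'"{nid}"' in dot
        for rid in kb.recommendations:
            assert f'"{rid}"' in dot
        assert dot.count("[label=\"yes\"]") == len(kb.nodes)
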