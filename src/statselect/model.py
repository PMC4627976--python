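"""Domain model for the test-selection knowledge base.

A :class:`KnowledgeBase` bundles six identifier-keyed collections — decision
nodes, questions, recommendations, test methods, glossary entries and source
trees — plus the id of the root node.  Decision nodes are strictly binary:
each carries a question and two targets (``yes``/``no``), each target being
either another node or a recommendation leaf naming one or more tests.

Ids are stable human-readable slugs (``q_...`` questions, ``n_...`` nodes,
``r_...`` recommendations, ``t_...`` tests) so the serialized document diffs
cleanly, but nothing in the code relies on the prefixes: an id's kind is
decided by the collection it lives in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterator

__all__ = [
    "CATEGORIES",
    "TEST_FAMILIES",
    "GlossaryEntry",
    "Question",
    "TestMethod",
    "SourceTree",
    "Recommendation",
    "DecisionNode",
    "KnowledgeBase",
    "lookup_glossary",
    "canonicalize_test_name",
    "normalize_name",
]

#: Question content categories: what facet of the data set a question probes.
CATEGORIES = (
    "number_of_variables",
    "number_of_samples",
    "sample_dependency",
    "normality_assumption",
    "scale_type",
    "special_case",
)

#: Coarse families for the catalogued statistical tests.
TEST_FAMILIES = (
    "parametric",
    "nonparametric",
    "correlation_agreement",
    "regression",
    "categorical",
    "survival",
    "multiple_comparison",
    "variance",
    "diagnostic_roc",
    "rates_incidence",
)


@dataclass(frozen=True)
class GlossaryEntry:
    """A statistical term and its plain-language definition."""

    term: str
    definition: str


@dataclass(frozen=True)
class Question:
    """A yes/no question shown at a decision step.

    ``explanation`` is the optional clarifying text shown on demand;
    ``glossary_terms`` lists glossary keys occurring in ``text``.
    """

    id: str
    text: str
    category: str
    explanation: str = ""
    glossary_terms: tuple[str, ...] = ()


@dataclass(frozen=True)
class TestMethod:
    """One statistical test (or named procedure) the tree can recommend.

    Synonymous names (e.g. Mann–Whitney U test / Wilcoxon rank sum test)
    collapse to a single record with ``aliases``; ``sources`` names the
    published source trees that provide decision support for the test.
    """

    id: str
    canonical_name: str
    family: str
    aliases: tuple[str, ...] = ()
    sources: tuple[str, ...] = ()


@dataclass(frozen=True)
class SourceTree:
    """A published decision tree whose tests were folded into the unified one."""

    name: str
    test_ids: tuple[str, ...]
    is_base: bool = False


@dataclass(frozen=True)
class Recommendation:
    """A terminal leaf: one or more tests appropriate under the path's answers."""

    id: str
    test_ids: tuple[str, ...]
    guidance: str = ""

    def label(self, kb: "KnowledgeBase") -> str:
        """Human-readable test listing, e.g. for trace rendering."""
        return " or ".join(kb.tests[t].canonical_name for t in self.test_ids)


@dataclass(frozen=True)
class DecisionNode:
    """An internal binary branching point."""

    id: str
    question_id: str
    yes_target: str
    no_target: str

    def target(self, answer_yes: bool) -> str:
        return self.yes_target if answer_yes else self.no_target


@dataclass
class KnowledgeBase:
    """The whole decision apparatus, fully cross-linked."""

    metadata: dict
    root: str
    nodes: dict[str, DecisionNode] = field(default_factory=dict)
    questions: dict[str, Question] = field(default_factory=dict)
    recommendations: dict[str, Recommendation] = field(default_factory=dict)
    tests: dict[str, TestMethod] = field(default_factory=dict)
    glossary: dict[str, GlossaryEntry] = field(default_factory=dict)
    sources: dict[str, SourceTree] = field(default_factory=dict)

    # -- resolution helpers -------------------------------------------------

    def is_node(self, target_id: str) -> bool:
        return target_id in self.nodes

    def is_recommendation(self, target_id: str) -> bool:
        return target_id in self.recommendations

    def question_of(self, node_id: str) -> Question:
        return self.questions[self.nodes[node_id].question_id]

    def root_node(self) -> DecisionNode:
        return self.nodes[self.root]

    def iter_targets(self) -> Iterator[tuple[str, str, str]]:
        """Yield ``(node_id, branch, target_id)`` for every branch."""
        for node in self.nodes.values():
            yield node.id, "yes", node.yes_target
            yield node.id, "no", node.no_target

    def structurally_equal(self, other: "KnowledgeBase") -> bool:
        """Same ids, branching and texts; metadata is compared too."""
        return (
            self.metadata == other.metadata
            and self.root == other.root
            and self.nodes == other.nodes
            and self.questions == other.questions
            and self.recommendations == other.recommendations
            and self.tests == other.tests
            and self.glossary == other.glossary
            and self.sources == other.sources
        )

    def copy(self) -> "KnowledgeBase":
        return replace(
            self,
            metadata=dict(self.metadata),
            nodes=dict(self.nodes),
            questions=dict(self.questions),
            recommendations=dict(self.recommendations),
            tests=dict(self.tests),
            glossary=dict(self.glossary),
            sources=dict(self.sources),
        )


# -- name normalization and lookups ------------------------------------------

_DASHES = "‐‑‒–—―−"


def normalize_name(name: str) -> str:
    """Case-, whitespace- and dash-insensitive key for name matching.

    ``"Mann–Whitney U test"``, ``"mann-whitney u test"`` and
    ``"Mann Whitney U Test"`` all map to the same key.
    """
    s = name.strip().lower()
    for d in _DASHES:
        s = s.replace(d, "-")
    s = s.replace("-", " ")
    s = s.replace("’", "'")
    s = re.sub(r"\s+", " ", s)
    return s


def lookup_glossary(kb: KnowledgeBase, term: str) -> GlossaryEntry | None:
    """Case-insensitive glossary lookup; ``None`` signals not-found."""
    key = normalize_name(term)
    for entry in kb.glossary.values():
        if normalize_name(entry.term) == key:
            return entry
    return None


def canonicalize_test_name(kb: KnowledgeBase, name: str) -> TestMethod | None:
    """Resolve a test name or alias to its TestMethod; ``None`` if unknown.

    Matching ignores case, surrounding whitespace and dash style, so the
    spelling variants kept as aliases (Cochrane/Cochran, Dunnet/Dunnett…)
    and typographic dashes all resolve.
    """
    key = normalize_name(name)
    for test in kb.tests.values():
        if normalize_name(test.canonical_name) == key:
            return test
        for alias in test.aliases:
            if normalize_name(alias) == key:
                return test
    return None
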