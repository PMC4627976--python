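"""Structural validation, exhaustive path enumeration and provenance.

This module turns the knowledge base's structural claims into computed
facts: every summary number (path counts, depth extremes, coverage) is
derived from an actual traversal of the tree, never read from metadata.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import InvalidKBError, UnreachableTestError
from .model import CATEGORIES, KnowledgeBase, TestMethod, normalize_name

__all__ = [
    "Finding", "ValidationReport", "Path", "PathSummary", "PathCatalog",
    "validate_kb", "enumerate_paths", "shortest_path_to",
    "provenance_report", "export_dot",
]


@dataclass(frozen=True)
class Finding:
    """One validation observation: severity is error / warning / info."""

    severity: str
    code: str
    message: str
    record_id: str = ""


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    def render(self) -> str:
        status = "PASSED" if self.passed else "FAILED"
        lines = [f"Validation {status} "
                 f"({len(self.errors())} error(s), {len(self.findings)} finding(s))"]
        for f in self.findings:
            rid = f" [{f.record_id}]" if f.record_id else ""
            lines.append(f"  {f.severity.upper():7} {f.code}{rid}: {f.message}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "findings": [
                {"severity": f.severity, "code": f.code,
                 "message": f.message, "record_id": f.record_id}
                for f in self.findings
            ],
        }


# --------------------------------------------------------------------------
# validation

def validate_kb(kb: KnowledgeBase) -> ValidationReport:
    """Audit a knowledge base; problems are findings, not exceptions.

    Error-level checks (break traversal or core contracts): unresolvable
    root/targets/questions, cycles among decision nodes, unreachable nodes
    or recommendations, illegal question categories, empty recommendations,
    ambiguous test names.  Warning-level checks: orphan questions, glossary
    terms and tests referenced by nothing reachable.
    """
    report = ValidationReport()
    add = report.findings.append

    # resolvability (binary totality). load_kb already guarantees this for
    # file-loaded KBs; hand-constructed ones get findings instead of crashes.
    resolvable = True
    if kb.root not in kb.nodes:
        add(Finding("error", "unresolved_root",
                    f"root {kb.root!r} is not a decision node", kb.root))
        resolvable = False
    for node in kb.nodes.values():
        if node.question_id not in kb.questions:
            add(Finding("error", "unresolved_question",
                        f"node references unknown question {node.question_id!r}",
                        node.id))
        for branch, target in (("yes", node.yes_target), ("no", node.no_target)):
            if not target:
                add(Finding("error", "missing_branch",
                            f"{branch}-branch target is empty", node.id))
                resolvable = False
            elif target not in kb.nodes and target not in kb.recommendations:
                add(Finding("error", "unresolved_target",
                            f"{branch}-branch target {target!r} does not resolve",
                            node.id))
                resolvable = False

    for rec in kb.recommendations.values():
        if not rec.test_ids:
            add(Finding("error", "empty_recommendation",
                        "recommendation names no tests", rec.id))
        for tid in rec.test_ids:
            if tid not in kb.tests:
                add(Finding("error", "unresolved_test",
                            f"recommendation references unknown test {tid!r}",
                            rec.id))

    for q in kb.questions.values():
        if q.category not in CATEGORIES:
            add(Finding("error", "illegal_category",
                        f"category {q.category!r} is not one of {CATEGORIES}",
                        q.id))
        for term in q.glossary_terms:
            if term not in kb.glossary:
                add(Finding("error", "unresolved_glossary_term",
                            f"question references unknown glossary term {term!r}",
                            q.id))

    # acyclicity over node->node edges
    if resolvable:
        _check_cycles(kb, add)

    # reachability from root
    reached_nodes, reached_recs = _reachable(kb)
    for nid in kb.nodes:
        if nid not in reached_nodes:
            add(Finding("error", "unreachable_node",
                        "decision node is not reachable from the root", nid))
    for rid in kb.recommendations:
        if rid not in reached_recs:
            add(Finding("error", "unreachable_recommendation",
                        "recommendation is not reachable from the root", rid))

    # orphans (warnings)
    used_questions = {kb.nodes[nid].question_id for nid in reached_nodes}
    for qid in kb.questions:
        if qid not in used_questions:
            add(Finding("warning", "orphan_question",
                        "question is referenced by no reachable node", qid))
    covered_tests = {
        tid for rid in reached_recs for tid in kb.recommendations[rid].test_ids
    }
    for tid in kb.tests:
        if tid not in covered_tests:
            add(Finding("warning", "orphan_test",
                        "test appears in no reachable recommendation", tid))
    used_terms = {
        term for qid in used_questions
        for term in kb.questions[qid].glossary_terms if qid in kb.questions
    }
    for term in kb.glossary:
        if term not in used_terms:
            add(Finding("warning", "orphan_glossary_term",
                        "glossary term occurs in no used question", term))

    # ambiguous test names: no string may resolve to two TestMethods
    seen: dict[str, str] = {}
    for test in kb.tests.values():
        for name in (test.canonical_name, *test.aliases):
            key = normalize_name(name)
            if key in seen and seen[key] != test.id:
                add(Finding("error", "duplicate_alias",
                            f"name {name!r} resolves to both "
                            f"{seen[key]!r} and {test.id!r}", test.id))
            else:
                seen[key] = test.id
    return report


def _check_cycles(kb: KnowledgeBase, add) -> None:
    WHITE, GREY, BLACK = 0, 1, 2
    color = {nid: WHITE for nid in kb.nodes}

    def dfs(nid: str) -> None:
        color[nid] = GREY
        node = kb.nodes[nid]
        for target in (node.yes_target, node.no_target):
            if target in kb.nodes:
                if color[target] == GREY:
                    add(Finding("error", "cycle",
                                f"back-edge {nid} -> {target} creates a cycle",
                                nid))
                elif color[target] == WHITE:
                    dfs(target)
        color[nid] = BLACK

    for nid in kb.nodes:
        if color[nid] == WHITE:
            dfs(nid)


def _reachable(kb: KnowledgeBase) -> tuple[set[str], set[str]]:
    nodes: set[str] = set()
    recs: set[str] = set()
    stack = [kb.root] if kb.root in kb.nodes else []
    while stack:
        nid = stack.pop()
        if nid in nodes:
            continue
        nodes.add(nid)
        for target in (kb.nodes[nid].yes_target, kb.nodes[nid].no_target):
            if target in kb.nodes:
                stack.append(target)
            elif target in kb.recommendations:
                recs.add(target)
    return nodes, recs


# --------------------------------------------------------------------------
# path enumeration

@dataclass(frozen=True)
class Path:
    """One root-to-leaf route: its answer vector, leaf and depth."""

    answers: str          # compact vector over {y, n}
    recommendation_id: str
    depth: int


@dataclass(frozen=True)
class PathSummary:
    n_paths: int
    n_distinct_recommendations: int
    n_questions_used: int
    n_tests_covered: int
    depth_min: int
    depth_max: int
    depth_histogram: dict[int, int]

    def to_dict(self) -> dict:
        return {
            "n_paths": self.n_paths,
            "n_distinct_recommendations": self.n_distinct_recommendations,
            "n_questions_used": self.n_questions_used,
            "n_tests_covered": self.n_tests_covered,
            "depth_min": self.depth_min,
            "depth_max": self.depth_max,
            "depth_histogram": dict(self.depth_histogram),
        }


@dataclass(frozen=True)
class PathCatalog:
    paths: tuple[Path, ...]
    summary: PathSummary


def enumerate_paths(kb: KnowledgeBase) -> PathCatalog:
    """Exhaustive depth-first enumeration of all root-to-leaf paths.

    Ordering is deterministic: at every node the yes-branch is explored
    first.  All summary counts are tallied from the enumeration itself.
    Refuses a KB that fails :func:`validate_kb`.
    """
    report = validate_kb(kb)
    if not report.passed:
        raise InvalidKBError(report)

    paths: list[Path] = []
    questions_used: set[str] = set()

    def dfs(target: str, answers: list[str]) -> None:
        if kb.is_recommendation(target):
            paths.append(Path("".join(answers), target, len(answers)))
            return
        node = kb.nodes[target]
        questions_used.add(node.question_id)
        answers.append("y")
        dfs(node.yes_target, answers)
        answers[-1] = "n"
        dfs(node.no_target, answers)
        answers.pop()

    dfs(kb.root, [])

    rec_ids = {p.recommendation_id for p in paths}
    tests_covered = {
        tid for rid in rec_ids for tid in kb.recommendations[rid].test_ids
    }
    depths = [p.depth for p in paths]
    summary = PathSummary(
        n_paths=len(paths),
        n_distinct_recommendations=len(rec_ids),
        n_questions_used=len(questions_used),
        n_tests_covered=len(tests_covered),
        depth_min=min(depths),
        depth_max=max(depths),
        depth_histogram=dict(sorted(Counter(depths).items())),
    )
    return PathCatalog(paths=tuple(paths), summary=summary)


def shortest_path_to(kb: KnowledgeBase, test: TestMethod | str
                     ) -> tuple[str, int]:
    """Minimal-depth answer vector whose recommendation includes ``test``.

    ``test`` may be a TestMethod, a test id, or any resolvable name/alias.
    Ties break toward the yes-first enumeration order.  A test reachable by
    no path raises :class:`UnreachableTestError` — that would be a KB
    coverage bug.
    """
    from .model import canonicalize_test_name

    if isinstance(test, TestMethod):
        test_id = test.id
    elif test in kb.tests:
        test_id = test
    else:
        resolved = canonicalize_test_name(kb, test)
        if resolved is None:
            raise UnreachableTestError(test)
        test_id = resolved.id

    catalog = enumerate_paths(kb)
    best: Path | None = None
    for p in catalog.paths:  # yes-first order; strict < keeps first at min depth
        if test_id in kb.recommendations[p.recommendation_id].test_ids:
            if best is None or p.depth < best.depth:
                best = p
    if best is None:
        raise UnreachableTestError(test_id)
    return best.answers, best.depth


def provenance_report(kb: KnowledgeBase) -> dict[str, dict]:
    """Per-source test counts and lists, computed by counting test_ids."""
    out: dict[str, dict] = {}
    for name, source in sorted(kb.sources.items()):
        out[name] = {
            "n_tests": len(source.test_ids),
            "is_base": source.is_base,
            "tests": [kb.tests[tid].canonical_name for tid in source.test_ids],
        }
    return out


# --------------------------------------------------------------------------
# DOT export

def export_dot(kb: KnowledgeBase) -> str:
    """Graphviz DOT rendering: questions as boxes, recommendations as ovals."""
    lines = [
        "digraph decision_tree {",
        "  rankdir=TB;",
        '  node [fontname="Helvetica", fontsize=10];',
    ]
    for nid, node in sorted(kb.nodes.items()):
        text = _dot_escape(kb.questions[node.question_id].text)
        lines.append(f'  "{nid}" [shape=box, label="{text}"];')
    for rid, rec in sorted(kb.recommendations.items()):
        label = _dot_escape(rec.label(kb))
        lines.append(f'  "{rid}" [shape=oval, style=filled, '
                     f'fillcolor=lightgrey, label="{label}"];')
    for nid, branch, target in sorted(kb.iter_targets()):
        lines.append(f'  "{nid}" -> "{target}" [label="{branch}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')
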