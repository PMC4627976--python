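"""Reading and writing knowledge-base documents.

The on-disk format is a single YAML document (JSON is accepted
interchangeably on load, and produced when the output path ends in
``.json``) with top-level keys ``metadata``, ``root``, ``nodes``,
``questions``, ``recommendations``, ``tests``, ``glossary`` and
``sources``.  Branch targets are spelled ``yes_target`` / ``no_target``
(never bare ``yes:``/``no:`` keys, which YAML 1.1 would read as booleans).

Loading performs schema validation (typed fields, id uniqueness) and
enforces referential closure: every id mentioned anywhere must resolve.
Deeper structural audits — acyclicity, reachability, orphan detection —
are findings produced by :func:`statselect.analysis.validate_kb`, so that
a structurally suspect KB can still be loaded and inspected.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml

from .errors import DanglingReferenceError, InvalidKBError, KBSchemaError
from .model import (
    CATEGORIES,
    TEST_FAMILIES,
    DecisionNode,
    GlossaryEntry,
    KnowledgeBase,
    Question,
    Recommendation,
    SourceTree,
    TestMethod,
)

__all__ = ["load_kb", "save_kb", "loads_kb", "dumps_kb",
           "packaged_kb_path", "load_packaged_kb"]

_TOP_KEYS = ("metadata", "root", "nodes", "questions", "recommendations",
             "tests", "glossary", "sources")


def packaged_kb_path() -> Path:
    """Path of the unified decision tree shipped with the package."""
    return Path(resources.files("statselect") / "data" / "unified_tree.yaml")


def load_packaged_kb() -> KnowledgeBase:
    return load_kb(packaged_kb_path())


# --------------------------------------------------------------------------
# loading

def load_kb(path: str | Path) -> KnowledgeBase:
    """Load and cross-link a knowledge base from a YAML/JSON document.

    Raises
    ------
    FileNotFoundError
        if ``path`` does not exist.
    KBSchemaError
        naming the offending section/record/field on schema violations.
    DanglingReferenceError
        naming source and target ids when a reference does not resolve.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"knowledge base file not found: {path}")
    return loads_kb(path.read_text(encoding="utf-8"))


def loads_kb(text: str) -> KnowledgeBase:
    """Parse a KB document from a string (YAML or JSON)."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - parser detail
        raise KBSchemaError(f"document is not parseable YAML/JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise KBSchemaError("top level of the KB document must be a mapping")
    for key in _TOP_KEYS:
        if key not in doc:
            raise KBSchemaError("missing required top-level key", section=key)

    metadata = _expect(doc, "metadata", dict, section="metadata")
    root = _expect(doc, "root", str, section="root")

    questions = _load_records(doc, "questions", _load_question)
    tests = _load_records(doc, "tests", _load_test)
    recommendations = _load_records(doc, "recommendations", _load_recommendation)
    nodes = _load_records(doc, "nodes", _load_node)
    glossary = _load_records(doc, "glossary", _load_glossary_entry,
                             key_field="term")
    sources = _load_records(doc, "sources", _load_source, key_field="name")

    kb = KnowledgeBase(
        metadata=metadata, root=root, nodes=nodes, questions=questions,
        recommendations=recommendations, tests=tests, glossary=glossary,
        sources=sources,
    )
    _check_references(kb)
    _derive_test_sources(kb)
    return kb


def _derive_test_sources(kb: KnowledgeBase) -> None:
    """Populate each TestMethod's ``sources`` from SourceTree membership.

    The document states provenance once, in the ``sources`` section; the
    per-test view is the inverse mapping and is always rederived so the
    two can never disagree.
    """
    from dataclasses import replace

    membership: dict[str, list[str]] = {}
    for name, source in kb.sources.items():
        for tid in source.test_ids:
            membership.setdefault(tid, []).append(name)
    for tid, test in kb.tests.items():
        kb.tests[tid] = replace(test, sources=tuple(sorted(membership.get(tid, []))))


def _expect(record: dict, key: str, typ, *, section: str,
            record_id: str | None = None, default=None, required: bool = True):
    if key not in record or record[key] is None:
        if required:
            raise KBSchemaError("missing required field", section=section,
                                record_id=record_id, field=key)
        return default
    value = record[key]
    if typ is str and isinstance(value, (int, float, bool)):
        raise KBSchemaError(f"field must be text, got {value!r}",
                            section=section, record_id=record_id, field=key)
    if not isinstance(value, typ):
        raise KBSchemaError(
            f"field has wrong type {type(value).__name__}",
            section=section, record_id=record_id, field=key)
    return value


def _str_list(record: dict, key: str, *, section: str, record_id: str,
              required: bool = False) -> tuple[str, ...]:
    raw = _expect(record, key, list, section=section, record_id=record_id,
                  required=required, default=[])
    out = []
    for item in raw:
        if not isinstance(item, str):
            raise KBSchemaError(f"list items must be text, got {item!r}",
                                section=section, record_id=record_id, field=key)
        out.append(item)
    return tuple(out)


def _load_records(doc: dict, section: str, loader, key_field: str = "id") -> dict:
    raw = _expect(doc, section, list, section=section)
    out: dict = {}
    for record in raw:
        if not isinstance(record, dict):
            raise KBSchemaError("record must be a mapping", section=section)
        key = _expect(record, key_field, str, section=section)
        if key in out:
            raise KBSchemaError("duplicate record key", section=section,
                                record_id=key, field=key_field)
        out[key] = loader(record, key)
    return out


def _load_question(rec: dict, rid: str) -> Question:
    text = _expect(rec, "text", str, section="questions", record_id=rid)
    if not text.rstrip().endswith("?"):
        raise KBSchemaError("question text must end with '?'",
                            section="questions", record_id=rid, field="text")
    category = _expect(rec, "category", str, section="questions", record_id=rid)
    if category not in CATEGORIES:
        raise KBSchemaError(
            f"category must be one of {CATEGORIES}, got {category!r}",
            section="questions", record_id=rid, field="category")
    return Question(
        id=rid, text=text, category=category,
        explanation=_expect(rec, "explanation", str, section="questions",
                            record_id=rid, required=False, default=""),
        glossary_terms=_str_list(rec, "glossary_terms", section="questions",
                                 record_id=rid),
    )


def _load_test(rec: dict, rid: str) -> TestMethod:
    family = _expect(rec, "family", str, section="tests", record_id=rid)
    if family not in TEST_FAMILIES:
        raise KBSchemaError(
            f"family must be one of {TEST_FAMILIES}, got {family!r}",
            section="tests", record_id=rid, field="family")
    return TestMethod(
        id=rid,
        canonical_name=_expect(rec, "name", str, section="tests", record_id=rid),
        family=family,
        aliases=_str_list(rec, "aliases", section="tests", record_id=rid),
        sources=_str_list(rec, "sources", section="tests", record_id=rid),
    )


def _load_recommendation(rec: dict, rid: str) -> Recommendation:
    test_ids = _str_list(rec, "tests", section="recommendations",
                         record_id=rid, required=True)
    if not test_ids:
        raise KBSchemaError("a recommendation must name at least one test",
                            section="recommendations", record_id=rid,
                            field="tests")
    return Recommendation(
        id=rid, test_ids=test_ids,
        guidance=_expect(rec, "guidance", str, section="recommendations",
                         record_id=rid, required=False, default=""),
    )


def _load_node(rec: dict, rid: str) -> DecisionNode:
    return DecisionNode(
        id=rid,
        question_id=_expect(rec, "question", str, section="nodes", record_id=rid),
        yes_target=_expect(rec, "yes_target", str, section="nodes", record_id=rid),
        no_target=_expect(rec, "no_target", str, section="nodes", record_id=rid),
    )


def _load_glossary_entry(rec: dict, term: str) -> GlossaryEntry:
    if not term.strip():
        raise KBSchemaError("glossary term must be non-empty",
                            section="glossary", field="term")
    return GlossaryEntry(
        term=term,
        definition=_expect(rec, "definition", str, section="glossary",
                           record_id=term),
    )


def _load_source(rec: dict, name: str) -> SourceTree:
    base = rec.get("base", False)
    if not isinstance(base, bool):
        raise KBSchemaError("'base' must be a boolean", section="sources",
                            record_id=name, field="base")
    return SourceTree(
        name=name,
        test_ids=_str_list(rec, "tests", section="sources", record_id=name,
                           required=True),
        is_base=base,
    )


def _check_references(kb: KnowledgeBase) -> None:
    """Referential closure: every id mentioned anywhere must resolve."""
    if kb.root not in kb.nodes:
        raise DanglingReferenceError("root", kb.root, "root")
    for node in kb.nodes.values():
        if node.question_id not in kb.questions:
            raise DanglingReferenceError(node.id, node.question_id, "question")
        for fieldname, target in (("yes_target", node.yes_target),
                                  ("no_target", node.no_target)):
            if target not in kb.nodes and target not in kb.recommendations:
                raise DanglingReferenceError(node.id, target, fieldname)
    for rec in kb.recommendations.values():
        for tid in rec.test_ids:
            if tid not in kb.tests:
                raise DanglingReferenceError(rec.id, tid, "tests")
    for question in kb.questions.values():
        for term in question.glossary_terms:
            if term not in kb.glossary:
                raise DanglingReferenceError(question.id, term, "glossary_terms")
    for source in kb.sources.values():
        for tid in source.test_ids:
            if tid not in kb.tests:
                raise DanglingReferenceError(source.name, tid, "tests")
    for test in kb.tests.values():
        for src in test.sources:
            if src not in kb.sources:
                raise DanglingReferenceError(test.id, src, "sources")


# --------------------------------------------------------------------------
# saving

def save_kb(kb: KnowledgeBase, path: str | Path) -> Path:
    """Serialize a validated KB; refuses one that fails validation.

    Serialization is deterministic (records sorted by id), so saving the
    same KB twice produces byte-identical documents and
    ``load_kb(save_kb(kb))`` is structurally identical to ``kb``.
    """
    from .analysis import validate_kb  # local import: analysis depends on model only

    report = validate_kb(kb)
    if not report.passed:
        raise InvalidKBError(report)
    path = Path(path)
    text = dumps_kb(kb, fmt="json" if path.suffix.lower() == ".json" else "yaml")
    path.write_text(text, encoding="utf-8")
    return path


def dumps_kb(kb: KnowledgeBase, fmt: str = "yaml") -> str:
    doc = {
        "metadata": dict(sorted(kb.metadata.items())),
        "root": kb.root,
        "questions": [_dump_question(q) for _, q in sorted(kb.questions.items())],
        "nodes": [_dump_node(n) for _, n in sorted(kb.nodes.items())],
        "recommendations": [
            _dump_recommendation(r) for _, r in sorted(kb.recommendations.items())
        ],
        "tests": [_dump_test(t) for _, t in sorted(kb.tests.items())],
        "glossary": [
            {"term": g.term, "definition": g.definition}
            for _, g in sorted(kb.glossary.items())
        ],
        "sources": [
            {"name": s.name, "base": s.is_base, "tests": list(s.test_ids)}
            for _, s in sorted(kb.sources.items())
        ],
    }
    if fmt == "json":
        return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True, width=79)


def _dump_question(q: Question) -> dict:
    out = {"id": q.id, "text": q.text, "category": q.category}
    if q.explanation:
        out["explanation"] = q.explanation
    if q.glossary_terms:
        out["glossary_terms"] = list(q.glossary_terms)
    return out


def _dump_node(n: DecisionNode) -> dict:
    return {"id": n.id, "question": n.question_id,
            "yes_target": n.yes_target, "no_target": n.no_target}


def _dump_recommendation(r: Recommendation) -> dict:
    out = {"id": r.id, "tests": list(r.test_ids)}
    if r.guidance:
        out["guidance"] = r.guidance
    return out


def _dump_test(t: TestMethod) -> dict:
    out = {"id": t.id, "name": t.canonical_name, "family": t.family}
    if t.aliases:
        out["aliases"] = list(t.aliases)
    if t.sources:
        out["sources"] = list(t.sources)
    return out
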